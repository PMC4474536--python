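"""Canonical exchange formats for the drug-target integration pipeline.

Every table the pipeline touches is plain UTF-8 tab-separated text with a
header row; lines starting with ``#`` are comments.  The association table
carries one row per raw drug-target assertion from one source database:

    source  drug_name  cid  sid  drugbank_id  chebi_id  target_ns  target_value  taxon  pmids

Cross-reference cells may be empty; ``pmids`` is a ``;``-delimited list of
PubMed identifiers (treated as opaque grouping keys, never validated).
Readers never silently drop a data row: every row becomes either a record or
an entry in the returned rejects list, so ``rows_in == records_out +
rejects_out`` always holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

PMID_DELIMITER = ";"

XREF_NAMESPACES = ("cid", "sid", "drugbank_id", "chebi_id")
TARGET_NAMESPACES = ("uniprot-ac", "gene-id", "gene-symbol")

ASSOCIATION_COLUMNS = [
    "source", "drug_name", "cid", "sid", "drugbank_id", "chebi_id",
    "target_ns", "target_value", "taxon", "pmids",
]

#: Taxon code for "unknown"; treated as non-human by the purification filter.
UNKNOWN_TAXON = 0


class FormatError(ValueError):
    """A file does not conform to the exchange format (e.g. missing column)."""


@dataclass(frozen=True)
class SourceAssociationRecord:
    """One raw drug-target assertion from one source database."""

    source: str
    drug_name: str
    drug_xrefs: Mapping[str, str]
    target_ns: str
    target_value: str
    taxon: int = UNKNOWN_TAXON
    references: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.source:
            raise ValueError("source must be non-empty")
        if not self.drug_name.strip():
            raise ValueError("drug_name must be non-empty after trimming")
        if self.target_ns not in TARGET_NAMESPACES:
            raise ValueError(f"unknown target namespace {self.target_ns!r}")

    @property
    def raw_target(self) -> tuple[str, str]:
        return (self.target_ns, self.target_value)


@dataclass(frozen=True)
class RejectedRow:
    """A data row the reader could not turn into a record."""

    index: int
    reason: str
    detail: str = ""


@dataclass
class MappingTables:
    """Static lookup tables used for identifier normalization.

    ``synonym_to_cid`` keys are case-folded and whitespace-collapsed exactly
    once, at load time.  ``gene_info`` maps a gene ID to its ``(symbol,
    taxon)``.  ``atc_map`` and ``protein_class_map`` are optional annotation
    joins.
    """

    synonym_to_cid: dict[str, str] = field(default_factory=dict)
    uniprot_to_gene: dict[str, set[str]] = field(default_factory=dict)
    gene_info: dict[str, tuple[str, int]] = field(default_factory=dict)
    atc_map: dict[str, set[str]] = field(default_factory=dict)
    protein_class_map: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._symbol_index: dict[str, str] | None = None

    def human_symbol_index(self) -> dict[str, str]:
        """Gene symbol -> gene ID, restricted to human entries.

        Conflicting symbols keep the lexicographically smallest gene ID so
        resolution is deterministic.
        """
        if self._symbol_index is None:
            index: dict[str, str] = {}
            for gene_id, (symbol, taxon) in self.gene_info.items():
                if taxon != 9606 or not symbol:
                    continue
                if symbol not in index or gene_id < index[symbol]:
                    index[symbol] = gene_id
            self._symbol_index = index
        return self._symbol_index


@dataclass
class TrialLabelTable:
    """Clinical-trial labels: (drug key, condition token) -> trial count.

    Drug keys are matched case-folded; a candidate matches a row if any of
    its identifiers (UID, then display name) matches a key.
    """

    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @staticmethod
    def _fold(key: str) -> str:
        return " ".join(key.split()).casefold()

    def add(self, drug_key: str, condition: str, n_trials: int) -> None:
        if n_trials < 0:
            raise ValueError("trial count must be non-negative")
        key = (self._fold(drug_key), condition)
        if key in self.counts:
            raise ValueError(f"duplicate (drug, condition) key {key}")
        self.counts[key] = n_trials

    def count(self, identifiers: Iterable[str], condition: str) -> int:
        """Trial count for the first identifier with a row for *condition*."""
        for ident in identifiers:
            key = (self._fold(ident), condition)
            if key in self.counts:
                return self.counts[key]
        return 0

    def has_trial(self, identifiers: Iterable[str], condition: str) -> bool:
        return self.count(identifiers, condition) > 0


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       keep_default_na=False, **kwargs)


def _parse_pmids(cell: str) -> frozenset[str]:
    return frozenset(p.strip() for p in cell.split(PMID_DELIMITER) if p.strip())


def read_associations(
    path: str | Path,
) -> tuple[list[SourceAssociationRecord], list[RejectedRow]]:
    """Read the canonical association table.

    Returns the parsed records plus a list of rejected rows (malformed taxon,
    empty mandatory fields); a missing required column raises
    :class:`FormatError` naming the column.
    """
    df = _read_table(path)
    missing = [c for c in ASSOCIATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"association table missing column(s): {', '.join(missing)}")
    records: list[SourceAssociationRecord] = []
    rejects: list[RejectedRow] = []
    for i, row in enumerate(df.itertuples(index=False)):
        taxon_cell = row.taxon.strip()
        try:
            taxon = int(taxon_cell) if taxon_cell else UNKNOWN_TAXON
        except ValueError:
            rejects.append(RejectedRow(i, "malformed-taxon", taxon_cell))
            continue
        xrefs = {ns: getattr(row, ns).strip()
                 for ns in XREF_NAMESPACES if getattr(row, ns).strip()}
        try:
            records.append(SourceAssociationRecord(
                source=row.source.strip(),
                drug_name=row.drug_name,
                drug_xrefs=xrefs,
                target_ns=row.target_ns.strip(),
                target_value=row.target_value.strip(),
                taxon=taxon,
                references=_parse_pmids(row.pmids),
            ))
        except ValueError as exc:
            rejects.append(RejectedRow(i, "invalid-record", str(exc)))
    if not records and not rejects:
        logger.warning("association table %s has no data rows", path)
    return records, rejects


def write_associations(
    records: Iterable[SourceAssociationRecord], path: str | Path
) -> None:
    rows = []
    for r in records:
        rows.append({
            "source": r.source,
            "drug_name": r.drug_name,
            **{ns: r.drug_xrefs.get(ns, "") for ns in XREF_NAMESPACES},
            "target_ns": r.target_ns,
            "target_value": r.target_value,
            "taxon": r.taxon,
            "pmids": PMID_DELIMITER.join(sorted(r.references)),
        })
    pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS).to_csv(path, sep="\t", index=False)


def _normalize_synonym(name: str) -> str:
    return " ".join(name.split()).casefold()


def read_mappings(
    synonyms: str | Path | None = None,
    uniprot: str | Path | None = None,
    gene_info: str | Path | None = None,
    atc: str | Path | None = None,
    protein_class: str | Path | None = None,
) -> MappingTables:
    """Load the static mapping tables (each argument optional).

    Synonym keys are normalized exactly once here.  A synonym mapping to two
    different compound IDs keeps the lexicographically smallest ID and logs
    the conflict.
    """
    maps = MappingTables()
    if synonyms is not None:
        for row in _read_table(synonyms).itertuples(index=False):
            key = _normalize_synonym(row[0])
            cid = str(row[1]).strip()
            if not key or not cid:
                continue
            prev = maps.synonym_to_cid.get(key)
            if prev is not None and prev != cid:
                keep = min(prev, cid)
                logger.warning("synonym conflict %r -> %s vs %s; keeping %s",
                               key, prev, cid, keep)
                maps.synonym_to_cid[key] = keep
            else:
                maps.synonym_to_cid[key] = cid
    if uniprot is not None:
        for row in _read_table(uniprot).itertuples(index=False):
            ac, gene = str(row[0]).strip(), str(row[1]).strip()
            if ac and gene:
                maps.uniprot_to_gene.setdefault(ac, set()).add(gene)
    if gene_info is not None:
        for row in _read_table(gene_info).itertuples(index=False):
            gene, symbol, taxon = str(row[0]).strip(), str(row[1]).strip(), int(row[2])
            if not symbol or taxon <= 0:
                raise FormatError(
                    f"gene_info entry {gene!r} needs a symbol and positive taxon")
            maps.gene_info[gene] = (symbol, taxon)
    if atc is not None:
        for row in _read_table(atc).itertuples(index=False):
            key, code = str(row[0]).strip(), str(row[1]).strip()
            if key and code:
                maps.atc_map.setdefault(key, set()).add(code)
    if protein_class is not None:
        for row in _read_table(protein_class).itertuples(index=False):
            gene, label = str(row[0]).strip(), str(row[1]).strip()
            if gene and label:
                maps.protein_class_map.setdefault(gene, set()).add(label)
    return maps


def read_ppi(path: str | Path) -> nx.Graph:
    """Read a 2-column protein-protein interaction edge list over gene IDs.

    Edges are undirected and stored once; self-loop rows are dropped (count
    kept in ``graph.graph['self_loops_dropped']``), unparsable rows in
    ``graph.graph['rejects']``.
    """
    graph = nx.Graph()
    self_loops = 0
    rejects: list[RejectedRow] = []
    for i, row in enumerate(_read_table(path).itertuples(index=False)):
        try:
            a, b = str(row[0]).strip(), str(row[1]).strip()
        except IndexError:
            a = b = ""
        if not a or not b:
            rejects.append(RejectedRow(i, "unparsable-edge", "\t".join(map(str, row))))
            continue
        if a == b:
            self_loops += 1
            continue
        graph.add_edge(a, b)
    if self_loops:
        logger.info("dropped %d self-loop PPI rows from %s", self_loops, path)
    graph.graph["self_loops_dropped"] = self_loops
    graph.graph["rejects"] = rejects
    return graph


def write_ppi(graph: nx.Graph, path: str | Path) -> None:
    rows = sorted(tuple(sorted(e)) for e in graph.edges())
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def read_trials(path: str | Path) -> TrialLabelTable:
    """Read the 3-column trial-label table (drug key, condition, count)."""
    table = TrialLabelTable()
    for row in _read_table(path).itertuples(index=False):
        table.add(str(row[0]), str(row[1]).strip(), int(row[2]))
    return table


def write_trials(table: TrialLabelTable, path: str | Path) -> None:
    rows = [(k, c, n) for (k, c), n in sorted(table.counts.items())]
    pd.DataFrame(rows, columns=["drug", "condition", "n_trials"]).to_csv(
        path, sep="\t", index=False)


# Scores are serialized with enough digits for an exact float round trip.
_SCORE_FMT = "%.17g"


def write_interactome(assocs: Iterable, path: str | Path) -> None:
    """Write scored associations (one row per unique drug-target pair)."""
    rows = []
    for a in assocs:
        rows.append({
            "drug_uid": a.drug_uid,
            "gene_id": a.gene_id,
            "sources": PMID_DELIMITER.join(sorted(a.sources)),
            "pmids": PMID_DELIMITER.join(sorted(a.references)),
            "score_s": a.score_s,
            "score_r": _SCORE_FMT % a.score_r,
        })
    pd.DataFrame(rows, columns=["drug_uid", "gene_id", "sources", "pmids",
                                "score_s", "score_r"]).to_csv(path, sep="\t", index=False)


def read_interactome(path: str | Path) -> list:
    from .scoring import WeightedAssociation

    out = []
    for row in _read_table(path).itertuples(index=False):
        out.append(WeightedAssociation(
            drug_uid=row.drug_uid,
            gene_id=row.gene_id,
            sources=frozenset(s for s in row.sources.split(PMID_DELIMITER) if s),
            references=_parse_pmids(row.pmids),
            score_s=int(row.score_s),
            score_r=float(row.score_r),
        ))
    return out


def write_candidates(candidates: Iterable, path: str | Path) -> None:
    rows = []
    for c in sorted(candidates, key=lambda c: c.drug_uid):
        rows.append({
            "drug_uid": c.drug_uid,
            "routes": PMID_DELIMITER.join(sorted(c.routes)),
            "anchors": PMID_DELIMITER.join(sorted(c.anchor_targets)),
            "best_score_s": c.best_score_s,
            "best_score_r": _SCORE_FMT % c.best_score_r,
        })
    pd.DataFrame(rows, columns=["drug_uid", "routes", "anchors",
                                "best_score_s", "best_score_r"]).to_csv(
        path, sep="\t", index=False)


def read_candidates(path: str | Path) -> list:
    from .repurpose import RepurposingCandidate

    out = []
    for row in _read_table(path).itertuples(index=False):
        out.append(RepurposingCandidate(
            drug_uid=row.drug_uid,
            routes=frozenset(r for r in row.routes.split(PMID_DELIMITER) if r),
            anchor_targets=frozenset(
                a for a in row.anchors.split(PMID_DELIMITER) if a),
            best_score_s=int(row.best_score_s),
            best_score_r=float(row.best_score_r),
        ))
    return out
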