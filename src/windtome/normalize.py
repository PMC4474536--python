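"""Record linkage of heterogeneous drug and target identifiers.

Drugs from the different source databases are merged onto a unified
identifier (UID): an explicit compound-ID cross-reference wins, then an
exact (case-folded, whitespace-collapsed) synonym match against the compound
synonym table, and drugs that resolve neither way keep their source name.
Targets are normalized to gene IDs (UniProt accessions may expand to several
genes; gene symbols are matched against the human gene table).

Purification then removes degenerate associations: drug names shorter than
three characters, purely numeric drug names, and non-human targets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .exchange_io import MappingTables, SourceAssociationRecord

#: Purification rule indices (reported in reject records).
RULE_SHORT_NAME = 1
RULE_NUMERIC_NAME = 2
RULE_NON_HUMAN = 3

HUMAN_TAXON = 9606


def normalize_name(name: str) -> str:
    """Case-fold, trim, and collapse internal whitespace — applied once."""
    return " ".join(name.split()).casefold()


@dataclass(frozen=True)
class DrugRecord:
    """A drug with its unified identifier and retained cross-references."""

    uid: str
    display_name: str
    xrefs: tuple[tuple[str, str], ...] = ()
    atc_codes: frozenset[str] = frozenset()


@dataclass(frozen=True)
class TargetRecord:
    """A normalized drug target (gene ID, symbol, taxon)."""

    gene_id: str
    symbol: str
    taxon: int


@dataclass(frozen=True)
class ResolvedAssociation:
    """One source assertion after identifier resolution, pre-scoring."""

    drug: DrugRecord
    target: TargetRecord
    source: str
    references: frozenset[str] = frozenset()


@dataclass(frozen=True)
class PurgeReject:
    association: ResolvedAssociation
    rule: int


@dataclass
class NormalizationResult:
    kept: list[ResolvedAssociation]
    purged: list[PurgeReject]
    unresolved_targets: list[SourceAssociationRecord]


def resolve_drug(record: SourceAssociationRecord, maps: MappingTables) -> DrugRecord:
    """Assign the unified drug identifier for one raw assertion.

    Priority: explicit compound-ID xref, then exact synonym match, then the
    source's own name.  Every record resolves to some UID.
    """
    name = record.drug_name.strip()
    xrefs = tuple(sorted(record.drug_xrefs.items()))
    cid = record.drug_xrefs.get("cid")
    if cid:
        return DrugRecord(uid=f"CID:{cid}", display_name=name, xrefs=xrefs)
    mapped = maps.synonym_to_cid.get(normalize_name(name))
    if mapped:
        return DrugRecord(uid=f"CID:{mapped}", display_name=name, xrefs=xrefs)
    return DrugRecord(uid=f"NAME:{normalize_name(name)}", display_name=name,
                      xrefs=xrefs)


def resolve_target(
    record: SourceAssociationRecord, maps: MappingTables
) -> set[TargetRecord]:
    """Normalize the raw target reference to gene records.

    UniProt accessions may map to several genes — the association is expanded
    to one per gene.  An unresolvable target yields the empty set (the caller
    counts it as a reject).
    """
    ns, value = record.raw_target
    gene_ids: set[str] = set()
    if ns == "uniprot-ac":
        gene_ids = {g for g in maps.uniprot_to_gene.get(value, set())
                    if g in maps.gene_info}
    elif ns == "gene-id":
        if value in maps.gene_info:
            gene_ids = {value}
    elif ns == "gene-symbol":
        gene_id = maps.human_symbol_index().get(value)
        if gene_id is not None:
            gene_ids = {gene_id}
    out = set()
    for g in sorted(gene_ids):
        symbol, taxon = maps.gene_info[g]
        out.add(TargetRecord(gene_id=g, symbol=symbol, taxon=taxon))
    return out


def purge_rule(assoc: ResolvedAssociation) -> int | None:
    """Return the index of the first purification rule hit, or None."""
    name = assoc.drug.display_name
    if len(name) < 3:
        return RULE_SHORT_NAME
    if name.strip().isdigit():
        return RULE_NUMERIC_NAME
    if assoc.target.taxon != HUMAN_TAXON:
        return RULE_NON_HUMAN
    return None


def purify(
    assocs: Iterable[ResolvedAssociation],
) -> tuple[list[ResolvedAssociation], list[PurgeReject]]:
    """Apply the three purification filters; order-independent on the kept set."""
    kept, purged = [], []
    for assoc in assocs:
        rule = purge_rule(assoc)
        if rule is None:
            kept.append(assoc)
        else:
            purged.append(PurgeReject(assoc, rule))
    return kept, purged


def normalize_associations(
    records: Sequence[SourceAssociationRecord], maps: MappingTables
) -> NormalizationResult:
    """Resolve and purify a batch of raw assertions.

    Deterministic: the same inputs always give the same UIDs and gene sets,
    independent of record order.
    """
    resolved: list[ResolvedAssociation] = []
    unresolved: list[SourceAssociationRecord] = []
    for record in records:
        drug = resolve_drug(record, maps)
        targets = resolve_target(record, maps)
        if not targets:
            unresolved.append(record)
            continue
        for target in sorted(targets, key=lambda t: t.gene_id):
            resolved.append(ResolvedAssociation(
                drug=drug, target=target, source=record.source,
                references=record.references))
    kept, purged = purify(resolved)
    return NormalizationResult(kept=kept, purged=purged,
                               unresolved_targets=unresolved)


def build_drug_registry(
    assocs: Iterable[ResolvedAssociation], maps: MappingTables | None = None
) -> dict[str, DrugRecord]:
    """UID -> representative DrugRecord over a batch of kept associations.

    When several sources spell the same drug differently, the
    lexicographically smallest display name is kept so the registry is
    order-independent.  ATC codes are joined in if a map is supplied (keys
    may be UIDs, bare compound IDs, or names).
    """
    registry: dict[str, DrugRecord] = {}
    for assoc in assocs:
        cur = registry.get(assoc.drug.uid)
        if cur is None or assoc.drug.display_name < cur.display_name:
            registry[assoc.drug.uid] = assoc.drug
    if maps is not None and maps.atc_map:
        for uid, drug in registry.items():
            codes: set[str] = set()
            for key in (uid, uid.split(":", 1)[1], drug.display_name):
                codes |= maps.atc_map.get(key, set())
            if codes:
                registry[uid] = replace(drug, atc_codes=frozenset(codes))
    return registry
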