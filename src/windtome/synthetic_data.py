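"""Synthetic multi-source drug-target datasets with a ground-truth manifest.

The generator emits everything the pipeline consumes — per-source
association assertions, synonym/UniProt/gene-info mapping tables, ATC and
protein-class maps, a PPI edge list, disease inputs and a trial-label table
— together with a manifest of what was planted, so every stage can be tested
end-to-end without any external download.

The statistical structure mirrors what the integration method assumes:

* each planted pair is asserted by an assigned number of sources
  (its multiplicity, which the pipeline must recover as Score_S), with
  deliberately heterogeneous identifiers across sources (compound-ID
  cross-references vs bare names resolved through the synonym table;
  UniProt accessions vs gene IDs vs symbols);
* focused references support a single pair (profile f=d=t=1) while
  HTS-style references span ``hts_breadth`` drugs against one target;
  two of the sources carry no references at all;
* a disease neighborhood is planted: known drugs and their targets,
  disease genes of which a subset are direct PPI neighbors of known
  targets, candidate drugs reachable by each inference route at the
  default threshold, and decoy candidates only reachable below it;
* trial labels are assigned with precision increasing in multiplicity, so
  enrichment improves with the Score_S threshold.

Planted structure is *constructed*, not sampled, wherever tests assert
exact equality; randomness (seeded) only chooses which grid cells host
pairs, synonym noise, and background PPI wiring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exchange_io import (
    MappingTables,
    SourceAssociationRecord,
    write_associations,
)
from .repurpose import DiseaseInputs

HUMAN = 9606
MOUSE = 10090

#: Emission style per source position: (emit_cid, emit_sid, name_style,
#: target_namespace, has_references).  Styles cycle if n_sources != 6.
_SOURCE_STYLES = [
    (True, False, "canonical", "uniprot-ac", True),
    (True, False, "canonical", "gene-id", False),
    (False, False, "plain", "gene-symbol", False),
    (False, False, "noisy", "uniprot-ac", True),
    (True, True, "canonical", "gene-id", True),
    (True, False, "canonical", "gene-symbol", True),
]


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults give six sources, 500 background drugs, 80 background targets
    and roughly two thousand raw assertions — seconds to generate and to
    push through the full pipeline.
    """

    seed: int = 0
    n_sources: int = 6
    n_drugs: int = 500
    n_targets: int = 80
    #: planted pairs per source-multiplicity value
    multiplicity_counts: dict[int, int] = field(
        default_factory=lambda: {1: 500, 2: 230, 3: 110, 4: 45, 5: 18, 6: 9})
    #: fraction of all references that are HTS-style publications
    hts_reference_fraction: float = 0.02
    #: drugs per HTS reference (each against one target)
    hts_breadth: int = 10
    #: probability a compound-ID drug also circulates under an alternate name
    synonym_noise_rate: float = 0.2
    #: probability a background drug has no compound ID anywhere
    no_cid_rate: float = 0.1
    #: fraction of raw assertions pointing at a non-human target
    nonhuman_rate: float = 0.03
    # disease-module sizes
    n_known_drugs: int = 4
    n_known_targets: int = 5
    n_anchor_genes: int = 3     # disease genes adjacent to known targets
    n_other_disease_genes: int = 5
    n_route1_candidates: int = 6
    n_route2_candidates: int = 4
    n_dual_route_candidates: int = 1
    n_decoys_multiplicity2: int = 8
    n_decoys_multiplicity1: int = 20
    #: fraction of candidates per Score_S stratum with a primary-condition trial
    trial_precision: dict[int, float] = field(
        default_factory=lambda: {3: 0.6, 2: 0.25, 1: 0.05})
    #: same, for the related-condition class
    class_trial_precision: dict[int, float] = field(
        default_factory=lambda: {3: 0.8, 2: 0.4, 1: 0.1})
    ppi_background_edges: int = 150
    primary_condition: str = "disease-of-interest"
    class_condition: str = "related-class"

    def validate(self) -> None:
        for rate in (self.hts_reference_fraction, self.synonym_noise_rate,
                     self.no_cid_rate, self.nonhuman_rate,
                     *self.trial_precision.values(),
                     *self.class_trial_precision.values()):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        counts = (self.n_sources, self.n_drugs, self.n_targets,
                  self.hts_breadth, self.n_known_drugs, self.n_known_targets,
                  self.n_anchor_genes, self.n_route1_candidates,
                  self.n_route2_candidates)
        if any(c <= 0 for c in counts):
            raise ValueError("entity counts must be positive")
        if any(m < 1 or m > self.n_sources for m in self.multiplicity_counts):
            raise ValueError("multiplicities must lie in 1..n_sources")
        if sum(self.multiplicity_counts.values()) > self.n_drugs * self.n_targets:
            raise ValueError("more planted pairs than background grid cells")


@dataclass(frozen=True)
class PlantedPair:
    drug_uid: str
    gene_id: str
    multiplicity: int
    sources: tuple[str, ...]
    expected_score_r: float
    ref_class: str  # specific | hts | none | shared


@dataclass
class GroundTruthManifest:
    """Ledger of everything planted in one synthetic dataset."""

    pairs: dict[tuple[str, str], PlantedPair]
    route1_drugs: frozenset[str]
    route2_drugs: frozenset[str]
    candidates_by_threshold: dict[int, frozenset[str]]
    trial_hits: dict[str, frozenset[str]]
    purge_counts: dict[int, int]
    n_unresolved: int
    n_records: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_drugs(self) -> int:
        return len({uid for uid, _ in self.pairs})

    @property
    def n_targets(self) -> int:
        return len({g for _, g in self.pairs})

    def multiplicity_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for p in self.pairs.values():
            hist[p.multiplicity] = hist.get(p.multiplicity, 0) + 1
        return hist


@dataclass
class SyntheticDataset:
    """In-memory form of one generated dataset plus its manifest."""

    config: GeneratorConfig
    records: list[SourceAssociationRecord]
    synonym_rows: list[tuple[str, str]]
    uniprot_rows: list[tuple[str, str]]
    gene_info_rows: list[tuple[str, str, int]]
    atc_rows: list[tuple[str, str]]
    class_rows: list[tuple[str, str]]
    ppi_edges: list[tuple[str, str]]
    disease: DiseaseInputs
    trial_rows: list[tuple[str, str, int]]
    manifest: GroundTruthManifest

    def mapping_tables(self) -> MappingTables:
        """The mapping tables exactly as the readers would load them."""
        from .exchange_io import _normalize_synonym  # same normalization path

        maps = MappingTables()
        for syn, cid in self.synonym_rows:
            key = _normalize_synonym(syn)
            prev = maps.synonym_to_cid.get(key)
            maps.synonym_to_cid[key] = min(prev, cid) if prev else cid
        for ac, gene in self.uniprot_rows:
            maps.uniprot_to_gene.setdefault(ac, set()).add(gene)
        for gene, symbol, taxon in self.gene_info_rows:
            maps.gene_info[gene] = (symbol, taxon)
        for key, code in self.atc_rows:
            maps.atc_map.setdefault(key, set()).add(code)
        for gene, label in self.class_rows:
            maps.protein_class_map.setdefault(gene, set()).add(label)
        return maps


@dataclass
class _Drug:
    name: str
    cid: str | None
    alt_name: str | None = None

    @property
    def uid(self) -> str:
        return f"CID:{self.cid}" if self.cid else f"NAME:{self.name}"


class _Builder:
    def __init__(self, config: GeneratorConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.sources = [f"src{i + 1}" for i in range(config.n_sources)]
        self.styles = [_SOURCE_STYLES[i % len(_SOURCE_STYLES)]
                       for i in range(config.n_sources)]
        self.records: list[SourceAssociationRecord] = []
        self.synonym_rows: list[tuple[str, str]] = []
        self.uniprot_rows: list[tuple[str, str]] = []
        self.gene_info_rows: list[tuple[str, str, int]] = []
        self.atc_rows: list[tuple[str, str]] = []
        self.class_rows: list[tuple[str, str]] = []
        self.pairs: dict[tuple[str, str], PlantedPair] = {}
        self.pair_counter = 0
        self.n_specific_refs = 0
        self.gene_meta: dict[str, tuple[str, str]] = {}

    # -- entity helpers -------------------------------------------------

    def add_gene(self, gene_id: str, symbol: str, uniprot: str | None,
                 taxon: int = HUMAN) -> None:
        self.gene_info_rows.append((gene_id, symbol, taxon))
        if uniprot:
            self.uniprot_rows.append((uniprot, gene_id))
        self.gene_meta[gene_id] = (symbol, uniprot or "")

    def register_drug(self, drug: _Drug, with_alt: bool = False) -> None:
        if drug.cid:
            self.synonym_rows.append((drug.name, drug.cid))
            if with_alt:
                drug.alt_name = f"{drug.name} alt"
                self.synonym_rows.append((drug.alt_name, drug.cid))

    # -- record emission ------------------------------------------------

    def emit(self, source_idx: int, drug: _Drug, gene_id: str,
             pmids: Iterable[str] = (), taxon: int = HUMAN,
             target_override: tuple[str, str] | None = None) -> None:
        emit_cid, emit_sid, name_style, target_ns, _ = self.styles[source_idx]
        xrefs: dict[str, str] = {}
        if emit_cid and drug.cid:
            xrefs["cid"] = drug.cid
        if emit_sid and drug.cid:
            xrefs["sid"] = f"S{drug.cid}"
        name = drug.name
        if name_style == "noisy" and drug.alt_name:
            name = drug.alt_name
        if target_override is not None:
            target_ns, target_value = target_override
        else:
            target_value = self.gene_ref(gene_id, target_ns)
        self.records.append(SourceAssociationRecord(
            source=self.sources[source_idx], drug_name=name, drug_xrefs=xrefs,
            target_ns=target_ns, target_value=target_value, taxon=taxon,
            references=frozenset(pmids)))

    def gene_ref(self, gene_id: str, namespace: str) -> str:
        if namespace == "gene-id":
            return gene_id
        symbol, uniprot = self.gene_meta[gene_id]
        return symbol if namespace == "gene-symbol" else uniprot

    # -- planted pairs ---------------------------------------------------

    def plant_pair(self, drug: _Drug, gene_id: str, multiplicity: int,
                   ref_class: str = "specific") -> None:
        """Emit one pair into ``multiplicity`` rotated sources.

        Every reference-bearing source attaches one fresh single-pair PubMed
        ID, so the pair's expected Score_R equals the number of
        reference-bearing sources asserting it.
        """
        k = self.pair_counter
        self.pair_counter += 1
        chosen = [(k + j) % self.cfg.n_sources for j in range(multiplicity)]
        n_refs = 0
        for j, s in enumerate(chosen):
            pmids: list[str] = []
            if self.styles[s][4] and ref_class == "specific":
                pmids = [f"PM{k:05d}x{j}"]
                n_refs += 1
            self.emit(s, drug, gene_id, pmids)
        self.n_specific_refs += n_refs
        key = (drug.uid, gene_id)
        assert key not in self.pairs, f"pair collision {key}"
        self.pairs[key] = PlantedPair(
            drug_uid=drug.uid, gene_id=gene_id, multiplicity=multiplicity,
            sources=tuple(self.sources[s] for s in chosen),
            expected_score_r=float(n_refs),
            ref_class="specific" if n_refs else "none")


def build_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Construct one synthetic dataset entirely in memory."""
    cfg = config or GeneratorConfig()
    b = _Builder(cfg)
    rng = b.rng

    # ---- background ("grid") universe ---------------------------------
    grid_drugs = []
    for i in range(cfg.n_drugs):
        has_cid = rng.random() >= cfg.no_cid_rate
        drug = _Drug(name=f"drug{i:04d}", cid=f"C{i:05d}" if has_cid else None)
        b.register_drug(drug, with_alt=has_cid and
                        rng.random() < cfg.synonym_noise_rate)
        grid_drugs.append(drug)
        if has_cid and i % 3 == 0:
            b.atc_rows.append((drug.cid, f"N{i % 7:02d}A"))
            if i % 6 == 0:
                b.atc_rows.append((drug.cid, f"C{i % 5:02d}B"))

    grid_genes = []
    class_labels = ["receptor", "transporter", "kinase", "enzyme modulator"]
    for j in range(cfg.n_targets):
        gene, symbol, uniprot = f"g{j:04d}", f"GS{j:04d}", f"P{j:04d}"
        b.add_gene(gene, symbol, uniprot)
        grid_genes.append(gene)
        if j % 7 != 0:  # some targets stay unclassified
            b.class_rows.append((gene, class_labels[j % 4]))
            if j % 5 == 0:
                b.class_rows.append((gene, class_labels[(j + 1) % 4]))

    # ---- reserved disease-module entities ------------------------------
    def reserved_gene(gene: str, symbol: str, uniprot: str) -> str:
        b.add_gene(gene, symbol, uniprot)
        b.class_rows.append((gene, "receptor"))
        return gene

    known_targets = [reserved_gene(f"kt{j}", f"KTS{j}", f"PKT{j}")
                     for j in range(cfg.n_known_targets)]
    anchor_genes = [reserved_gene(f"ag{j}", f"AGS{j}", f"PAG{j}")
                    for j in range(cfg.n_anchor_genes)]
    other_disease = [reserved_gene(f"dg{j}", f"DGS{j}", f"PDG{j}")
                     for j in range(cfg.n_other_disease_genes)]

    def reserved_drug(name: str, cid: str) -> _Drug:
        drug = _Drug(name=name, cid=cid)
        b.register_drug(drug)
        b.atc_rows.append((cid, "N05A"))
        return drug

    known_drugs = [reserved_drug(f"knowndrug{i}", f"CKD{i:02d}")
                   for i in range(cfg.n_known_drugs)]
    route1_drugs = [reserved_drug(f"routeonedrug{i}", f"CR1{i:02d}")
                    for i in range(cfg.n_route1_candidates)]
    route2_drugs = [reserved_drug(f"routetwodrug{i}", f"CR2{i:02d}")
                    for i in range(cfg.n_route2_candidates)]
    dual_drugs = [reserved_drug(f"dualroutedrug{i}", f"CDU{i:02d}")
                  for i in range(cfg.n_dual_route_candidates)]
    decoys2 = [reserved_drug(f"decoytwo{i}", f"CD2{i:02d}")
               for i in range(cfg.n_decoys_multiplicity2)]
    decoys1 = [reserved_drug(f"decoyone{i}", f"CD1{i:02d}")
               for i in range(cfg.n_decoys_multiplicity1)]

    # ---- background pairs with assigned multiplicity -------------------
    n_grid_pairs = sum(cfg.multiplicity_counts.values())
    cells = rng.choice(cfg.n_drugs * cfg.n_targets, size=n_grid_pairs,
                       replace=False)
    multiplicities = [m for m in sorted(cfg.multiplicity_counts)
                      for _ in range(cfg.multiplicity_counts[m])]
    for cell, m in zip(cells, multiplicities):
        drug = grid_drugs[int(cell) // cfg.n_targets]
        gene = grid_genes[int(cell) % cfg.n_targets]
        b.plant_pair(drug, gene, m)

    # ---- disease module -------------------------------------------------
    cap = cfg.n_sources
    for i, drug in enumerate(known_drugs):
        b.plant_pair(drug, known_targets[i % len(known_targets)], min(3, cap))
    for i, drug in enumerate(route1_drugs):
        b.plant_pair(drug, known_targets[i % len(known_targets)],
                     min(3 + i % 2, cap))
    for i, drug in enumerate(route2_drugs):
        b.plant_pair(drug, anchor_genes[i % len(anchor_genes)],
                     min(3 + i % 2, cap))
    for i, drug in enumerate(dual_drugs):
        b.plant_pair(drug, known_targets[0], min(3, cap))
        b.plant_pair(drug, anchor_genes[0], min(3, cap))
    for i, drug in enumerate(decoys2):
        gene = known_targets[i % len(known_targets)] if i % 2 == 0 \
            else anchor_genes[i % len(anchor_genes)]
        b.plant_pair(drug, gene, min(2, cap))
    for i, drug in enumerate(decoys1):
        gene = known_targets[i % len(known_targets)] if i % 2 == 0 \
            else anchor_genes[i % len(anchor_genes)]
        b.plant_pair(drug, gene, 1)

    # ---- HTS-style references ------------------------------------------
    frac = cfg.hts_reference_fraction
    n_hts = 0
    if frac > 0:
        n_hts = max(1, round(frac / (1.0 - frac) * b.n_specific_refs))
    ref_bearing = [i for i, st in enumerate(b.styles) if st[4]]
    for h in range(n_hts):
        gene = grid_genes[h % cfg.n_targets]
        pmid = f"PMHTS{h:03d}"
        source_idx = ref_bearing[h % len(ref_bearing)]
        spec = cfg.hts_breadth / cfg.hts_breadth ** 2  # d*t/f^2 with t=1
        for i in range(cfg.hts_breadth):
            drug = _Drug(name=f"htsdrug{h:03d}n{i:02d}", cid=f"CH{h:03d}{i:02d}")
            b.register_drug(drug)
            b.emit(source_idx, drug, gene, [pmid])
            b.pairs[(drug.uid, gene)] = PlantedPair(
                drug_uid=drug.uid, gene_id=gene, multiplicity=1,
                sources=(b.sources[source_idx],),
                expected_score_r=spec, ref_class="hts")

    # ---- one multi-gene UniProt expansion ------------------------------
    gx1, gx2 = "gx1", "gx2"
    b.add_gene(gx1, "GXS1", "PMULTI")
    b.add_gene(gx2, "GXS2", "PMULTI")
    exp_drug = _Drug(name="expansiondrug", cid=None)
    b.emit(0, exp_drug, gx1, ["PMEXP"],
           target_override=("uniprot-ac", "PMULTI"))
    for gene in (gx1, gx2):
        # PMEXP supports two pairs of one drug: d=1, t=2, f=2 -> 0.5 each
        b.pairs[(exp_drug.uid, gene)] = PlantedPair(
            drug_uid=exp_drug.uid, gene_id=gene, multiplicity=1,
            sources=(b.sources[0],), expected_score_r=0.5, ref_class="shared")

    # ---- records destined for purification / rejection ------------------
    purge_counts = {1: 2, 2: 2, 3: 0}
    for i in range(2):  # rule 1: name shorter than three characters
        short = _Drug(name="ab", cid="CAB00")
        b.emit(i % cfg.n_sources, short, grid_genes[i])
    for i in range(2):  # rule 2: purely numeric name, unresolvable to a CID
        b.emit((i + 1) % cfg.n_sources, _Drug(name="12345", cid=None),
               grid_genes[i + 2])
    n_mouse = max(1, int(cfg.nonhuman_rate * len(b.records)))
    mouse_genes = []
    for j in range(min(n_mouse, 25)):
        gene = f"mg{j:03d}"
        b.add_gene(gene, f"MGS{j:03d}", None, taxon=MOUSE)
        b.gene_meta[gene] = (f"MGS{j:03d}", "")
        mouse_genes.append(gene)
    for i in range(n_mouse):  # rule 3: non-human target
        b.emit(1, grid_drugs[i % cfg.n_drugs], mouse_genes[i % len(mouse_genes)],
               taxon=MOUSE, target_override=("gene-id",
                                             mouse_genes[i % len(mouse_genes)]))
    purge_counts[3] = n_mouse
    n_unresolved = 2
    for i in range(n_unresolved):  # unresolvable UniProt accession
        b.emit(0, grid_drugs[i], grid_genes[0],
               target_override=("uniprot-ac", f"Q9UNKNOWN{i}"))

    # ---- PPI network ----------------------------------------------------
    ppi_edges: list[tuple[str, str]] = []
    for j, anchor in enumerate(anchor_genes):
        ppi_edges.append((known_targets[j % len(known_targets)], anchor))
    for j, kt in enumerate(known_targets):  # neighbors outside disease genes
        ppi_edges.append((kt, grid_genes[j % cfg.n_targets]))
    for j, dg in enumerate(other_disease):  # disease genes off the neighborhood
        ppi_edges.append((dg, grid_genes[(10 + j) % cfg.n_targets]))
    seen = set(map(frozenset, ppi_edges))
    target_total = len(ppi_edges) + cfg.ppi_background_edges
    while len(ppi_edges) < target_total:
        a, c = rng.choice(cfg.n_targets, size=2, replace=False)
        edge = frozenset((grid_genes[int(a)], grid_genes[int(c)]))
        if edge not in seen:
            seen.add(edge)
            ppi_edges.append((grid_genes[int(a)], grid_genes[int(c)]))

    disease = DiseaseInputs(
        known_drugs=frozenset(d.uid for d in known_drugs),
        known_targets=frozenset(known_targets),
        disease_genes=frozenset(anchor_genes) | frozenset(other_disease),
    )

    # ---- candidate sets by threshold and trial labels -------------------
    theta3 = frozenset(d.uid for d in route1_drugs + route2_drugs + dual_drugs)
    theta2_extra = frozenset(d.uid for d in decoys2)
    theta1_extra = frozenset(d.uid for d in decoys1)
    candidates_by_threshold = {
        3: theta3,
        2: theta3 | theta2_extra,
        1: theta3 | theta2_extra | theta1_extra,
    }
    route1_uids = frozenset(d.uid for d in route1_drugs + dual_drugs)
    route2_uids = frozenset(d.uid for d in route2_drugs + dual_drugs)

    trial_rows: list[tuple[str, str, int]] = []
    trial_hits: dict[str, set[str]] = {cfg.primary_condition: set(),
                                       cfg.class_condition: set()}

    def label_stratum(uids: frozenset[str], stratum: int) -> None:
        ordered = sorted(uids)
        for condition, precision in (
                (cfg.primary_condition, cfg.trial_precision.get(stratum, 0.0)),
                (cfg.class_condition, cfg.class_trial_precision.get(stratum, 0.0))):
            n_hit = math.ceil(precision * len(ordered))
            for idx, uid in enumerate(ordered[:n_hit]):
                trial_rows.append((uid, condition, 1 + idx % 3))
                trial_hits[condition].add(uid)

    label_stratum(theta3, 3)
    label_stratum(theta2_extra, 2)
    label_stratum(theta1_extra, 1)
    # noise rows that must not influence any hit rate
    trial_rows.append((known_drugs[0].uid, "other", 2))
    trial_rows.append((grid_drugs[0].uid, "other", 1))

    manifest = GroundTruthManifest(
        pairs=b.pairs,
        route1_drugs=route1_uids,
        route2_drugs=route2_uids,
        candidates_by_threshold=candidates_by_threshold,
        trial_hits={c: frozenset(s) for c, s in trial_hits.items()},
        purge_counts=purge_counts,
        n_unresolved=n_unresolved,
        n_records=len(b.records),
    )
    return SyntheticDataset(
        config=cfg, records=b.records,
        synonym_rows=b.synonym_rows, uniprot_rows=b.uniprot_rows,
        gene_info_rows=b.gene_info_rows, atc_rows=b.atc_rows,
        class_rows=b.class_rows, ppi_edges=ppi_edges, disease=disease,
        trial_rows=trial_rows, manifest=manifest)


def generate(config: GeneratorConfig | None = None,
             outdir: str | Path = ".") -> GroundTruthManifest:
    """Generate a dataset and write the full file set under *outdir*.

    The same seed always produces a byte-identical directory tree.
    """
    ds = build_dataset(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    write_associations(ds.records, out / "associations.tsv")

    def tsv(name: str, rows, columns) -> None:
        pd.DataFrame(rows, columns=columns).to_csv(out / name, sep="\t",
                                                   index=False)

    tsv("synonyms.tsv", ds.synonym_rows, ["synonym", "cid"])
    tsv("uniprot.tsv", sorted(ds.uniprot_rows), ["uniprot_ac", "gene_id"])
    tsv("gene_info.tsv", ds.gene_info_rows, ["gene_id", "symbol", "taxon"])
    tsv("atc.tsv", ds.atc_rows, ["drug_key", "atc_code"])
    tsv("classes.tsv", ds.class_rows, ["gene_id", "class_label"])
    tsv("ppi.tsv", ds.ppi_edges, ["gene_a", "gene_b"])
    tsv("trials.tsv", ds.trial_rows, ["drug", "condition", "n_trials"])
    for name, ids in (("known_drugs.txt", ds.disease.known_drugs),
                      ("known_targets.txt", ds.disease.known_targets),
                      ("disease_genes.txt", ds.disease.disease_genes)):
        (out / name).write_text("\n".join(sorted(ids)) + "\n")

    m = ds.manifest
    tsv("manifest_pairs.tsv",
        [(p.drug_uid, p.gene_id, p.multiplicity, ";".join(p.sources),
          "%.12g" % p.expected_score_r, p.ref_class)
         for p in (m.pairs[k] for k in sorted(m.pairs))],
        ["drug_uid", "gene_id", "multiplicity", "sources",
         "expected_score_r", "ref_class"])
    cand_rows = []
    for theta in sorted(m.candidates_by_threshold, reverse=True):
        for uid in sorted(m.candidates_by_threshold[theta]):
            routes = []
            if uid in m.route1_drugs:
                routes.append("shared-target")
            if uid in m.route2_drugs:
                routes.append("ppi-neighbor")
            cand_rows.append((theta, uid, ";".join(routes) or "decoy"))
    tsv("manifest_candidates.tsv", cand_rows, ["min_score_s", "drug_uid", "routes"])
    hist = m.multiplicity_histogram()
    summary = [
        f"records\t{m.n_records}",
        f"planted_pairs\t{m.n_pairs}",
        f"planted_drugs\t{m.n_drugs}",
        f"planted_targets\t{m.n_targets}",
        *(f"multiplicity_{k}\t{hist[k]}" for k in sorted(hist)),
        *(f"purged_rule_{k}\t{v}" for k, v in sorted(m.purge_counts.items())),
        f"unresolved_targets\t{m.n_unresolved}",
    ]
    (out / "manifest_summary.txt").write_text("\n".join(summary) + "\n")
    return m


def validate_against_manifest(
    interactome,
    inference,
    manifest: GroundTruthManifest,
    score_r_tol: float = 1e-9,
) -> list[str]:
    """Compare pipeline outputs with the generation manifest.

    Checks pair-set identity, Score_S against planted multiplicity, Score_R
    against the constructed reference structure, and exact recovery of the
    planted candidate set at the default threshold.  Returns a list of
    mismatch descriptions (empty on a clean run).
    """
    mismatches: list[str] = []
    got = interactome.associations
    for key in sorted(set(manifest.pairs) - set(got)):
        mismatches.append(f"planted pair missing from interactome: {key}")
    for key in sorted(set(got) - set(manifest.pairs)):
        mismatches.append(f"unplanted pair in interactome: {key}")
    for key in sorted(set(got) & set(manifest.pairs)):
        planted, scored = manifest.pairs[key], got[key]
        if scored.score_s != planted.multiplicity:
            mismatches.append(
                f"{key}: score_s {scored.score_s} != planted multiplicity "
                f"{planted.multiplicity}")
        if abs(scored.score_r - planted.expected_score_r) > score_r_tol:
            mismatches.append(
                f"{key}: score_r {scored.score_r!r} != expected "
                f"{planted.expected_score_r!r}")
    if inference is not None:
        expected = manifest.candidates_by_threshold.get(3, frozenset())
        found = set(inference.candidates)
        for uid in sorted(expected - found):
            mismatches.append(f"planted candidate not inferred: {uid}")
        for uid in sorted(found - expected):
            mismatches.append(f"unplanted candidate inferred: {uid}")
    return mismatches
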