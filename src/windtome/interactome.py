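"""Assembly of the weighted interactome and its summary statistics.

Beyond the container itself this module computes the pairwise source-overlap
matrix (for drugs, targets and pairs the proportion of the *smaller* source
covered by the intersection) and joins ATC / protein-class annotations onto
the assembled drugs and targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import AbstractSet, Iterable, Mapping

import pandas as pd

from .exchange_io import MappingTables
from .normalize import DrugRecord, ResolvedAssociation, build_drug_registry
from .scoring import WeightedAssociation

ENTITY_KINDS = ("drug", "target", "pair")


@dataclass(frozen=True)
class OverlapCell:
    """Overlap of one entity kind between two sources.

    ``proportion`` is the intersection divided by the smaller of the two
    source counts, i.e. the coverage of the smaller source; it is symmetric
    in the two sources and lies in [0, 1].
    """

    entity_kind: str
    source_a: str
    source_b: str
    count_a: int
    count_b: int
    intersection: int

    def __post_init__(self) -> None:
        if self.entity_kind not in ENTITY_KINDS:
            raise ValueError(f"unknown entity kind {self.entity_kind!r}")
        if self.intersection > min(self.count_a, self.count_b):
            raise ValueError("intersection cannot exceed the smaller source")

    @property
    def proportion(self) -> float:
        smaller = min(self.count_a, self.count_b)
        return self.intersection / smaller if smaller else 0.0

    @property
    def proportion_rounded(self) -> float:
        """Proportion at reporting precision (3 decimals)."""
        return round(self.proportion, 3)


def pairwise_overlap(
    per_source_sets: Mapping[str, AbstractSet], entity_kind: str
) -> list[OverlapCell]:
    """All unordered source-pair overlap cells (diagonal included)."""
    names = sorted(per_source_sets)
    cells = []
    for i, a in enumerate(names):
        for b in names[i:]:
            cells.append(OverlapCell(
                entity_kind=entity_kind, source_a=a, source_b=b,
                count_a=len(per_source_sets[a]),
                count_b=len(per_source_sets[b]),
                intersection=len(per_source_sets[a] & per_source_sets[b]),
            ))
    return cells


def source_entity_sets(
    assocs: Iterable[ResolvedAssociation],
) -> dict[str, dict[str, set]]:
    """Per-source sets of drugs, targets and pairs, after normalization."""
    sets: dict[str, dict[str, set]] = {k: {} for k in ENTITY_KINDS}
    for a in assocs:
        sets["drug"].setdefault(a.source, set()).add(a.drug.uid)
        sets["target"].setdefault(a.source, set()).add(a.target.gene_id)
        sets["pair"].setdefault(a.source, set()).add(
            (a.drug.uid, a.target.gene_id))
    return sets


def overlap_table(assocs: Iterable[ResolvedAssociation]) -> pd.DataFrame:
    """Source-overlap matrix as a flat table over all kinds and source pairs."""
    sets = source_entity_sets(list(assocs))
    rows = []
    for kind in ENTITY_KINDS:
        for cell in pairwise_overlap(sets[kind], kind):
            rows.append({
                "entity_kind": kind,
                "source_a": cell.source_a, "source_b": cell.source_b,
                "count_a": cell.count_a, "count_b": cell.count_b,
                "intersection": cell.intersection,
                "proportion": cell.proportion_rounded,
            })
    return pd.DataFrame(rows)


@dataclass
class Interactome:
    """The assembled weighted drug-target interactome."""

    associations: dict[tuple[str, str], WeightedAssociation]
    drugs: dict[str, DrugRecord] = field(default_factory=dict)
    target_classes: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.associations)

    @property
    def n_drugs(self) -> int:
        return len({uid for uid, _ in self.associations})

    @property
    def n_targets(self) -> int:
        return len({gene for _, gene in self.associations})

    def pairs_for_targets(
        self, genes: AbstractSet[str], min_score_s: int = 1
    ) -> list[WeightedAssociation]:
        return [a for a in self.associations.values()
                if a.gene_id in genes and a.score_s >= min_score_s]


def assemble(
    scored: Iterable[WeightedAssociation],
    drug_registry: Mapping[str, DrugRecord] | None = None,
) -> Interactome:
    """Build the interactome container from scored pairs (keys must be unique)."""
    associations: dict[tuple[str, str], WeightedAssociation] = {}
    for a in scored:
        key = (a.drug_uid, a.gene_id)
        if key in associations:
            raise AssertionError(f"duplicate pair {key}: scoring must deduplicate")
        associations[key] = a
    return Interactome(associations=associations,
                       drugs=dict(drug_registry or {}))


@dataclass
class AnnotationSummary:
    drugs_single_atc: int
    drugs_multi_atc: int
    drugs_unclassified: int
    targets_single_class: int
    targets_multi_class: int
    targets_unclassified: int


def annotate(inter: Interactome, maps: MappingTables) -> AnnotationSummary:
    """Join ATC codes onto drugs and level-2 protein classes onto targets.

    Unmapped entities stay unclassified and are counted; classified entities
    are bucketed into "exactly one" vs "multiple" labels.
    """
    from dataclasses import replace

    for uid in sorted({u for u, _ in inter.associations}):
        drug = inter.drugs.get(uid) or DrugRecord(uid=uid, display_name=uid)
        codes: set[str] = set()
        for key in (uid, uid.split(":", 1)[-1], drug.display_name):
            codes |= maps.atc_map.get(key, set())
        inter.drugs[uid] = replace(drug, atc_codes=frozenset(codes))
    inter.target_classes = {
        gene: frozenset(maps.protein_class_map.get(gene, set()))
        for gene in sorted({g for _, g in inter.associations})
    }
    n_atc = [len(d.atc_codes) for d in inter.drugs.values()]
    n_cls = [len(c) for c in inter.target_classes.values()]
    return AnnotationSummary(
        drugs_single_atc=sum(1 for n in n_atc if n == 1),
        drugs_multi_atc=sum(1 for n in n_atc if n > 1),
        drugs_unclassified=sum(1 for n in n_atc if n == 0),
        targets_single_class=sum(1 for n in n_cls if n == 1),
        targets_multi_class=sum(1 for n in n_cls if n > 1),
        targets_unclassified=sum(1 for n in n_cls if n == 0),
    )


def build_interactome(
    assocs: Iterable[ResolvedAssociation], maps: MappingTables | None = None
) -> Interactome:
    """Convenience path: score resolved associations and assemble."""
    from .scoring import score_pairs

    assocs = list(assocs)
    registry = build_drug_registry(assocs, maps)
    inter = assemble(score_pairs(assocs), registry)
    if maps is not None:
        annotate(inter, maps)
    return inter
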