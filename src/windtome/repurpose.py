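"""Two-route network-based inference of repurposing candidates.

Starting from the drugs already approved for a disease and their known
targets, two candidate groups are formed from high-confidence interactome
associations (source concordance score_s at or above a threshold, default 3):

* **shared-target** — drugs outside the known set that hit a known drug
  target directly;
* **ppi-neighbor** — drugs whose targets are disease genes encoding proteins
  that directly interact (one hop in the PPI network) with a known drug
  target.  Proteins that are themselves known targets are excluded, so the
  two routes anchor on disjoint protein sets.

A drug found by both routes keeps both labels; per drug the best supporting
association is chosen by (score_s, score_r) lexicographic maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .interactome import Interactome
from .scoring import WeightedAssociation

logger = logging.getLogger(__name__)

ROUTE_SHARED_TARGET = "shared-target"
ROUTE_PPI_NEIGHBOR = "ppi-neighbor"

DEFAULT_MIN_SCORE_S = 3


@dataclass(frozen=True)
class DiseaseInputs:
    """Known drugs for the disease, their targets, and disease genes."""

    known_drugs: frozenset[str]
    known_targets: frozenset[str]
    disease_genes: frozenset[str] = frozenset()


@dataclass(frozen=True)
class RepurposingCandidate:
    drug_uid: str
    routes: frozenset[str]
    anchor_targets: frozenset[str]
    best_score_s: int
    best_score_r: float


@dataclass
class InferenceResult:
    candidates: dict[str, RepurposingCandidate]
    summary: dict[str, int] = field(default_factory=dict)

    @property
    def drug_uids(self) -> set[str]:
        return set(self.candidates)


def _candidates_from_anchors(
    inter: Interactome,
    anchors: frozenset[str],
    known_drugs: frozenset[str],
    route: str,
    min_score_s: int,
) -> dict[str, RepurposingCandidate]:
    by_drug: dict[str, list[WeightedAssociation]] = {}
    for assoc in inter.pairs_for_targets(anchors, min_score_s):
        if assoc.drug_uid in known_drugs:
            continue
        by_drug.setdefault(assoc.drug_uid, []).append(assoc)
    out = {}
    for uid, assocs in by_drug.items():
        best = max(assocs, key=lambda a: (a.score_s, a.score_r))
        out[uid] = RepurposingCandidate(
            drug_uid=uid,
            routes=frozenset({route}),
            anchor_targets=frozenset(a.gene_id for a in assocs),
            best_score_s=best.score_s,
            best_score_r=best.score_r,
        )
    return out


def shared_target_candidates(
    inter: Interactome,
    disease: DiseaseInputs,
    min_score_s: int = DEFAULT_MIN_SCORE_S,
) -> dict[str, RepurposingCandidate]:
    """Route 1: non-disease drugs hitting a known drug target at threshold."""
    if min_score_s < 1:
        raise ValueError("min_score_s must be >= 1")
    present = {a.gene_id for a in inter.pairs_for_targets(
        disease.known_targets, min_score_s)}
    if not present:
        logger.warning(
            "none of the %d known targets has an association at score_s >= %d",
            len(disease.known_targets), min_score_s)
        return {}
    return _candidates_from_anchors(
        inter, disease.known_targets, disease.known_drugs,
        ROUTE_SHARED_TARGET, min_score_s)


def disease_related_proteins(
    disease: DiseaseInputs, ppi: nx.Graph
) -> frozenset[str]:
    """Disease genes whose proteins directly interact with a known target.

    Known targets themselves are excluded so the route-2 anchor set is
    disjoint from the route-1 anchors.
    """
    neighbors: set[str] = set()
    for target in disease.known_targets:
        if ppi.has_node(target):
            neighbors.update(ppi.neighbors(target))
    return frozenset((neighbors & disease.disease_genes)
                     - disease.known_targets)


def ppi_neighbor_candidates(
    inter: Interactome,
    disease: DiseaseInputs,
    ppi: nx.Graph,
    min_score_s: int = DEFAULT_MIN_SCORE_S,
) -> dict[str, RepurposingCandidate]:
    """Route 2: non-disease drugs targeting disease genes one PPI hop away."""
    if min_score_s < 1:
        raise ValueError("min_score_s must be >= 1")
    anchors = disease_related_proteins(disease, ppi)
    if not anchors:
        n_neigh = len({n for t in disease.known_targets if ppi.has_node(t)
                       for n in ppi.neighbors(t)})
        logger.warning(
            "no disease-related proteins: %d PPI neighbors of known targets, "
            "%d disease genes, empty intersection",
            n_neigh, len(disease.disease_genes))
        return {}
    return _candidates_from_anchors(
        inter, anchors, disease.known_drugs, ROUTE_PPI_NEIGHBOR, min_score_s)


def infer(
    inter: Interactome,
    disease: DiseaseInputs,
    ppi: nx.Graph,
    min_score_s: int = DEFAULT_MIN_SCORE_S,
) -> InferenceResult:
    """Union of both routes with per-drug route provenance and run summary."""
    route1 = shared_target_candidates(inter, disease, min_score_s)
    route2 = ppi_neighbor_candidates(inter, disease, ppi, min_score_s)
    merged: dict[str, RepurposingCandidate] = dict(route1)
    for uid, cand in route2.items():
        if uid in merged:
            prev = merged[uid]
            merged[uid] = RepurposingCandidate(
                drug_uid=uid,
                routes=prev.routes | cand.routes,
                anchor_targets=prev.anchor_targets | cand.anchor_targets,
                best_score_s=max(
                    (prev.best_score_s, prev.best_score_r),
                    (cand.best_score_s, cand.best_score_r))[0],
                best_score_r=max(
                    (prev.best_score_s, prev.best_score_r),
                    (cand.best_score_s, cand.best_score_r))[1],
            )
        else:
            merged[uid] = cand
    anchors = set().union(*(c.anchor_targets for c in merged.values())) \
        if merged else set()
    summary = {
        "n_route1": len(route1),
        "n_route2": len(route2),
        "n_unique_drugs": len(merged),
        "n_unique_anchor_proteins": len(anchors),
    }
    return InferenceResult(candidates=merged, summary=summary)


def candidate_uids(candidates: Iterable[RepurposingCandidate] | dict) -> set[str]:
    if isinstance(candidates, dict):
        return set(candidates)
    return {c.drug_uid for c in candidates}
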