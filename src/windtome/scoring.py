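"""Reliability scores for normalized drug-target associations.

Two complementary scores are attached to every unique (drug UID, gene ID)
pair:

* **Score_S** — source concordance: the number of distinct source databases
  asserting the pair (duplicates within one source count once).  With six
  configured sources it ranges 1..6.

* **Score_R** — reference specificity: for a pair *x* supported by PubMed
  references r_1..r_n,

      Score_R(x) = sum_i  d_i * t_i / f_i**2

  where f_i is the number of distinct normalized pairs reference r_i
  supports anywhere in the dataset, and d_i, t_i are the distinct drugs and
  targets among those pairs.  A focused study supporting a single pair
  contributes 1; a high-throughput screen reporting k drugs against one
  target contributes k/k**2 = 1/k per pair, so broad screens are
  down-weighted while additional references always add score.

Pairs with no references keep Score_S but get Score_R = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import DrugRecord, ResolvedAssociation


@dataclass(frozen=True)
class ReferenceProfile:
    """Dataset-wide support profile of one PubMed reference."""

    pmid: str
    f: int  # distinct (drug, gene) pairs this reference supports
    d: int  # distinct drugs among them
    t: int  # distinct targets among them

    def __post_init__(self) -> None:
        if self.f < 1 or self.d < 1 or self.t < 1:
            raise ValueError("reference profile counts must be >= 1")
        if self.d * self.t < self.f:
            # every supported pair pairs one of the d drugs with one of the t
            # targets, so the d x t grid must cover all f pairs
            raise ValueError(f"inconsistent profile for {self.pmid}: "
                             f"d*t={self.d * self.t} < f={self.f}")

    @property
    def specificity(self) -> float:
        return (self.d * self.t) / (self.f * self.f)


@dataclass(frozen=True)
class WeightedAssociation:
    """A unique normalized drug-target pair with its reliability scores."""

    drug_uid: str
    gene_id: str
    sources: frozenset[str]
    references: frozenset[str]
    score_s: int
    score_r: float

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("a scored pair must have at least one source")
        if self.score_s != len(self.sources):
            raise ValueError("score_s must equal the number of distinct sources")


def compute_reference_profiles(
    assocs: Iterable[ResolvedAssociation],
) -> dict[str, ReferenceProfile]:
    """Profile every reference over the normalized dataset.

    Support is counted on distinct (drug UID, gene ID) pairs, pooled across
    sources — a reference cited for the same pair by two sources counts that
    pair once.
    """
    pairs_by_pmid: dict[str, set[tuple[str, str]]] = {}
    for assoc in assocs:
        pair = (assoc.drug.uid, assoc.target.gene_id)
        for pmid in assoc.references:
            pairs_by_pmid.setdefault(pmid, set()).add(pair)
    profiles = {}
    for pmid, pairs in pairs_by_pmid.items():
        profiles[pmid] = ReferenceProfile(
            pmid=pmid,
            f=len(pairs),
            d=len({p[0] for p in pairs}),
            t=len({p[1] for p in pairs}),
        )
    return profiles


def score_pairs(
    assocs: Iterable[ResolvedAssociation],
    profiles: Mapping[str, ReferenceProfile] | None = None,
) -> list[WeightedAssociation]:
    """Collapse resolved assertions to unique scored pairs.

    ``profiles`` must have been computed over the same dataset; if omitted it
    is computed here.
    """
    assocs = list(assocs)
    if profiles is None:
        profiles = compute_reference_profiles(assocs)
    grouped: dict[tuple[str, str], tuple[set[str], set[str]]] = {}
    for assoc in assocs:
        key = (assoc.drug.uid, assoc.target.gene_id)
        sources, refs = grouped.setdefault(key, (set(), set()))
        sources.add(assoc.source)
        refs.update(assoc.references)
    out = []
    for (uid, gene), (sources, refs) in sorted(grouped.items()):
        score_r = sum(profiles[p].specificity for p in refs)
        out.append(WeightedAssociation(
            drug_uid=uid, gene_id=gene,
            sources=frozenset(sources), references=frozenset(refs),
            score_s=len(sources), score_r=score_r,
        ))
    return out


def _atc_uids(
    assocs: list[WeightedAssociation],
    registry: Mapping[str, DrugRecord] | None,
    atc_map: Mapping[str, set] | None,
) -> set[str] | None:
    """UIDs of drugs carrying at least one ATC code, or None for no filter."""
    if registry is None and atc_map is None:
        return None
    uids = set()
    for a in assocs:
        if registry is not None and registry.get(a.drug_uid) is not None \
                and registry[a.drug_uid].atc_codes:
            uids.add(a.drug_uid)
        elif atc_map is not None:
            bare = a.drug_uid.split(":", 1)[-1]
            if atc_map.get(a.drug_uid) or atc_map.get(bare):
                uids.add(a.drug_uid)
    return uids


def stratify_by_threshold(
    assocs: Iterable[WeightedAssociation],
    registry: Mapping[str, DrugRecord] | None = None,
    atc_map: Mapping[str, set] | None = None,
) -> pd.DataFrame:
    """Entity counts and mean Score_R per Score_S threshold stratum.

    Row θ counts drugs, targets and pairs among associations with
    score_s ≥ θ, for θ = 1..max observed.  Supplying a drug registry or an
    ATC map restricts the table to pairs whose drug carries at least one ATC
    code.  ``sem_score_r`` is the standard error of the mean.
    """
    assocs = list(assocs)
    atc = _atc_uids(assocs, registry, atc_map)
    if atc is not None:
        assocs = [a for a in assocs if a.drug_uid in atc]
    max_s = max((a.score_s for a in assocs), default=0)
    rows = []
    for theta in range(1, max_s + 1):
        stratum = [a for a in assocs if a.score_s >= theta]
        rs = np.array([a.score_r for a in stratum])
        rows.append({
            "threshold": theta,
            "n_drugs": len({a.drug_uid for a in stratum}),
            "n_targets": len({a.gene_id for a in stratum}),
            "n_pairs": len(stratum),
            "mean_score_r": float(rs.mean()) if len(rs) else float("nan"),
            "sem_score_r": float(rs.std(ddof=1) / np.sqrt(len(rs)))
            if len(rs) > 1 else float("nan"),
        })
    return pd.DataFrame(rows, columns=["threshold", "n_drugs", "n_targets",
                                       "n_pairs", "mean_score_r", "sem_score_r"])


class ConstantScoreError(ValueError):
    """Correlation is undefined when either score vector is constant."""


def score_correlation(
    assocs: Iterable[WeightedAssociation],
    registry: Mapping[str, DrugRecord] | None = None,
    atc_map: Mapping[str, set] | None = None,
) -> float:
    """Pearson correlation between Score_S and Score_R over pairs."""
    assocs = list(assocs)
    atc = _atc_uids(assocs, registry, atc_map)
    if atc is not None:
        assocs = [a for a in assocs if a.drug_uid in atc]
    if len(assocs) < 2:
        raise ConstantScoreError("need at least two pairs for a correlation")
    s = np.array([a.score_s for a in assocs], dtype=float)
    r = np.array([a.score_r for a in assocs], dtype=float)
    if np.ptp(s) == 0 or np.ptp(r) == 0:
        raise ConstantScoreError("score vector is constant; correlation undefined")
    return float(stats.pearsonr(s, r).statistic)
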