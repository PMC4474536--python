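"""Clinical-trial enrichment evaluation of repurposing candidates.

The evaluation metric is the trial hit rate: the fraction of inferred
candidates with at least one registered clinical trial for the condition of
interest (and, separately, for a configurable related condition class).
Percentages are reported to one decimal.  Candidates are joined to the trial
table by UID when available, otherwise by case-folded drug name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .exchange_io import TrialLabelTable
from .interactome import Interactome
from .normalize import DrugRecord
from .repurpose import DiseaseInputs, RepurposingCandidate, infer

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HitRate:
    hits: int
    total: int

    @property
    def pct(self) -> float | None:
        """Percentage at reporting precision (1 decimal); None when empty."""
        if self.total == 0:
            return None
        return round(100.0 * self.hits / self.total, 1)


@dataclass(frozen=True)
class EvaluationRow:
    label: str
    n_candidates: int
    n_hits_primary: int
    n_hits_class: int

    @property
    def pct_primary(self) -> float | None:
        return HitRate(self.n_hits_primary, self.n_candidates).pct

    @property
    def pct_class(self) -> float | None:
        return HitRate(self.n_hits_class, self.n_candidates).pct


def _identifiers(
    candidate, registry: Mapping[str, DrugRecord] | None
) -> list[str]:
    """Join keys for one candidate: UID first, then display name."""
    if isinstance(candidate, RepurposingCandidate):
        uid = candidate.drug_uid
    else:
        uid = str(candidate)
    idents = [uid]
    if registry is not None and uid in registry:
        idents.append(registry[uid].display_name)
    # a name-based UID is also matchable by its bare name
    if ":" in uid:
        idents.append(uid.split(":", 1)[1])
    return idents


def trial_hit_rate(
    candidates: Iterable,
    trials: TrialLabelTable,
    condition: str,
    registry: Mapping[str, DrugRecord] | None = None,
) -> HitRate:
    """Hit rate of *candidates* for one condition token.

    A candidate is a hit iff it has at least one trial row for the
    condition.  An empty candidate set gives (0, 0) with undefined pct.
    """
    candidates = list(candidates)
    if not candidates:
        logger.warning("empty candidate set: hit rate undefined")
        return HitRate(0, 0)
    hits = sum(1 for c in candidates
               if trials.has_trial(_identifiers(c, registry), condition))
    return HitRate(hits, len(candidates))


def sum_trials(
    candidates: Iterable,
    trials: TrialLabelTable,
    condition: str,
    registry: Mapping[str, DrugRecord] | None = None,
) -> int:
    """Total trial count for the condition, summed over hit candidates.

    Note this sums the per-drug counts; a trial investigating several
    candidate drugs contributes once per drug.
    """
    return sum(trials.count(_identifiers(c, registry), condition)
               for c in candidates)


def evaluate_candidates(
    label: str,
    candidates: Iterable,
    trials: TrialLabelTable,
    primary_condition: str,
    class_condition: str,
    registry: Mapping[str, DrugRecord] | None = None,
) -> EvaluationRow:
    candidates = list(candidates)
    primary = trial_hit_rate(candidates, trials, primary_condition, registry)
    related = trial_hit_rate(candidates, trials, class_condition, registry)
    if not candidates:
        logger.warning("configuration %r produced zero candidates", label)
    return EvaluationRow(
        label=label,
        n_candidates=len(candidates),
        n_hits_primary=primary.hits,
        n_hits_class=related.hits,
    )


def compare_configurations(
    configs: Sequence[tuple[str, Interactome, int]],
    disease: DiseaseInputs,
    ppi: nx.Graph,
    trials: TrialLabelTable,
    primary_condition: str,
    class_condition: str,
) -> list[EvaluationRow]:
    """Run the inference under each configuration and tabulate hit rates.

    Each config is ``(label, interactome, min_score_s)``; a single-source or
    external interactome is simply passed with threshold 1.  Duplicate labels
    are an error.
    """
    labels = [label for label, _, _ in configs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate configuration labels")
    rows = []
    for label, inter, min_score_s in configs:
        result = infer(inter, disease, ppi, min_score_s)
        rows.append(evaluate_candidates(
            label, result.candidates.values(), trials,
            primary_condition, class_condition, registry=inter.drugs))
    return rows
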