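"""Published reference tables distributed with the package.

Three small curated tables support worked examples and regression checks:

* ``source_overlap_counts.tsv`` — per-source entity counts and pairwise
  intersections for the six integrated drug-target databases, with the
  overlap proportions at 3-decimal reporting precision.
* ``scz_trial_drugs.tsv`` — the 39 inferred schizophrenia candidates that
  reached clinical trials, with indication, ATC codes and per-drug
  schizophrenia-trial counts.
* ``evaluation_counts.tsv`` — candidate and hit counts for each evaluated
  configuration (integrated interactome at three thresholds, six single
  sources, one external resource), with hit-rate percentages at 1 decimal.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .exchange_io import TrialLabelTable
from .interactome import OverlapCell


def _load(name: str) -> pd.DataFrame:
    with resources.files("windtome.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def load_source_overlap_counts() -> pd.DataFrame:
    return _load("source_overlap_counts.tsv")


def source_overlap_cells() -> list[tuple[OverlapCell, float]]:
    """Overlap cells built from the published counts, paired with the
    published proportion for each."""
    out = []
    for row in load_source_overlap_counts().itertuples(index=False):
        cell = OverlapCell(
            entity_kind=row.entity_kind,
            source_a=row.source_a, source_b=row.source_b,
            count_a=int(row.count_a), count_b=int(row.count_b),
            intersection=int(row.intersection),
        )
        out.append((cell, float(row.proportion)))
    return out


def load_scz_trial_drugs() -> pd.DataFrame:
    df = _load("scz_trial_drugs.tsv")
    df["n_scz_trials"] = df["n_scz_trials"].astype(int)
    return df


def scz_trial_table(condition: str = "schizophrenia") -> TrialLabelTable:
    """The per-drug schizophrenia-trial counts as a trial-label table."""
    table = TrialLabelTable()
    for row in load_scz_trial_drugs().itertuples(index=False):
        table.add(row.drug, condition, int(row.n_scz_trials))
    return table


def load_evaluation_counts() -> pd.DataFrame:
    df = _load("evaluation_counts.tsv")
    for col in ("n_candidates", "n_hits_primary", "n_hits_class"):
        df[col] = df[col].astype(int)
    return df
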