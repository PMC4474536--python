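"""End-to-end orchestration: read a dataset directory, build the weighted
interactome, and run the network inference.

A dataset directory follows the layout the generator emits: an
``associations.tsv`` exchange table, the mapping tables, ``ppi.tsv``,
``trials.tsv`` and the three disease input lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from . import exchange_io, normalize, scoring
from .exchange_io import MappingTables, TrialLabelTable
from .interactome import Interactome, annotate, assemble
from .normalize import NormalizationResult
from .repurpose import DiseaseInputs, InferenceResult, infer
from .scoring import WeightedAssociation


def read_id_list(path: str | Path) -> frozenset[str]:
    """One identifier per line; blank lines and ``#`` comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return frozenset(out)


@dataclass
class PipelineResult:
    maps: MappingTables
    normalization: NormalizationResult
    weighted: list[WeightedAssociation]
    interactome: Interactome
    ppi: nx.Graph | None = None
    disease: DiseaseInputs | None = None
    trials: TrialLabelTable | None = None
    inference: InferenceResult | None = None
    read_rejects: list = field(default_factory=list)


def run_pipeline(datadir: str | Path, min_score_s: int = 3) -> PipelineResult:
    """Run normalization, scoring, assembly and (when the disease inputs are
    present) the two-route inference over one dataset directory."""
    datadir = Path(datadir)
    records, read_rejects = exchange_io.read_associations(
        datadir / "associations.tsv")

    def opt(name: str) -> Path | None:
        p = datadir / name
        return p if p.exists() else None

    maps = exchange_io.read_mappings(
        synonyms=opt("synonyms.tsv"), uniprot=opt("uniprot.tsv"),
        gene_info=opt("gene_info.tsv"), atc=opt("atc.tsv"),
        protein_class=opt("classes.tsv"))
    norm = normalize.normalize_associations(records, maps)
    profiles = scoring.compute_reference_profiles(norm.kept)
    weighted = scoring.score_pairs(norm.kept, profiles)
    registry = normalize.build_drug_registry(norm.kept, maps)
    inter = assemble(weighted, registry)
    annotate(inter, maps)

    result = PipelineResult(
        maps=maps, normalization=norm, weighted=weighted,
        interactome=inter, read_rejects=read_rejects)

    if opt("ppi.tsv"):
        result.ppi = exchange_io.read_ppi(datadir / "ppi.tsv")
    if opt("trials.tsv"):
        result.trials = exchange_io.read_trials(datadir / "trials.tsv")
    if all(opt(n) for n in ("known_drugs.txt", "known_targets.txt",
                            "disease_genes.txt")):
        result.disease = DiseaseInputs(
            known_drugs=read_id_list(datadir / "known_drugs.txt"),
            known_targets=read_id_list(datadir / "known_targets.txt"),
            disease_genes=read_id_list(datadir / "disease_genes.txt"))
        if result.ppi is not None:
            result.inference = infer(inter, result.disease, result.ppi,
                                     min_score_s)
    return result


def single_source_interactome(
    result: PipelineResult, source: str
) -> Interactome:
    """Interactome rebuilt from one source's assertions alone.

    Every pair then has score_s = 1, so threshold 1 is the only meaningful
    cutoff for such a configuration.
    """
    kept = [a for a in result.normalization.kept if a.source == source]
    registry = normalize.build_drug_registry(kept, result.maps)
    return assemble(scoring.score_pairs(kept), registry)
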