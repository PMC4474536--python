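import pytest

from windtome import GeneratorConfig, generate, run_pipeline
from windtome.normalize import DrugRecord, ResolvedAssociation, TargetRecord
from windtome.scoring import WeightedAssociation


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """One generated dataset directory plus its manifest, shared read-only."""
    outdir = tmp_path_factory.mktemp("simdata")
    manifest = generate(GeneratorConfig(seed=11), outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def default_result(default_dataset):
    outdir, _ = default_dataset
    return run_pipeline(outdir)


def resolved(drug: str, gene: str, source: str, pmids=()) -> ResolvedAssociation:
    """Shorthand for a resolved association in toy tests."""
    return ResolvedAssociation(
        drug=DrugRecord(uid=drug, display_name=drug),
        target=TargetRecord(gene_id=gene, symbol=gene.upper(), taxon=9606),
        source=source,
        references=frozenset(pmids),
    )


def weighted(drug: str, gene: str, score_s: int, score_r: float = 0.0,
             sources=None) -> WeightedAssociation:
    """Shorthand for a scored pair with a consistent source set."""
    srcs = frozenset(sources) if sources else \
        frozenset(f"src{i + 1}" for i in range(score_s))
    return WeightedAssociation(
        drug_uid=drug, gene_id=gene, sources=srcs,
        references=frozenset(), score_s=len(srcs), score_r=score_r)
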