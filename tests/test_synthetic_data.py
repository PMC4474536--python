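import dataclasses
from collections import Counter

import pytest

from windtome import run_pipeline
from windtome.synthetic_data import (
    GeneratorConfig,
    build_dataset,
    generate,
    validate_against_manifest,
)


def small_config(**overrides):
    base = dict(seed=5, n_drugs=40, n_targets=12,
                multiplicity_counts={1: 20, 2: 10, 3: 6},
                ppi_background_edges=20)
    base.update(overrides)
    return GeneratorConfig(**base)


class TestGeneratorConfig:
    def test_rate_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(synonym_noise_rate=1.5).validate()

    def test_multiplicity_beyond_sources_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_sources=3,
                            multiplicity_counts={4: 1}).validate()

    def test_overfull_grid_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_drugs=2, n_targets=2,
                            multiplicity_counts={1: 100}).validate()


class TestDeterminism:
    def test_same_seed_gives_byte_identical_trees(self, tmp_path):
        generate(GeneratorConfig(seed=7), tmp_path / "a")
        generate(GeneratorConfig(seed=7), tmp_path / "b")
        names = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert names == sorted(p.name for p in (tmp_path / "b").iterdir())
        for name in names:
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        generate(small_config(seed=1), tmp_path / "a")
        generate(small_config(seed=2), tmp_path / "b")
        assert (tmp_path / "a" / "associations.tsv").read_bytes() != \
            (tmp_path / "b" / "associations.tsv").read_bytes()


class TestPlantedStructure:
    def test_score_s_distribution_equals_planted_multiplicities(
            self, default_dataset, default_result):
        _, manifest = default_dataset
        empirical = Counter(a.score_s for a in default_result.weighted)
        assert dict(empirical) == manifest.multiplicity_histogram()

    def test_all_six_multiplicity_config(self, tmp_path):
        cfg = small_config(multiplicity_counts={6: 15})
        generate(cfg, tmp_path)
        result = run_pipeline(tmp_path)
        grid = [a for a in result.weighted if a.drug_uid.startswith("CID:C0")
                or a.drug_uid.startswith("NAME:drug")]
        assert grid and all(a.score_s == 6 for a in grid)

    def test_zero_noise_all_cid_means_trivial_normalization(self, tmp_path):
        cfg = small_config(synonym_noise_rate=0.0, no_cid_rate=0.0)
        manifest = generate(cfg, tmp_path)
        grid_uids = {p.drug_uid for p in manifest.pairs.values()
                     if p.drug_uid != "NAME:expansiondrug"}
        assert all(uid.startswith("CID:") for uid in grid_uids)
        result = run_pipeline(tmp_path)
        assert validate_against_manifest(
            result.interactome, result.inference, manifest) == []

    def test_score_r_separation_specific_vs_hts(self, default_dataset,
                                                default_result):
        _, manifest = default_dataset
        scored = default_result.interactome.associations
        spec = [scored[k].score_r for k, p in manifest.pairs.items()
                if p.ref_class == "specific" and len(scored[k].references) == 1]
        hts = [scored[k].score_r for k, p in manifest.pairs.items()
               if p.ref_class == "hts"]
        assert spec and hts
        assert min(spec) > max(hts)

    def test_purge_and_reject_counts_match_manifest(
            self, default_dataset, default_result):
        _, manifest = default_dataset
        purged = Counter(p.rule for p in default_result.normalization.purged)
        assert dict(purged) == manifest.purge_counts
        assert len(default_result.normalization.unresolved_targets) == \
            manifest.n_unresolved


class TestValidateAgainstManifest:
    def test_clean_run_has_no_mismatches(self, default_dataset,
                                         default_result):
        _, manifest = default_dataset
        assert validate_against_manifest(
            default_result.interactome, default_result.inference,
            manifest) == []

    def test_edited_multiplicity_detected_as_exactly_one_mismatch(
            self, default_dataset, default_result):
        _, manifest = default_dataset
        key = next(iter(sorted(manifest.pairs)))
        edited = dict(manifest.pairs)
        edited[key] = dataclasses.replace(
            edited[key], multiplicity=edited[key].multiplicity + 1)
        broken = dataclasses.replace(manifest, pairs=edited)
        mismatches = validate_against_manifest(
            default_result.interactome, default_result.inference, broken)
        assert len(mismatches) == 1 and "score_s" in mismatches[0]

    def test_shuffled_input_rows_still_validate(self, default_dataset):
        outdir, manifest = default_dataset
        import random

        from windtome import exchange_io, normalize, scoring
        from windtome.interactome import assemble

        records, _ = exchange_io.read_associations(outdir / "associations.tsv")
        random.Random(3).shuffle(records)
        maps = exchange_io.read_mappings(
            synonyms=outdir / "synonyms.tsv", uniprot=outdir / "uniprot.tsv",
            gene_info=outdir / "gene_info.tsv")
        norm = normalize.normalize_associations(records, maps)
        inter = assemble(scoring.score_pairs(norm.kept))
        assert validate_against_manifest(inter, None, manifest) == []
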