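import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import resolved, weighted
from oracles import brute_force_scores, random_instance
from windtome.normalize import DrugRecord, ResolvedAssociation, TargetRecord
from windtome.scoring import (
    ConstantScoreError,
    ReferenceProfile,
    compute_reference_profiles,
    score_correlation,
    score_pairs,
    stratify_by_threshold,
)


def from_raws(raws):
    """Raw (drug, gene, source, pmids) tuples -> resolved associations."""
    return [
        ResolvedAssociation(
            drug=DrugRecord(uid=d, display_name=d),
            target=TargetRecord(gene_id=g, symbol=g, taxon=9606),
            source=s, references=frozenset(pm))
        for d, g, s, pm in raws
    ]


class TestReferenceProfiles:
    def test_minimal_reference_has_unit_specificity(self):
        profiles = compute_reference_profiles(
            [resolved("d1", "t1", "src1", ["p1"])])
        assert profiles["p1"] == ReferenceProfile("p1", f=1, d=1, t=1)
        assert profiles["p1"].specificity == 1.0

    def test_hts_screen_100_drugs_one_target(self):
        assocs = [resolved(f"d{i}", "t1", "src1", ["p1"]) for i in range(100)]
        prof = compute_reference_profiles(assocs)["p1"]
        assert (prof.f, prof.d, prof.t) == (100, 100, 1)
        assert prof.specificity == pytest.approx(0.01)

    def test_mixed_reference_counts_distinct_entities(self):
        assocs = [resolved(d, t, "src1", ["p1"])
                  for d, t in [("d1", "t1"), ("d1", "t2"), ("d2", "t1")]]
        prof = compute_reference_profiles(assocs)["p1"]
        assert (prof.f, prof.d, prof.t) == (3, 2, 2)
        assert prof.specificity == pytest.approx(4 / 9)

    def test_pooled_across_sources(self):
        # the same pair cited by two sources counts once in f
        assocs = [resolved("d1", "t1", "src1", ["p1"]),
                  resolved("d1", "t1", "src2", ["p1"])]
        assert compute_reference_profiles(assocs)["p1"].f == 1

    def test_inconsistent_profile_rejected(self):
        with pytest.raises(ValueError):
            ReferenceProfile("p", f=5, d=2, t=2)


class TestScorePairs:
    def test_source_concordance_counts_distinct_sources(self):
        assocs = [resolved("d1", "t1", "src1"),
                  resolved("d1", "t1", "src1"),   # duplicate within a source
                  resolved("d1", "t1", "src2")]
        (pair,) = score_pairs(assocs)
        assert pair.score_s == 2

    def test_all_sources_give_max_score(self):
        assocs = [resolved("d1", "t1", f"src{i}") for i in range(1, 7)]
        assert score_pairs(assocs)[0].score_s == 6

    def test_two_minimal_references_sum_to_two(self):
        assocs = [resolved("d1", "t1", "src1", ["p1"]),
                  resolved("d1", "t1", "src2", ["p2"])]
        assert score_pairs(assocs)[0].score_r == pytest.approx(2.0)

    def test_no_references_gives_zero_score_r(self):
        (pair,) = score_pairs([resolved("d1", "t1", "src1")])
        assert pair.score_r == 0.0 and pair.references == frozenset()

    def test_additivity_of_reference_removal(self):
        with_both = from_raws([("d1", "t1", "src1", {"p1", "p2"}),
                               ("d2", "t1", "src1", {"p2"})])
        profiles = compute_reference_profiles(with_both)
        full = score_pairs(with_both, profiles)
        pair = next(p for p in full if p.drug_uid == "d1")
        without = from_raws([("d1", "t1", "src1", {"p2"}),
                             ("d2", "t1", "src1", {"p2"})])
        reduced = next(p for p in score_pairs(without)
                       if p.drug_uid == "d1")
        assert pair.score_r - reduced.score_r == \
            pytest.approx(profiles["p1"].specificity)

    @pytest.mark.parametrize("k", [2, 5, 20])
    def test_hts_reference_scores_below_minimal_reference(self, k):
        # same pmid count per pair; the HTS variant must score strictly lower
        minimal = score_pairs([resolved("d0", "t1", "src1", ["pm"])])[0]
        hts_assocs = [resolved(f"d{i}", "t1", "src1", ["ph"])
                      for i in range(k)]
        hts = next(p for p in score_pairs(hts_assocs) if p.drug_uid == "d0")
        assert hts.score_r < minimal.score_r

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_instances(self, seed):
        raws = random_instance(seed)
        expected = brute_force_scores(raws)
        got = {(p.drug_uid, p.gene_id): (p.score_s, p.score_r)
               for p in score_pairs(from_raws(raws))}
        assert got.keys() == expected.keys()
        for key in expected:
            assert got[key][0] == expected[key][0]
            assert got[key][1] == pytest.approx(expected[key][1], abs=1e-12)


class TestStratify:
    def test_counts_non_increasing_in_threshold(self, default_result):
        table = stratify_by_threshold(default_result.weighted)
        for col in ("n_drugs", "n_targets", "n_pairs"):
            assert (table[col].diff().dropna() <= 0).all()

    def test_single_pair_appears_in_all_strata_up_to_its_score(self):
        table = stratify_by_threshold([weighted("d1", "t1", 3, score_r=4.0)])
        assert list(table["threshold"]) == [1, 2, 3]
        assert (table["mean_score_r"] == 4.0).all()

    def test_atc_filter_restricts_to_annotated_drugs(self):
        assocs = [weighted("CID:C1", "t1", 2), weighted("CID:C2", "t2", 1)]
        table = stratify_by_threshold(assocs, atc_map={"C1": {"N05A"}})
        assert table.loc[0, "n_pairs"] == 1

    def test_mean_score_r_rises_with_threshold_on_synthetic_data(
            self, default_result):
        table = stratify_by_threshold(default_result.weighted)
        means = table["mean_score_r"].tolist()
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))


class TestCorrelation:
    def test_perfect_linearity(self):
        assocs = [weighted(f"d{s}", "t1", s, score_r=2.0 * s)
                  for s in (1, 2, 3)]
        assert score_correlation(assocs) == pytest.approx(1.0)

    def test_anti_monotone_vectors_negative(self):
        assocs = [weighted(f"d{s}", "t1", s, score_r=10.0 - s)
                  for s in (1, 2, 3)]
        assert score_correlation(assocs) < 0

    def test_constant_vector_raises(self):
        assocs = [weighted("d1", "t1", 2, 1.0), weighted("d2", "t1", 2, 2.0)]
        with pytest.raises(ConstantScoreError):
            score_correlation(assocs)

    def test_synthetic_defaults_positively_correlated(self, default_result):
        assert score_correlation(default_result.weighted) > 0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_scores_are_invariant_to_input_order(seed):
    raws = random_instance(seed, max_assocs=25)
    forward = {(p.drug_uid, p.gene_id): (p.score_s, p.score_r)
               for p in score_pairs(from_raws(raws))}
    backward = {(p.drug_uid, p.gene_id): (p.score_s, p.score_r)
                for p in score_pairs(from_raws(raws[::-1]))}
    assert forward.keys() == backward.keys()
    for key, (s, r) in forward.items():
        assert backward[key][0] == s
        assert backward[key][1] == pytest.approx(r, abs=1e-12)
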