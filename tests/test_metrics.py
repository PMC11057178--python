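"""Metric correctness: rank points, F-max sweep vs brute force, bootstrap, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import priobench as pb
from priobench.metrics import outcomes_from_band_counts

from conftest import brute_force_fmax, random_small_submission, vk


def outcomes_from_ranks(ranks):
    """ranks: iterable of int or None (miss)."""
    return [
        pb.MatchOutcome(f"p{i}", matched=r is not None, match_rank=r)
        for i, r in enumerate(ranks)
    ]


class TestMeanRankPoints:
    def test_points_schedule(self):
        assert [pb.rank_to_points(r) for r in (1, 3, 5, 6, 10, 12, 20, 21, 50, 51, 100)] == [
            100, 100, 100, 50, 50, 25, 25, 10, 10, 5, 5
        ]
        assert pb.rank_to_points(101) == 0 and pb.rank_to_points(None) == 0

    def test_invalid_rank_rejected(self):
        with pytest.raises(ValueError):
            pb.rank_to_points(0)

    def test_thirteen_hits_one_miss(self):
        # 13 of 14 in the top five, one missed entirely
        outs = outcomes_from_ranks([1] * 9 + [3] * 4 + [None])
        assert pb.mean_rank_points(outs) == pytest.approx(1300 / 14)
        assert round(pb.mean_rank_points(outs), 1) == 92.9

    def test_disjoint_band_occupancy(self):
        # 5 in top5, 1 in 6-10, 2 in 11-20, 4 in 21-50, 1 in 51-100, 1 miss
        outs = outcomes_from_ranks([2] * 5 + [7] + [15] * 2 + [30] * 4 + [70] + [None])
        assert pb.mean_rank_points(outs) == pytest.approx((500 + 50 + 50 + 40 + 5) / 14)

    def test_all_rank_one_is_maximum(self):
        assert pb.mean_rank_points(outcomes_from_ranks([1] * 14)) == 100.0

    def test_zero_entries_undefined(self):
        with pytest.raises(ValueError):
            pb.mean_rank_points([])

    @given(
        ranks=st.lists(st.integers(min_value=1, max_value=120), min_size=1, max_size=20),
        idx=st.integers(min_value=0, max_value=19),
        improvement=st.integers(min_value=0, max_value=60),
    )
    def test_monotone_in_rank(self, ranks, idx, improvement):
        """Decreasing any match rank never decreases the score."""
        idx %= len(ranks)
        before = pb.mean_rank_points(outcomes_from_ranks(ranks))
        improved = list(ranks)
        improved[idx] = max(1, improved[idx] - improvement)
        after = pb.mean_rank_points(outcomes_from_ranks(improved))
        assert after >= before


class TestBandCounts:
    def test_enumerated_example(self):
        outs = outcomes_from_ranks([1, 1, 7, 15, None])
        assert pb.rank_band_counts(outs) == (2, 2, 3, 4, 4, 4)

    def test_all_misses_and_all_hits(self):
        assert pb.rank_band_counts(outcomes_from_ranks([None] * 5)) == (0, 0, 0, 0, 0, 0)
        assert pb.rank_band_counts(outcomes_from_ranks([1] * 14)) == (14,) * 6

    def test_reconstruction_from_band_counts_is_consistent(self):
        counts = (6, 9, 11, 12, 12, 12)
        outs = outcomes_from_band_counts(counts, n_solved=14)
        assert pb.rank_band_counts(outs) == counts
        assert len(outs) == 14


class TestPrecisionRecallF:
    def test_perfect_model(self, two_proband_key):
        sub = pb.ModelSubmission(
            "t", "m",
            {
                "A": [pb.PredictionRecord("A", frozenset({vk("1:100:A:G")}), 1.0, 1)],
                "B": [pb.PredictionRecord("B", frozenset({vk("2:200:C:T")}), 1.0, 1)],
            },
        )
        assert pb.precision_recall_at(sub, two_proband_key, 1.0) == (1.0, 1.0, 1.0)

    def test_worked_example_thresholds(self, worked_example):
        sub, key = worked_example
        p, r, f = pb.precision_recall_at(sub, key, 0.6)
        assert (p, r, f) == (0.5, 1.0, pytest.approx(2 / 3))
        p, r, f = pb.precision_recall_at(sub, key, 0.7)
        assert (p, r) == (pytest.approx(1 / 3), 0.5)
        assert f == pytest.approx(0.4)


class TestFmaxSweep:
    def test_worked_example_tiebreak_largest_threshold(self, worked_example):
        sub, key = worked_example
        res = pb.fmax_sweep(sub, key)
        assert res.fmax == pytest.approx(2 / 3)
        assert res.threshold == 0.9  # ties at 0.9 and 0.6; largest wins
        assert res.mean_calls_per_proband == 0.5
        tying = [t for t, _p, _r, f in res.curve if f == pytest.approx(2 / 3)]
        assert set(tying) == {0.9, 0.6}

    def test_empty_submission_is_na_not_error(self, two_proband_key):
        res = pb.fmax_sweep(pb.ModelSubmission("t6", "m", {}), two_proband_key)
        assert res.is_na and res.threshold is None

    def test_zero_correct_predictions(self, two_proband_key):
        sub = pb.ModelSubmission(
            "t", "m",
            {"A": [pb.PredictionRecord("A", frozenset({vk("9:9:A:G")}), 0.8, 1)]},
        )
        assert pb.fmax_sweep(sub, two_proband_key).fmax == 0.0

    def test_sweep_matches_dense_grid_oracle(self):
        """F is piecewise constant between unique EPCRs, so the sweep must agree
        with a brute-force dense-grid maximum on random small submissions."""
        rng = np.random.default_rng(20251001)
        for _ in range(30):
            sub, key = random_small_submission(rng)
            swept = pb.fmax_sweep(sub, key)
            oracle = brute_force_fmax(sub, key, n_grid=10_000)
            if swept.is_na:
                assert oracle == 0.0
            else:
                assert swept.fmax == pytest.approx(oracle, abs=1e-12)

    def test_curve_values_bounded(self):
        rng = np.random.default_rng(7)
        sub, key = random_small_submission(rng)
        res = pb.fmax_sweep(sub, key)
        if not res.is_na:
            for _t, p, r, f in res.curve:
                assert 0 <= p <= 1 and 0 <= r <= 1 and 0 <= f <= 1


class TestBootstrap:
    def test_constant_statistic_has_zero_se(self):
        outs = outcomes_from_ranks([1] * 14)
        assert pb.bootstrap_se_mean_rank_points(outs, B=200, seed=0) == 0.0

    def test_converges_to_closed_form(self):
        """13×100 + 1×0 → SE → sqrt(pop.var/14) ≈ 6.883 as B grows."""
        outs = outcomes_from_ranks([1] * 13 + [None])
        points = np.array([100.0] * 13 + [0.0])
        limit = math.sqrt(points.var() / 14)
        assert limit == pytest.approx(6.8832, abs=1e-3)
        se = pb.bootstrap_se_mean_rank_points(outs, B=100_000, seed=1)
        assert se == pytest.approx(limit, abs=0.1)

    def test_generic_and_vectorized_agree_in_law(self):
        outs = outcomes_from_ranks([1, 6, 11, 21, 51, None] * 2)
        se_fast = pb.bootstrap_se_mean_rank_points(outs, B=4000, seed=3)
        se_generic = pb.bootstrap_se(pb.mean_rank_points, outs, B=4000, seed=4)
        assert se_fast == pytest.approx(se_generic, rel=0.15)

    def test_deterministic_under_seed(self):
        outs = outcomes_from_ranks([1, 7, None, 30])
        a = pb.bootstrap_se_mean_rank_points(outs, B=500, seed=42)
        b = pb.bootstrap_se_mean_rank_points(outs, B=500, seed=42)
        assert a == b

    def test_b_below_two_rejected(self):
        with pytest.raises(ValueError):
            pb.bootstrap_se(pb.mean_rank_points, outcomes_from_ranks([1]), B=1)

    def test_fmax_bootstrap_matches_generic_resweep(self, worked_example):
        """The vectorized F-max bootstrap must agree with literally re-sweeping
        each replicate through fmax_sweep."""
        sub, key = worked_example

        profiles = {"A": sub.records_for("A"), "B": sub.records_for("B")}

        def fmax_of(pids):
            preds = {}
            for i, pid in enumerate(pids):
                preds[f"{pid}#{i}"] = [
                    pb.PredictionRecord(f"{pid}#{i}", r.variants, r.epcr, r.rank)
                    for r in profiles[pid]
                ]
            entries = []
            for i, pid in enumerate(pids):
                orig = key[pid]
                entries.append(
                    pb.AnswerKeyEntry(f"{pid}#{i}", True, orig.match_mode, orig.required_set)
                )
            return pb.fmax_sweep(
                pb.ModelSubmission("t", "m", preds), pb.AnswerKey(entries)
            ).fmax

        se_generic = pb.bootstrap_se(fmax_of, ["A", "B"], B=3000, seed=11)
        se_fast = pb.bootstrap_se_fmax(sub, key, B=3000, seed=12)
        assert se_fast == pytest.approx(se_generic, rel=0.1)


class TestDetectionCounts:
    def test_three_models_enumerated(self, two_proband_key):
        entry = two_proband_key["A"]
        causal = frozenset({vk("1:100:A:G")})

        def model_with_rank(rank):
            if rank is None:
                return pb.ModelSubmission("t", "m", {})
            recs = [
                pb.PredictionRecord("A", frozenset({vk(f"21:{i}:A:G")}), 0.5, i)
                for i in range(1, rank)
            ]
            recs.append(pb.PredictionRecord("A", causal, 0.4, rank))
            return pb.ModelSubmission("t", "m", {"A": recs})

        models = [model_with_rank(1), model_with_rank(7), model_with_rank(None)]
        assert pb.detection_counts(models, entry) == (1, 1, 2, 2, 2, 2)
        assert pb.detection_counts([model_with_rank(None)] * 3, entry) == (0,) * 6
        assert pb.detection_counts([model_with_rank(1)] * 3, entry) == (3,) * 6


class TestConcordance:
    def test_identical_submissions_have_concordance_one(self):
        rng = np.random.default_rng(2)
        sub, _ = random_small_submission(rng, n_probands=5)
        if sub.n_records:
            assert pb.concordance(sub, sub) == 1.0

    def test_disjoint_top5_everywhere_is_zero(self):
        a = pb.ModelSubmission(
            "a", "m", {"P": [pb.PredictionRecord("P", frozenset({vk("1:1:A:G")}), 0.9, 1)]}
        )
        b = pb.ModelSubmission(
            "b", "m", {"P": [pb.PredictionRecord("P", frozenset({vk("2:2:C:T")}), 0.9, 1)]}
        )
        assert pb.concordance(a, b) == 0.0

    def test_jaccard_two_of_eight(self):
        shared = [frozenset({vk(f"1:{i}:A:G")}) for i in (1, 2)]
        only_a = [frozenset({vk(f"2:{i}:A:G")}) for i in (1, 2, 3)]
        only_b = [frozenset({vk(f"3:{i}:A:G")}) for i in (1, 2, 3)]
        a = pb.ModelSubmission(
            "a", "m",
            {"P": [pb.PredictionRecord("P", fs, 0.9, i + 1)
                   for i, fs in enumerate(shared + only_a)]},
        )
        b = pb.ModelSubmission(
            "b", "m",
            {"P": [pb.PredictionRecord("P", fs, 0.9, i + 1)
                   for i, fs in enumerate(shared + only_b)]},
        )
        assert pb.concordance(a, b) == pytest.approx(2 / 8)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(3)
        a, _ = random_small_submission(rng)
        b, _ = random_small_submission(rng)
        c_ab, c_ba = pb.concordance(a, b), pb.concordance(b, a)
        if not math.isnan(c_ab):
            assert c_ab == c_ba and 0 <= c_ab <= 1

    def test_both_empty_is_na(self):
        empty = pb.ModelSubmission("t", "m", {})
        assert math.isnan(pb.concordance(empty, empty))


class TestStratified:
    def _families(self, completeness_by_pid):
        from priobench.families import FamilyInfo, FamilyMember, Relation

        out = {}
        for pid, comp in completeness_by_pid.items():
            members = {FamilyMember(pid, Relation.PROBAND, True)}
            if comp in (pb.Completeness.DUO, pb.Completeness.TRIO, pb.Completeness.QUAD):
                members.add(FamilyMember(f"{pid}f", Relation.FATHER, False))
            if comp in (pb.Completeness.TRIO, pb.Completeness.QUAD):
                members.add(FamilyMember(f"{pid}m", Relation.MOTHER, False))
            if comp is pb.Completeness.QUAD:
                members.add(FamilyMember(f"{pid}s", Relation.SIBLING, True))
            out[pid] = FamilyInfo(f"F{pid}", pid, frozenset(members))
        return out

    def test_two_strata_means(self):
        fams = self._families(
            {
                "a": pb.Completeness.PROBAND_ONLY,
                "b": pb.Completeness.DUO,
                "c": pb.Completeness.TRIO,
                "d": pb.Completeness.TRIO,
                "e": pb.Completeness.QUAD,
            }
        )
        outcomes = {
            "a": pb.MatchOutcome("a", True, 1),     # 100
            "b": pb.MatchOutcome("b", False),       # 0
            "c": pb.MatchOutcome("c", True, 1),     # 100
            "d": pb.MatchOutcome("d", True, 2),     # 100
            "e": pb.MatchOutcome("e", True, 6),     # 50
        }
        inc, comp = pb.stratified_mean_rank_points(outcomes, fams)
        assert inc == pytest.approx(50.0)
        assert comp == pytest.approx(250 / 3)

    def test_empty_stratum_is_na(self):
        fams = self._families({"a": pb.Completeness.TRIO})
        outcomes = {"a": pb.MatchOutcome("a", True, 1)}
        inc, comp = pb.stratified_mean_rank_points(outcomes, fams)
        assert math.isnan(inc) and comp == 100.0


class TestPairedT:
    def test_equal_vectors(self):
        t, p = pb.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_textbook_example(self):
        # d = (1, 2, 3): t = 2 / (1/sqrt(3)) = 3.464, df = 2
        t, p = pb.paired_t_test([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * math.sqrt(3), abs=1e-6)
        assert p == pytest.approx(0.0742, abs=5e-4)

    def test_sign_flip_negates_t_preserves_p(self):
        x, y = [0.0, 1.0, 0.0, 2.0], [1.0, 3.0, 2.0, 2.5]
        t1, p1 = pb.paired_t_test(x, y)
        t2, p2 = pb.paired_t_test(y, x)
        assert t2 == pytest.approx(-t1) and p2 == pytest.approx(p1)

    def test_degenerate_constant_nonzero_difference(self):
        t, p = pb.paired_t_test([0.0, 0.0], [1.0, 1.0])
        assert math.isinf(t) and t > 0 and p == 0.0
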