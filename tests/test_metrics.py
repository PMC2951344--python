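"""Rank-error metrics: worked examples, oracles, properties."""

import math
from itertools import combinations, permutations

import numpy as np
import pytest
from scipy import stats

import figrank as fr
from figrank.metrics import article_metrics, logistic_pair_weight


def brute_force_wrong_pairs(ref, sys):
    """Independent oracle: enumerate pairs and compare orders directly."""
    pos_r = {x: i for i, x in enumerate(ref)}
    pos_s = {x: i for i, x in enumerate(sys)}
    return sum(1 for i, j in combinations(ref, 2)
               if (pos_r[i] - pos_r[j]) * (pos_s[i] - pos_s[j]) < 0)


class TestWorkedExamples:
    """The two canonical system outputs against reference (1,2,3,4)."""

    @pytest.mark.parametrize("sys,expected_mer,expected_mwer,expected_mwer_rk", [
        ((2, 1, 3, 4), 0.167, 0.1, 0.108),
        ((1, 2, 4, 3), 0.167, 0.1, 0.019),
    ])
    def test_values_to_three_decimals(self, sys, expected_mer, expected_mwer,
                                      expected_mwer_rk):
        ref = (1, 2, 3, 4)
        assert fr.mer(ref, sys) == pytest.approx(expected_mer, abs=5e-4)
        assert fr.mwer(ref, sys) == pytest.approx(expected_mwer, abs=5e-4)
        assert fr.mwer_rk(ref, sys) == pytest.approx(expected_mwer_rk, abs=5e-4)

    def test_logistic_calibration(self):
        # for reference (1,2,3,4): sum of all pair distances is 10, so the
        # two single-swap outputs give 1*L(1)/10 and 1*L(3)/10
        assert 1 * logistic_pair_weight(1) / 10 == pytest.approx(0.108, abs=5e-4)
        assert 1 * logistic_pair_weight(3) / 10 == pytest.approx(0.019, abs=5e-4)


class TestPairwiseMetricBasics:
    def test_identity_is_zero(self):
        ref = (3, 1, 4, 2)
        assert fr.mer(ref, ref) == 0.0
        assert fr.mwer(ref, ref) == 0.0
        assert fr.mwer_rk(ref, ref) == 0.0

    def test_full_reversal(self):
        ref = (1, 2, 3, 4)
        rev = (4, 3, 2, 1)
        assert fr.mer(ref, rev) == 1.0
        assert fr.mwer(ref, rev) == 1.0

    def test_single_figure_undefined(self):
        with pytest.raises(ValueError):
            fr.mer((1,), (1,))

    def test_non_permutation_rejected(self):
        with pytest.raises(ValueError):
            fr.mwer((1, 2), (1, 3))

    def test_label_invariance(self):
        # metrics depend on order relations, not on the label values
        assert fr.mwer_rk((1, 2, 3, 4), (2, 1, 3, 4)) == \
               pytest.approx(fr.mwer_rk((9, 5, 7, 2), (5, 9, 7, 2)))


class TestMerOracles:
    def test_matches_kendall_tau_all_permutations(self):
        """MER equals Kendall discordant pairs / C(n,2) (scipy route)."""
        for n in range(2, 5):
            for ref in permutations(range(1, n + 1)):
                rr = {x: i for i, x in enumerate(ref)}
                for sys in permutations(ref):
                    ss = {x: i for i, x in enumerate(sys)}
                    labels = sorted(ref)
                    tau = stats.kendalltau([rr[x] for x in labels],
                                           [ss[x] for x in labels]).statistic
                    expected = (1 - tau) / 2
                    assert fr.mer(ref, sys) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_n5(self):
        ref = (1, 2, 3, 4, 5)
        for sys in permutations(ref):
            assert fr.mer(ref, sys) * 10 == pytest.approx(
                brute_force_wrong_pairs(ref, sys))


class TestMwerProperties:
    def test_bounds_and_zero_iff_perfect(self):
        ref = (1, 2, 3, 4, 5)
        for sys in permutations(ref):
            v = fr.mwer(ref, sys)
            w = fr.mwer_rk(ref, sys)
            assert 0.0 <= v <= 1.0
            assert w >= 0.0
            perfect = sys == ref
            assert (v == 0.0) == perfect
            assert (w == 0.0) == perfect

    def test_reversal_attains_one(self):
        assert fr.mwer((1, 2, 3, 4), (4, 3, 2, 1)) == 1.0

    def test_penalty_monotone_in_reference_rank(self):
        """Same-distance wrong pairs hurt more at the top of the reference."""
        ranks = list(range(1, 8))
        assert all(logistic_pair_weight(a) > logistic_pair_weight(a + 1)
                   for a in ranks)
        # adjacent swap at the top vs at the bottom of a 5-figure reference
        top = fr.mwer_rk((1, 2, 3, 4, 5), (2, 1, 3, 4, 5))
        bottom = fr.mwer_rk((1, 2, 3, 4, 5), (1, 2, 3, 5, 4))
        assert top > bottom


class TestHighestRankMetrics:
    def test_all_agree_zero(self):
        pairs = [((1, 2, 3), (1, 3, 2)), ((2, 1), (2, 1))]
        assert fr.er_hr(pairs) == 0.0
        assert fr.wer_hr(pairs) == 0.0

    def test_all_disagree_one(self):
        pairs = [((1, 2), (2, 1)), ((3, 1, 2), (2, 1, 3))]
        assert fr.er_hr(pairs) == 1.0

    def test_top_ranked_last_gives_one(self):
        assert fr.wer_hr([((1, 2, 3), (3, 2, 1))]) == 1.0

    def test_wer_hr_linear_in_system_rank(self):
        # n=4: reference top at system rank 2 scores 1/3
        assert fr.wer_hr([((1, 2, 3, 4), (2, 1, 3, 4))]) == pytest.approx(1 / 3)

    def test_wer_hr_depends_only_on_top_position(self):
        """Brute force over all 24 system permutations of a 4-figure article:
        the value is (position of the reference top - 1)/3, monotone in it."""
        ref = (1, 2, 3, 4)
        for sys in permutations(ref):
            expected = sys.index(ref[0]) / 3
            assert fr.wer_hr([(ref, sys)]) == pytest.approx(expected)

    def test_er_zero_implies_wer_zero(self):
        for sys in permutations((1, 2, 3, 4)):
            pairs = [((1, 2, 3, 4), sys)]
            if fr.er_hr(pairs) == 0.0:
                assert fr.wer_hr(pairs) == 0.0

    def test_single_figure_articles_always_agree(self):
        assert fr.er_hr([((1,), (1,))]) == 0.0
        assert fr.wer_hr([((1,), (1,))]) == 0.0

    def test_random_top_baseline(self):
        assert fr.random_top_baseline(5.9) == pytest.approx(0.831, abs=5e-4)
        assert fr.random_top_baseline(2.0) == pytest.approx(0.5)


class TestEvaluateCollection:
    def test_perfect_system_all_zero(self):
        report = fr.evaluate_collection(
            {"oracle": [("a1", (2, 1, 3), (2, 1, 3))]})
        assert report.rows["oracle"] == pytest.approx(
            {"mer": 0, "mwer": 0, "mwer_rk": 0, "er_hr": 0, "wer_hr": 0})

    def test_means_are_arithmetic_averages(self):
        triples = [("a1", (1, 2, 3, 4), (2, 1, 3, 4)),
                   ("a2", (1, 2, 3, 4), (1, 2, 4, 3))]
        report = fr.evaluate_collection({"m": triples})
        a1 = article_metrics("a1", (1, 2, 3, 4), (2, 1, 3, 4))
        a2 = article_metrics("a2", (1, 2, 3, 4), (1, 2, 4, 3))
        assert report.rows["m"]["mwer_rk"] == pytest.approx(
            (a1.mwer_rk + a2.mwer_rk) / 2)
        # only the top-swapped output misses the reference top figure
        assert report.rows["m"]["er_hr"] == pytest.approx(0.5)

    def test_single_figure_articles_excluded_from_pairwise(self):
        report = fr.evaluate_collection(
            {"m": [("a1", (1,), (1,)), ("a2", (1, 2), (2, 1))]})
        assert report.n_excluded_pairwise == 1
        assert report.rows["m"]["mer"] == 1.0
        assert report.rows["m"]["er_hr"] == 0.5

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            fr.evaluate_collection({"m": []})

    def test_report_frame_shape(self):
        report = fr.evaluate_collection(
            {"a": [("x", (1, 2), (1, 2))], "b": [("x", (1, 2), (2, 1))]},
            config_hash="cafe")
        frame = report.to_frame()
        assert set(frame["method_id"]) == {"a", "b"}
        assert (frame["config_hash"] == "cafe").all()


class TestPairedTTest:
    def test_identical_samples(self):
        assert fr.paired_t_test([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_constant_nonzero_difference(self):
        t, p = fr.paired_t_test([2, 3, 4], [1, 2, 3])
        assert math.isinf(t) and t > 0 and p == 0.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        a = rng.random(20)
        b = rng.random(20)
        t, p = fr.paired_t_test(a, b)
        d = a - b
        t_direct = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert t == pytest.approx(t_direct)
        assert 0.0 <= p <= 1.0

    def test_large_n_constant_shift_significant(self):
        rng = np.random.default_rng(0)
        base = rng.random(200)
        t, p = fr.paired_t_test(base + 0.5 + rng.normal(0, 0.01, 200), base)
        assert p < 1e-10
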