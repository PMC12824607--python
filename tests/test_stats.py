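"""Exact contingency tests, MTC procedures, rank/means tests, log-rank."""

import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats as sps

from phenogpc.stats import (
    MTC_METHODS,
    adjust_pvalues,
    exact_rx2,
    fisher_exact_2x2,
    log_rank,
    mann_whitney_u,
    t_test,
)


def bruteforce_fisher_2x2(table, alternative="two-sided"):
    """Exact-rational enumeration over the hypergeometric support."""
    (a, b), (c, d) = table
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d

    def prob(k):
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1))

    support = range(max(0, c1 - r2), min(c1, r1) + 1)
    p_obs = prob(a)
    if alternative == "greater":
        total = sum(prob(k) for k in support if k >= a)
    elif alternative == "less":
        total = sum(prob(k) for k in support if k <= a)
    else:
        total = sum(prob(k) for k in support if prob(k) <= p_obs)
    return float(total)


class TestFisher2x2:
    def test_extreme_table_one_and_two_sided(self):
        # 19/19 vs 7/19 with the phenotype: a maximally extreme table
        assert fisher_exact_2x2([[19, 0], [7, 12]], "greater") == pytest.approx(
            1.861e-5, rel=1e-3
        )
        assert fisher_exact_2x2([[19, 0], [7, 12]]) == pytest.approx(
            3.722e-5, rel=1e-3
        )

    def test_balanced_table_is_null(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_small_diagonal_table(self):
        assert fisher_exact_2x2([[4, 0], [0, 3]]) == pytest.approx(1 / 35)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            table = rng.integers(0, 15, size=(2, 2))
            if table.sum() == 0:
                continue
            for alt in ("two-sided", "greater", "less"):
                assert fisher_exact_2x2(table, alt) == pytest.approx(
                    float(sps.fisher_exact(table, alternative=alt)[1]), abs=1e-12
                )

    def test_matches_bruteforce_on_all_small_tables(self):
        # exhaustive over all 2x2 tables with total <= 8 (full <= 12 sweep
        # lives in the acceptance suite)
        for n in range(1, 9):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        table = [[a, b], [c, d]]
                        assert fisher_exact_2x2(table) == pytest.approx(
                            bruteforce_fisher_2x2(table), rel=1e-8
                        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])


class TestFreemanHalton:
    def test_hand_enumerated_3x2(self):
        # six margin-consistent tables with probabilities
        # 0.05, 0.05, 0.3, 0.15, 0.15, 0.3; observed prob 0.05
        assert exact_rx2([[3, 0], [0, 2], [0, 1]]) == pytest.approx(0.10)

    def test_zero_row_reduces_to_2x2(self):
        assert exact_rx2([[4, 0], [0, 3], [0, 0]]) == pytest.approx(1 / 35)

    def test_empty_column_is_certain(self):
        assert exact_rx2([[3, 0], [2, 0], [1, 0]]) == pytest.approx(1.0)

    def test_matches_2x2_engine_on_random_two_row_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            table = rng.integers(0, 10, size=(2, 2))
            if table.sum() == 0:
                continue
            assert exact_rx2(table) == pytest.approx(
                fisher_exact_2x2(table), rel=1e-10
            )

    def test_four_rows_rejected(self):
        with pytest.raises(ValueError):
            exact_rx2([[1, 1], [1, 1], [1, 1], [1, 1]])


class TestMultipleTesting:
    def test_bh_step_up(self):
        assert adjust_pvalues([0.01, 0.02, 0.03], "fdr_bh") == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_bonferroni(self):
        assert adjust_pvalues([0.01, 0.04], "bonferroni") == pytest.approx(
            [0.02, 0.08]
        )

    @pytest.mark.parametrize("method", MTC_METHODS)
    def test_single_p_unchanged_and_adjusted_ge_raw(self, method):
        if method != "fdr_tsbky":
            # the two-stage BKY procedure rescales by 1 + alpha even for m = 1
            assert adjust_pvalues([0.037], method) == pytest.approx([0.037])
        rng = np.random.default_rng(17)
        pvals = rng.uniform(size=25).tolist()
        adjusted = adjust_pvalues(pvals, method)
        assert all(pa >= p - 1e-12 for pa, p in zip(adjusted, pvals))
        assert all(0 <= pa <= 1 for pa in adjusted)

    def test_bh_monotone_after_sorting(self):
        rng = np.random.default_rng(19)
        pvals = sorted(rng.uniform(size=40))
        adjusted = adjust_pvalues(pvals, "fdr_bh")
        assert all(a <= b + 1e-12 for a, b in zip(adjusted, adjusted[1:]))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], "fdr_nope")


class TestMannWhitney:
    def test_fully_separated_small_samples_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(2 / 20)

    def test_identical_samples_null(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.5], [1.0, 2.0, 3.5])
        assert p == pytest.approx(1.0)

    def test_normal_mode_tracks_exact_mode(self):
        rng = np.random.default_rng(23)
        for _ in range(500):
            n1, n2 = rng.integers(5, 7, size=2)
            x = rng.normal(size=n1).tolist()
            y = rng.normal(size=n2).tolist()
            _, p_exact = mann_whitney_u(x, y, mode="exact")
            _, p_norm = mann_whitney_u(x, y, mode="normal")
            assert abs(p_exact - p_norm) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestTTest:
    def test_pooled_statistic(self):
        t, p = t_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert p == pytest.approx(0.2879, abs=1e-3)

    def test_identical_samples(self):
        t, p = t_test([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == 1.0

    def test_zero_variance_equal_means(self):
        t, p = t_test([5, 5], [5, 5])
        assert t == 0 and p == 1.0

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(29)
        x, y = rng.normal(size=10), rng.normal(1, 1, size=12)
        t1, p1 = t_test(x, y)
        t2, p2 = t_test(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_power_increases_with_shift(self):
        rng = np.random.default_rng(31)
        rejections = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            hits = 0
            for _ in range(200):
                x = rng.normal(size=20)
                y = rng.normal(shift, 1, size=20)
                hits += t_test(x, y)[1] < 0.05
            rejections.append(hits)
        assert rejections == sorted(rejections)

    def test_short_sample_rejected(self):
        with pytest.raises(ValueError):
            t_test([1.0], [1.0, 2.0])


class TestLogRank:
    def test_hand_computed_statistic(self):
        records = [(1, True, "A"), (2, True, "A"), (3, True, "B"), (4, True, "B")]
        chi2, p = log_rank(records)
        # O_A = 2, E_A = 0.8333, Var = 0.4722
        assert chi2 == pytest.approx(2.882, abs=1e-3)
        assert p == pytest.approx(0.0896, abs=1e-3)

    def test_identical_groups_are_null(self):
        base = [(1.0, True), (2.0, False), (3.0, True)]
        records = [(t, e, lab) for lab in ("A", "B") for t, e in base]
        chi2, p = log_rank(records)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_agrees_with_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(37)
        for _ in range(20):
            n = 30
            times = rng.exponential(1, size=n)
            events = rng.random(n) < 0.8
            groups = rng.random(n) < 0.5
            records = [
                (float(t), bool(e), "A" if g else "B")
                for t, e, g in zip(times, events, groups)
            ]
            chi2, p = log_rank(records)
            ref = logrank_test(
                times[groups], times[~groups], events[groups], events[~groups]
            )
            assert chi2 == pytest.approx(float(ref.test_statistic), rel=1e-6)
            assert p == pytest.approx(float(ref.p_value), rel=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            log_rank([(1.0, False, "A"), (2.0, False, "B")])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            log_rank([(1.0, True, "A"), (2.0, True, "A")])

    def test_null_pvalues_are_uniform(self):
        """Equal-rate exponential groups give uniform log-rank p (KS at alpha=0.01)."""
        rng = np.random.default_rng(41)
        pvals = []
        for _ in range(300):
            times = rng.exponential(1, size=40)
            labels = ["A"] * 20 + ["B"] * 20
            records = [(float(t), True, lab) for t, lab in zip(times, labels)]
            pvals.append(log_rank(records)[1])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
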