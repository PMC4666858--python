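"""Outlier flagging, SEMs, pooling, and the pooled-variance comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberratio.group_stats import (
    PoolingRefusal,
    RGroup,
    critical_t,
    flag_outliers,
    pool_washed_unwashed,
    pooled_test_from_summary,
    pooled_two_sample_test,
    sem_of_mean,
)


def quartiles_inclusive(values):
    """Independent inclusive-median quartile implementation."""
    v = sorted(values)
    n = len(v)

    def median(seq):
        m = len(seq)
        return seq[m // 2] if m % 2 else (seq[m // 2 - 1] + seq[m // 2]) / 2

    half = (n + 1) // 2
    return median(v[:half]), median(v[n - half:])


class TestFlagOutliers:
    def test_single_extreme_value_flagged(self):
        flags = flag_outliers([1.0, 1.1, 1.2, 1.1, 5.0])
        np.testing.assert_array_equal(flags, [False] * 4 + [True])

    def test_all_equal_no_flags(self):
        assert not flag_outliers([2.0] * 6).any()

    def test_small_group_warns_and_skips(self):
        with pytest.warns(UserWarning, match="at least 4"):
            flags = flag_outliers([1.0, 9.0, 1.1])
        assert not flags.any()

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_independent_quartile_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.lognormal(0.5, 0.4, size=rng.integers(5, 40))
        q1, q3 = quartiles_inclusive(v)
        iqr = q3 - q1
        expected = (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)
        np.testing.assert_array_equal(flag_outliers(v), expected)


class TestSemOfMean:
    def test_no_spread_gives_zero(self):
        assert sem_of_mean([1.0, 1.0, 1.0]) == 0.0

    def test_hand_case(self):
        # sd({0,2}) = sqrt(2), SEM = sqrt(2)/sqrt(2) = 1
        assert sem_of_mean([0.0, 2.0]) == pytest.approx(1.0)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(7)
        v = rng.random(17)
        mean = sum(v) / len(v)
        sd = math.sqrt(sum((x - mean) ** 2 for x in v) / (len(v) - 1))
        assert sem_of_mean(v) == pytest.approx(sd / math.sqrt(len(v)), rel=1e-12)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            sem_of_mean([1.0])


class TestCriticalT:
    def test_df48_rounds_to_published_2_01(self):
        value = critical_t(48, 0.05)
        assert value == pytest.approx(2.0106, abs=1e-3)
        assert round(value, 2) == 2.01

    def test_df1_standard_table_value(self):
        assert critical_t(1, 0.05) == pytest.approx(12.706, abs=1e-3)

    def test_normal_limit(self):
        assert abs(critical_t(1000, 0.05) - 1.96) < 0.01

    def test_monotone_decreasing_in_df(self):
        values = [critical_t(df, 0.05) for df in (1, 2, 5, 10, 100)]
        assert values == sorted(values, reverse=True)


class TestPooledTest:
    def test_published_mean_difference(self):
        """Groups constructed at means 2.08 and 1.22 (any spread) give a
        mean difference of exactly 0.86."""
        g1 = RGroup("A", 2.08 + np.array([-0.3, 0.0, 0.3] * 9 + [0.0]))
        g2 = RGroup("B", 1.22 + np.array([-0.2, 0.0, 0.2] * 9 + [0.0]))
        test = pooled_two_sample_test(g1, g2)
        assert test.mean_diff == pytest.approx(0.86, abs=1e-12)

    def test_df_and_tcrit_at_published_sample_sizes(self):
        rng = np.random.default_rng(1)
        g1 = RGroup("A", rng.lognormal(0.7, 0.3, 28))
        g2 = RGroup("B", rng.lognormal(0.2, 0.3, 22))
        test = pooled_two_sample_test(g1, g2)
        assert test.df == 48
        assert round(test.t_crit, 2) == 2.01

    def test_identical_groups_not_significant(self):
        v = np.array([1.0, 1.4, 1.2, 1.1])
        test = pooled_two_sample_test(RGroup("A", v), RGroup("B", v.copy()))
        assert test.mean_diff == 0.0
        assert test.ci_low == pytest.approx(-test.ci_high)
        assert not test.significant

    def test_invariant_formulas_hold(self):
        rng = np.random.default_rng(2)
        v1, v2 = rng.random(9) + 0.5, rng.random(13) + 0.5
        test = pooled_two_sample_test(RGroup("A", v1), RGroup("B", v2))
        assert test.s2_pooled == pytest.approx(
            (test.ss1 + test.ss2) / (test.n1 + test.n2 - 2), rel=1e-12
        )
        assert test.sem == pytest.approx(
            math.sqrt(test.s2_pooled * (1 / test.n1 + 1 / test.n2)), rel=1e-12
        )
        assert test.ci_low == pytest.approx(
            test.mean_diff - test.t_crit * test.sem, rel=1e-12
        )

    def test_zero_variance_edge_cases(self):
        same = pooled_test_from_summary(1.5, 1.5, 3, 3, 0.0, 0.0)
        assert not same.significant and same.ci_low == same.ci_high == 0.0
        apart = pooled_test_from_summary(2.0, 1.0, 3, 3, 0.0, 0.0)
        assert apart.significant

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n1=st.integers(2, 15),
        n2=st.integers(2, 15),
        shift=st.floats(0.0, 1.0),
    )
    def test_ci_decision_equals_t_statistic_decision(self, seed, n1, n2, shift):
        """CI-excludes-0 coincides with |t| > t_crit on every input."""
        rng = np.random.default_rng(seed)
        v1 = rng.random(n1) + 1.0
        v2 = rng.random(n2) + 1.0 + shift
        test = pooled_two_sample_test(RGroup("A", v1), RGroup("B", v2))
        if test.sem == 0:
            return
        t_stat = test.mean_diff / test.sem
        assert test.significant == (abs(t_stat) > test.t_crit)

    def test_type_one_error_calibrated(self):
        """Rejection rate under the null lies in [0.03, 0.07] at alpha =
        0.05 over 2000 replicate pairs of groups drawn identically."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_reps = 2000
        for _ in range(n_reps):
            v1 = rng.lognormal(0.5, 0.25, 12)
            v2 = rng.lognormal(0.5, 0.25, 12)
            test = pooled_two_sample_test(RGroup("A", v1), RGroup("B", v2))
            rejections += test.significant
        assert 0.03 <= rejections / n_reps <= 0.07


class TestPooling:
    def test_identically_drawn_groups_pool(self):
        rng = np.random.default_rng(4)
        gw = RGroup("EGV", rng.lognormal(0.7, 0.2, 10), washed=True)
        gu = RGroup("EGV", rng.lognormal(0.7, 0.2, 10), washed=False)
        merged = pool_washed_unwashed(gw, gu)
        assert merged.n == gw.n + gu.n
        assert merged.washed is None

    def test_extreme_separation_refused(self):
        gw = RGroup("EGV", [1.0, 1.01, 0.99, 1.0], washed=True)
        gu = RGroup("EGV", [3.0, 3.01, 2.99, 3.0], washed=False)
        with pytest.raises(PoolingRefusal):
            pool_washed_unwashed(gw, gu)

    def test_label_mismatch_rejected(self):
        gw = RGroup("EGV", [1.0, 1.1], washed=True)
        gu = RGroup("CBHI", [1.0, 1.1], washed=False)
        with pytest.raises(ValueError, match="different enzymes"):
            pool_washed_unwashed(gw, gu)

    def test_outlier_removal_before_testing(self):
        g = RGroup(
            "EGV",
            np.array([1.0, 1.1, 1.2, 9.0]),
            outlier_flags=np.array([False, False, False, True]),
        )
        clean = g.without_outliers()
        assert clean.n == 3
        assert 9.0 not in clean.R_values
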