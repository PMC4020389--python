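"""Normality tests, Mann-Whitney, paired t and the routed group comparison."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tonguelab.errors import AnalysisError, StatTestError
from tonguelab.stats import (
    group_compare,
    format_table,
    lilliefors_ks,
    mann_whitney,
    paired_t,
    shapiro_wilk,
    two_sample_t,
)
from tonguelab.synth import CohortSpec, generate_cohort


class TestLilliefors:
    def test_calibrated_under_the_null(self):
        x = np.random.default_rng(7).standard_normal(500)
        res = lilliefors_ks(x, n_mc=2000)
        assert res.p_value > 0.05

    def test_powerful_against_exponential(self):
        x = np.random.default_rng(8).exponential(size=500)
        res = lilliefors_ks(x, n_mc=2000)
        assert res.p_value < 0.01

    def test_three_point_statistic_hand_computed(self):
        # {-1, 0, 1}: sample mean 0, sd 1, so the standardized values are
        # themselves; the largest ECDF deviation is 1/3 - Phi(-1) = 0.17467808
        from tonguelab.stats import _lilliefors_statistic

        stat = _lilliefors_statistic(np.array([-1.0, 0.0, 1.0]))
        assert stat == pytest.approx(1 / 3 - sps.norm.cdf(-1.0), abs=1e-12)
        with pytest.raises(StatTestError):
            lilliefors_ks([-1.0, 0.0, 1.0])  # the full test requires n >= 4

    def test_p_above_bound_reported_as_lower_bound(self):
        x = np.random.default_rng(9).standard_normal(200)
        res = lilliefors_ks(x, n_mc=1000)
        if res.p_lower_bound:
            assert res.p_value == 0.2

    def test_statistic_matches_statsmodels(self):
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        x = np.random.default_rng(10).gamma(3.0, size=80)
        ours = lilliefors_ks(x, n_mc=5000)
        sm_stat, sm_p = sm_lilliefors(x, dist="norm")
        assert ours.statistic == pytest.approx(sm_stat, abs=1e-12)
        if not ours.p_lower_bound and sm_p < 0.2:
            assert ours.p_value == pytest.approx(sm_p, abs=0.05)

    def test_constant_sample_rejected(self):
        with pytest.raises(StatTestError):
            lilliefors_ks([3.0, 3.0, 3.0, 3.0])


class TestShapiroWilk:
    def test_null_and_alternative_behaviour(self):
        rng = np.random.default_rng(11)
        assert shapiro_wilk(rng.standard_normal(500)).p_value > 0.05
        assert shapiro_wilk(rng.exponential(size=500)).p_value < 0.01

    def test_constant_sample_rejected(self):
        with pytest.raises(StatTestError):
            shapiro_wilk([1.0, 1.0, 1.0])


def brute_force_mw_p(x, y):
    """Exact two-sided p by enumerating assignments, counting pairwise wins."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(
            1.0 if xi > yj else (0.5 if xi == yj else 0.0) for xi in xs for yj in ys
        )

    u_obs = u_of(tuple(range(n)))
    us = [u_of(idx) for idx in combinations(range(len(pooled)), n)]
    p_le = sum(u <= u_obs + 1e-9 for u in us) / len(us)
    p_ge = sum(u >= u_obs - 1e-9 for u in us) / len(us)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestMannWhitney:
    def test_identical_samples_give_central_u(self):
        x = [1.0, 2.0, 3.0]
        res = mann_whitney(x, x)
        assert res.statistic == pytest.approx(4.5)  # n*m/2
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_three_vs_three(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 orderings as extreme

    def test_exact_p_matches_permutation_oracle(self, rng):
        for _ in range(10):
            n, m = rng.integers(2, 6, 2)
            x = rng.integers(0, 5, n).astype(float)  # ties on purpose
            y = rng.integers(0, 5, m).astype(float)
            res = mann_whitney(x, y, method="exact")
            assert res.p_value == pytest.approx(brute_force_mw_p(x, y), abs=1e-12)

    def test_approximation_close_to_exact_where_asymptotics_hold(self, rng):
        # worst-case deviation of the continuity-corrected normal
        # approximation drops below 0.02 once both samples have >= 5 values
        worst = 0.0
        for _ in range(20):
            n, m = rng.integers(5, 9, 2)
            x = rng.normal(0, 1, n)
            y = rng.normal(0.5, 1, m)
            p_exact = mann_whitney(x, y, method="exact").p_value
            p_asym = mann_whitney(x, y, method="asymptotic").p_value
            worst = max(worst, abs(p_exact - p_asym))
        assert worst <= 0.02

    def test_label_swap_reflects_u_and_keeps_p(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.3, 1, 12)
        a = mann_whitney(x, y)
        b = mann_whitney(y, x)
        assert a.statistic + b.statistic == pytest.approx(len(x) * len(y))
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(StatTestError):
            mann_whitney([], [1.0])


class TestPairedT:
    def test_constant_shift_is_degenerate(self):
        x = np.arange(5.0)
        with pytest.raises(StatTestError):
            paired_t(x, x + 1.0)

    def test_zero_mean_differences(self):
        res = paired_t([0.0, 0.0, 0.0, 0.0], [1.0, -1.0, 1.0, -1.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_statistic_matches_direct_formula(self, rng):
        first = rng.normal(0.0, 1.0, 18)
        second = first + rng.normal(0.5, 1.0, 18)
        d = second - first
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert paired_t(first, second).statistic == pytest.approx(expected, abs=1e-12)

    def test_shift_identity_with_one_sample_t(self, rng):
        """paired_t(x, x + delta) depends on delta only."""
        x = rng.normal(0, 1, 25)
        delta = 0.4 + rng.normal(0, 0.3, 25)
        res = paired_t(x, x + delta)
        t, p = sps.ttest_1samp(delta, 0.0)
        assert res.statistic == pytest.approx(float(t), abs=1e-12)
        assert res.p_value == pytest.approx(float(p), abs=1e-12)


class TestGroupCompare:
    def test_nonnormal_cohort_routes_to_mann_whitney(self):
        cohort = generate_cohort(CohortSpec(seed=1))
        table = group_compare(cohort, lilliefors_mc=1000)
        assert (table["test"] == "mann_whitney").all()
        assert table["p_value"].between(0, 1).all()

    def test_normal_cohort_routes_to_t(self, rng):
        rows = []
        for g, loc in (("normal", 0.0), ("sleep_disorder", 0.3)):
            for i in range(40):
                rows.append({"group": g, "V1": rng.normal(loc, 1.0)})
        table = group_compare(pd.DataFrame(rows), ["V1"], lilliefors_mc=1000)
        assert table.loc[0, "test"] == "two_sample_t"

    def test_constant_variable_reported_as_error_without_aborting(self):
        cohort = generate_cohort(CohortSpec(n_normal=40, n_sleep_disorder=20, seed=2))
        cohort["V1"] = 0.5
        table = group_compare(cohort, lilliefors_mc=500)
        v1 = table[table["variable"] == "V1"].iloc[0]
        assert isinstance(v1["error"], str) and "constant" in v1["error"]
        assert table[table["variable"] == "V2"]["p_value"].notna().all()

    def test_paired_mode_uses_one_sample_t_on_differences(self):
        cohort = generate_cohort(CohortSpec(paired=True, n_paired=18, seed=3))
        table = group_compare(cohort, paired=True, lilliefors_mc=1000)
        assert (table["test"] == "paired_t").all()
        assert {"center_first", "center_second"} <= set(table.columns)

    def test_missing_group_rejected(self):
        cohort = generate_cohort(CohortSpec(n_normal=30, n_sleep_disorder=10, seed=4))
        with pytest.raises(AnalysisError):
            group_compare(cohort[cohort["group"] == "normal"])

    def test_bonferroni_adjustment_is_monotone(self):
        cohort = generate_cohort(CohortSpec(n_normal=60, n_sleep_disorder=30, seed=5))
        table = group_compare(cohort, lilliefors_mc=500, adjust="bonferroni")
        assert (table["p_adjusted"] >= table["p_value"] - 1e-15).all()

    def test_format_table_renders_each_variable(self):
        cohort = generate_cohort(CohortSpec(n_normal=40, n_sleep_disorder=20, seed=6))
        text = format_table(group_compare(cohort, lilliefors_mc=500))
        assert text.count("\n") == 7  # header + 7 variables


def test_two_sample_t_matches_scipy(rng):
    x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1, 15)
    res = two_sample_t(x, y)
    t, p = sps.ttest_ind(x, y)
    assert res.statistic == pytest.approx(float(t))
    assert res.p_value == pytest.approx(float(p))
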