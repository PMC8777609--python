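import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency, mannwhitneyu, spearmanr

from hypotrial.metrics import HypotensionSummary
from hypotrial.series import Patient, TrialDataset
from hypotrial.stats import (
    DegenerateInputError,
    InsufficientDataError,
    chi_square,
    compare_arms,
    compare_groups,
    hodges_lehmann,
    ks_normality,
    mann_whitney_u,
    midranks,
    spearman,
)


def enumeration_mw_p(x, y):
    """Exact two-sided Mann-Whitney p by brute-force enumeration of all
    rank assignments (tie-free data only)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    m, n = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    stat_obs = abs(u_obs - m * n / 2)
    count = 0
    total = 0
    for combo in itertools.combinations(range(m + n), m):
        r = sum(i + 1 for i in combo)
        u = r - m * (m + 1) / 2
        total += 1
        if abs(u - m * n / 2) >= stat_obs - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_complete_separation_small(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0
        assert p == pytest.approx(2 / math.comb(6, 3))  # = 0.1

    def test_identical_samples_symmetry(self):
        x = [3.0, 1.0, 4.0, 1.5]
        u, p = mann_whitney_u(x, list(x))
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("m,n", [(3, 4), (5, 5), (6, 3), (8, 8)])
    def test_exact_p_equals_enumeration_oracle(self, m, n, rng):
        x = rng.standard_normal(m)
        y = rng.standard_normal(n) + 0.5
        _, p = mann_whitney_u(x, y, mode="exact")
        assert p == pytest.approx(enumeration_mw_p(x, y), abs=1e-12)

    def test_matches_scipy_exact_and_approx(self, rng):
        x = rng.standard_normal(9)
        y = rng.standard_normal(11) + 0.3
        u, p = mann_whitney_u(x, y, mode="exact")
        ref = mannwhitneyu(x, y, method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)
        _, pn = mann_whitney_u(x, y, mode="normal_approx")
        refn = mannwhitneyu(x, y, method="asymptotic", use_continuity=True)
        assert pn == pytest.approx(refn.pvalue, rel=1e-9)

    def test_ties_use_midranks_and_match_scipy(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0]
        y = [2.0, 3.0, 3.0, 4.0, 4.0, 6.0]
        u, p = mann_whitney_u(x, y)  # auto -> normal approx because of ties
        ref = mannwhitneyu(x, y, method="asymptotic", use_continuity=True)
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_close_to_normal_at_trial_size(self, rng):
        for _ in range(20):
            x = rng.standard_normal(20)
            y = rng.standard_normal(20) + rng.uniform(-1, 1)
            _, pe = mann_whitney_u(x, y, mode="exact")
            _, pn = mann_whitney_u(x, y, mode="normal_approx")
            assert abs(pe - pn) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            mann_whitney_u([], [1.0])


class TestHodgesLehmann:
    def test_median_of_enumerated_differences(self):
        est, _, _ = hodges_lehmann([1.0, 5.0], [2.0, 3.0])
        # pairwise differences {-1, -2, 3, 2} -> median 0.5
        assert est == pytest.approx(0.5)

    def test_shift_recovery(self):
        x = np.array([1.0, 2.0, 3.0])
        est, _, _ = hodges_lehmann(x, x + 2.0)
        assert est == pytest.approx(-2.0)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=12),
           st.lists(st.floats(-100, 100), min_size=2, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_antisymmetry_and_enumeration(self, xs, ys):
        x, y = np.array(xs), np.array(ys)
        est_xy, lo, hi = hodges_lehmann(x, y)
        est_yx, _, _ = hodges_lehmann(y, x)
        assert est_xy == pytest.approx(-est_yx, abs=1e-9)
        diffs = np.subtract.outer(x, y).ravel()
        assert est_xy == pytest.approx(np.median(diffs), abs=1e-12)
        assert lo <= est_xy <= hi

    def test_matches_r_wilcox_test(self):
        # reference values from R: wilcox.test(x, y, conf.int=TRUE, exact=TRUE)
        x = [20.41, -25.56, 4.18, -5.68, -4.53, -2.16, -20.2, -2.32, -8.65, 33.23]
        y = [5.26, -0.53, 0.19, -3.68, -7.55, -0.91, 7.82, 0.61, 12.58, 1.0,
             3.24, 18.46]
        est, lo, hi = hodges_lehmann(x, y)
        assert est == pytest.approx(-5.275)
        assert lo == pytest.approx(-17.11)
        assert hi == pytest.approx(3.99)

    def test_ci_coverage_under_shift(self, rng):
        cover = 0
        n_sim = 800
        for _ in range(n_sim):
            x = rng.standard_normal(20) + 1.0
            y = rng.standard_normal(20)
            _, lo, hi = hodges_lehmann(x, y)
            cover += lo <= 1.0 <= hi
        assert cover / n_sim >= 0.92  # nominal 95% minus 3%


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [10, 20, 25, 40, 100]).rho == pytest.approx(1.0)
        assert spearman(x, [100, 40, 25, 20, 10]).rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x = rng.standard_normal(6)
        y = rng.standard_normal(6)
        res = spearman(x, y)
        rx = np.argsort(np.argsort(x)) + 1.0
        ry = np.argsort(np.argsort(y)) + 1.0
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(oracle, abs=1e-12)

    def test_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 4, size=30).astype(float)
        y = x + rng.standard_normal(30)
        res = spearman(x, y)
        ref = spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestChiSquare:
    def test_identical_rows_give_zero(self):
        stat, p = chi_square([[5, 10, 5], [5, 10, 5]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_formula_2x2(self):
        # gender split 10/10 vs 12/8
        obs = np.array([[10, 10], [12, 8]])
        stat, p = chi_square(obs)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        hand = ((obs - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(hand, abs=1e-12)
        ref = chi2_contingency(obs, correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_random_2x3_matches_scipy(self, rng):
        obs = rng.integers(1, 30, size=(2, 3))
        stat, p = chi_square(obs)
        ref = chi2_contingency(obs, correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateInputError):
            chi_square([[0, 0], [3, 4]])


class TestKSNormality:
    def test_statistic_matches_naive_loop(self, rng):
        x = rng.standard_normal(40)
        d, _ = ks_normality(x, reps=100, seed=1)
        from scipy.stats import norm
        mu, sd = x.mean(), x.std(ddof=1)
        xs = np.sort(x)
        n = len(xs)
        worst = 0.0
        for i in range(n):
            f = norm.cdf((xs[i] - mu) / sd)
            worst = max(worst, abs((i + 1) / n - f), abs(f - i / n))
        assert d == pytest.approx(worst, abs=1e-12)

    def test_normal_sample_not_rejected(self, rng):
        x = rng.standard_normal(500)
        _, p = ks_normality(x, reps=500, seed=2)
        assert p > 0.05

    def test_exponential_sample_rejected(self, rng):
        x = rng.exponential(size=500)
        _, p = ks_normality(x, reps=500, seed=3)
        assert p < 0.01

    def test_agrees_with_statsmodels_lilliefors(self, rng):
        from statsmodels.stats.diagnostic import lilliefors
        x = rng.exponential(size=80)
        d, p = ks_normality(x, reps=4000, seed=4)
        d_ref, p_ref = lilliefors(x, dist="norm")
        assert d == pytest.approx(d_ref, abs=1e-10)
        # both p-values are approximations; require qualitative agreement
        assert (p < 0.05) == (p_ref < 0.05)

    def test_constant_sample_rejected(self):
        with pytest.raises(DegenerateInputError):
            ks_normality([2.0, 2.0, 2.0, 2.0])


def _trial_from_values(int_values, ctl_values, outcome="twa"):
    patients = []
    for i, v in enumerate(list(int_values) + list(ctl_values)):
        arm = "intervention" if i < len(int_values) else "control"
        s = HypotensionSummary(
            patient_id=f"p{i}", n_episodes=1, total_time=1.0,
            relative_time=1.0, area_under_threshold=float(v) * 100,
            twa=float(v), surgery_duration=100.0)
        patients.append(Patient(patient_id=f"p{i}", arm=arm, summary=s))
    return TrialDataset(patients=patients)


class TestCompareArms:
    def test_identical_arms_null(self, rng):
        v = rng.standard_normal(20)
        c = compare_arms(_trial_from_values(v, v), "twa")
        assert c.hl_difference == pytest.approx(0.0)
        assert c.ci_low <= 0.0 <= c.ci_high
        assert c.p_value == pytest.approx(1.0)

    def test_pure_shift_recovered_with_sign(self, rng):
        ctl = rng.standard_normal(20) + 8.0
        c = compare_arms(_trial_from_values(ctl - 5.0, ctl), "twa")
        assert c.hl_difference == pytest.approx(-5.0)

    def test_midranks_match_scipy_rankdata(self, rng):
        from scipy.stats import rankdata
        x = rng.integers(0, 5, size=25).astype(float)
        np.testing.assert_allclose(midranks(x), rankdata(x))

    def test_missing_summary_is_error(self):
        trial = _trial_from_values([1.0], [2.0])
        trial.patients[0].summary = None
        with pytest.raises(InsufficientDataError):
            compare_arms(trial, "twa")

    def test_type_one_error_calibrated(self, rng):
        """Under the null the Mann-Whitney test in compare_groups rejects at
        the nominal 5% level (within Monte-Carlo error)."""
        rej = 0
        n_sim = 2000
        for _ in range(n_sim):
            x = rng.standard_normal(20)
            y = rng.standard_normal(20)
            rej += compare_groups(x, y).p_value < 0.05
        assert rej / n_sim == pytest.approx(0.05, abs=0.015)
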