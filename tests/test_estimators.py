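"""Univariable MR estimators against independent oracles and planted truth."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

import mrscreen as m
from conftest import harmonized_frame, harmonized_from_sim, random_harmonized


class TestWaldRatio:
    def test_point_estimate(self):
        assert m.wald_ratio(0.1, 0.02, 0.2, 0.05).beta == pytest.approx(2.0)

    def test_first_order_delta_se(self):
        # oracle: out_se / |exp_beta|
        assert m.wald_ratio(0.1, 0.02, 0.2, 0.05).se == pytest.approx(0.05 / 0.1)

    def test_second_order_adds_exposure_noise_term(self):
        est = m.wald_ratio(0.1, 0.02, 0.2, 0.05, second_order=True)
        oracle = np.sqrt(0.05**2 / 0.1**2 + 0.2**2 * 0.02**2 / 0.1**4)
        assert est.se == pytest.approx(oracle)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroDivisionError):
            m.wald_ratio(0.0, 0.02, 0.2, 0.05)


def ivw_oracle(h):
    """Weighted least squares of outcome on exposure effects through the
    origin, weights 1/out_se^2 (normal equations via whitened lstsq)."""
    x = h["beta_exp"].to_numpy()
    y = h["beta_out"].to_numpy()
    sw = 1.0 / h["se_out"].to_numpy()
    coef, *_ = np.linalg.lstsq((x * sw)[:, None], y * sw, rcond=None)
    return float(coef[0])


class TestIVW:
    def test_single_instrument_degrades_to_wald(self):
        h = harmonized_frame([0.1], 0.02, [0.2], 0.05)
        est = m.ivw(h)
        wald = m.wald_ratio(0.1, 0.02, 0.2, 0.05)
        assert (est.beta, est.se) == (wald.beta, wald.se)

    def test_equal_weights_symmetry(self):
        h = harmonized_frame([1.0, 1.0, 1.0], 0.01, [0.4, 0.5, 0.6], 0.05)
        assert m.ivw(h, effects="fixed").beta == pytest.approx(0.5)

    def test_matches_weighted_regression_oracle(self, rng):
        for _ in range(50):
            h = random_harmonized(rng, int(rng.integers(3, 21)))
            assert abs(m.ivw(h, effects="fixed").beta - ivw_oracle(h)) < 1e-10

    def test_random_effects_inflate_se_by_overdispersion(self, rng):
        h = random_harmonized(rng, 10)
        fixed = m.ivw(h, effects="fixed")
        random_ = m.ivw(h, effects="random")
        q, df, _ = m.cochran_q(h)
        assert random_.beta == fixed.beta
        assert random_.se == pytest.approx(fixed.se * max(1.0, np.sqrt(q / df)))

    def test_auto_uses_fixed_under_homogeneity(self):
        h = harmonized_frame([0.2, 0.3, 0.25], 0.01, [0.1, 0.15, 0.125], 0.05)
        assert m.ivw(h, effects="auto").method == "ivw_fixed"

    def test_no_instruments_raises(self):
        with pytest.raises(m.InsufficientInstrumentsError):
            m.ivw(harmonized_frame([], 0.01, [], 0.05))


class TestMREgger:
    def test_exact_linear_points_recovered(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        h = harmonized_frame(x, 0.01, 0.1 + 0.3 * x, 0.05)
        slope, intercept = m.mr_egger(h)
        assert slope.beta == pytest.approx(0.3, abs=1e-12)
        assert intercept.beta == pytest.approx(0.1, abs=1e-12)
        assert slope.se == pytest.approx(0.0, abs=1e-12)
        assert intercept.se == pytest.approx(0.0, abs=1e-12)

    def test_no_pleiotropy_gives_zero_intercept(self):
        x = np.array([0.1, -0.2, 0.3, -0.15, 0.25])
        h = harmonized_frame(x, 0.01, 0.4 * x, 0.05)
        _, intercept = m.mr_egger(h)
        assert intercept.beta == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels_wls_oracle(self, rng):
        for _ in range(50):
            h = random_harmonized(rng, int(rng.integers(3, 21)))
            slope, intercept = m.mr_egger(h)
            sign = np.where(h["beta_exp"] < 0, -1.0, 1.0)
            x = (h["beta_exp"] * sign).to_numpy()
            y = (h["beta_out"] * sign).to_numpy()
            fit = sm.WLS(y, sm.add_constant(x), weights=1.0 / h["se_out"] ** 2).fit()
            assert abs(slope.beta - fit.params[1]) < 1e-10
            assert abs(intercept.beta - fit.params[0]) < 1e-10
            assert abs(slope.se - fit.bse[1]) < 1e-10
            assert abs(intercept.pval - fit.pvalues[0]) < 1e-10

    def test_requires_three_instruments(self):
        with pytest.raises(m.InsufficientInstrumentsError):
            m.mr_egger(harmonized_frame([0.1, 0.2], 0.01, [0.1, 0.2], 0.05))


def weighted_median_oracle(ratios, weights):
    """Direct evaluation of the interpolation definition."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    for i in range(len(r) - 1):
        if s[i] <= 0.5 <= s[i + 1]:
            return r[i] + (r[i + 1] - r[i]) * (0.5 - s[i]) / (s[i + 1] - s[i])
    return r[0] if 0.5 < s[0] else r[-1]


class TestWeightedMedian:
    def h_for_ratios(self, ratios, weights):
        # exposure beta 1 everywhere: ratio = beta_out, weight = 1/se_out^2
        ratios = np.asarray(ratios, float)
        se_out = 1.0 / np.sqrt(np.asarray(weights, float))
        return harmonized_frame(np.ones_like(ratios), 0.01, ratios, se_out)

    def test_middle_order_statistic(self):
        h = self.h_for_ratios([0.2, 0.5, 0.9], [1, 1, 1])
        assert m.weighted_median(h, n_boot=100, seed=1).beta == pytest.approx(0.5)

    def test_majority_weight_ratio_wins(self):
        h = self.h_for_ratios([0.2, 0.7, 0.9], [0.2, 0.6, 0.2])
        assert m.weighted_median(h, n_boot=100, seed=1).beta == pytest.approx(0.7)

    def test_matches_interpolation_oracle(self, rng):
        for _ in range(50):
            k = int(rng.integers(3, 10))
            ratios = rng.normal(0.3, 0.5, k)
            weights = rng.uniform(0.5, 3.0, k)
            h = self.h_for_ratios(ratios, weights)
            est = m.weighted_median(h, n_boot=100, seed=2)
            assert abs(est.beta - weighted_median_oracle(ratios, weights)) < 1e-10

    def test_bootstrap_se_reproducible(self):
        h = self.h_for_ratios([0.2, 0.5, 0.9, 0.4], [1, 2, 1, 3])
        a = m.weighted_median(h, n_boot=500, seed=5)
        b = m.weighted_median(h, n_boot=500, seed=5)
        assert a.se == b.se
        assert a.se > 0


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        h = harmonized_frame([0.1, 0.2, 0.4], 0.01, [0.05, 0.1, 0.2], 0.05)
        q, df, pval = m.cochran_q(h)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert pval == pytest.approx(1.0)

    def test_two_instruments_one_degree_of_freedom(self):
        h = harmonized_frame([0.1, 0.2], 0.01, [0.1, 0.1], 0.05)
        _, df, _ = m.cochran_q(h)
        assert df == 1

    def test_null_mean_matches_chi_square_moment(self):
        """Under homogeneity with precisely-measured exposures, Q ~ chi2(J-1):
        its empirical mean over 2,000 replicates sits at J - 1."""
        j, reps = 10, 2000
        qs = np.empty(reps)
        for i in range(reps):
            cfg = m.SimulationConfig(
                n_snps=j, n_exp=10**9, causal_beta=0.3, seed=1_000_000 + i
            )
            e, o, _ = m.simulate_summary_stats(cfg)
            qs[i], _, _ = m.cochran_q(harmonized_from_sim(e, o))
        se_mean = np.sqrt(2.0 * (j - 1) / reps)
        assert abs(qs.mean() - (j - 1)) < 3 * se_mean


def plant_outlier(h, shift_se=10.0):
    """Displace the outcome beta of the strongest instrument."""
    k = int(np.argmax(np.abs(h["beta_exp"].to_numpy())))
    h = h.copy()
    h.loc[k, "beta_out"] += shift_se * h.loc[k, "se_out"]
    return h, k


class TestMRPresso:
    def test_minimum_instrument_guard(self):
        h = harmonized_frame([0.1, 0.2, 0.3], 0.01, [0.1, 0.2, 0.3], 0.05)
        with pytest.raises(m.InsufficientInstrumentsError, match="4"):
            m.mr_presso(h)

    def test_planted_outlier_flagged(self):
        cfg = m.SimulationConfig(n_snps=30, n_exp=100000, causal_beta=0.3, seed=51)
        e, o, _ = m.simulate_summary_stats(cfg)
        h, k = plant_outlier(harmonized_from_sim(e, o))
        res = m.mr_presso(h, n_sim=1000, seed=1)
        assert k in res.outlier_indices
        assert res.global_pval < 0.05
        assert res.distortion_pval is not None

    def test_homogeneous_data_not_flagged(self):
        cfg = m.SimulationConfig(n_snps=30, n_exp=100000, causal_beta=0.3, seed=52)
        e, o, _ = m.simulate_summary_stats(cfg)
        res = m.mr_presso(harmonized_from_sim(e, o), n_sim=1000, seed=2)
        assert res.global_pval > 0.05
        assert len(res.outlier_indices) == 0

    def test_reproducible_under_seed(self):
        cfg = m.SimulationConfig(n_snps=20, n_exp=100000, causal_beta=0.3, seed=53)
        e, o, _ = m.simulate_summary_stats(cfg)
        h, _ = plant_outlier(harmonized_from_sim(e, o))
        a = m.mr_presso(h, n_sim=500, seed=9)
        b = m.mr_presso(h, n_sim=500, seed=9)
        assert a.global_pval == b.global_pval
        np.testing.assert_array_equal(a.outlier_pvals, b.outlier_pvals)


def cooks_oracle(h):
    """Cook's distances from statsmodels OLS influence on the whitened
    through-origin design."""
    sw = 1.0 / h["se_out"].to_numpy()
    x = (h["beta_exp"].to_numpy() * sw)[:, None]
    y = h["beta_out"].to_numpy() * sw
    fit = sm.OLS(y, x).fit()
    return fit.get_influence().cooks_distance[0]


class TestCooksExclusion:
    def test_exact_fit_excludes_nothing(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        h = harmonized_frame(x, 0.01, 0.4 * x, 0.05)
        assert len(m.cooks_exclusion(h)) == 0

    def test_planted_high_leverage_outlier_excluded(self):
        cfg = m.SimulationConfig(n_snps=30, n_exp=100000, causal_beta=0.3, seed=54)
        e, o, _ = m.simulate_summary_stats(cfg)
        h, k = plant_outlier(harmonized_from_sim(e, o))
        assert k in m.cooks_exclusion(h)

    def test_matches_statsmodels_influence_oracle(self, rng):
        for _ in range(20):
            h = random_harmonized(rng, int(rng.integers(4, 15)))
            d = cooks_oracle(h)
            threshold = 4.0 / len(h)
            assert set(m.cooks_exclusion(h)) == set(np.flatnonzero(d > threshold))

    def test_default_threshold_rule(self):
        cfg = m.SimulationConfig(n_snps=12, n_exp=100000, causal_beta=0.3, seed=55)
        e, o, _ = m.simulate_summary_stats(cfg)
        h = harmonized_from_sim(e, o)
        assert set(m.cooks_exclusion(h)) == set(m.cooks_exclusion(h, threshold=4.0 / 12))


class TestRerunAfterRemoval:
    def test_empty_exclusion_is_identity(self, rng):
        h = random_harmonized(rng, 8)
        before = m.estimate_all(h, n_boot=100, seed=3)
        after = m.rerun_after_removal(h, [], n_boot=100, seed=3)
        assert before["ivw"].beta == after["ivw"].beta
        assert before["weighted_median"].se == after["weighted_median"].se

    def test_removing_planted_outlier_reduces_bias(self):
        # the PRESSO outlier p-value floor is 1/(n_sim+1) before Bonferroni,
        # so detection at alpha 0.05/J needs n_sim > J/0.05
        improved = flagged = 0
        for i in range(20):
            cfg = m.SimulationConfig(n_snps=30, n_exp=100000, causal_beta=0.3, seed=600 + i)
            e, o, _ = m.simulate_summary_stats(cfg)
            h, k = plant_outlier(harmonized_from_sim(e, o))
            res = m.mr_presso(h, n_sim=1000, seed=i)
            if len(res.outlier_indices) == 0:
                continue
            flagged += 1
            b_all = m.ivw(h, effects="fixed").beta
            b_rm = m.rerun_after_removal(h, res.outlier_indices)["ivw_fixed"].beta
            improved += abs(b_rm - 0.3) < abs(b_all - 0.3)
        assert flagged >= 18
        assert improved == flagged

    def test_too_few_survivors_raises(self, rng):
        h = random_harmonized(rng, 4)
        with pytest.raises(m.InsufficientInstrumentsError):
            m.rerun_after_removal(h, [0, 1, 2])


class TestSensitivityReport:
    def test_report_links_all_diagnostics(self):
        cfg = m.SimulationConfig(n_snps=25, n_exp=100000, causal_beta=0.3, seed=56)
        e, o, _ = m.simulate_summary_stats(cfg)
        h, k = plant_outlier(harmonized_from_sim(e, o))
        rep = m.sensitivity_report(h, n_sim=500, seed=4, n_boot=100)
        assert rep.q_df == len(h) - 1
        assert k in rep.excluded
        assert rep.post_removal is not None
        assert set(rep.presso.outlier_indices).issubset(range(len(h)))


class TestReverseMR:
    def make_reverse_pair(self, seed):
        # outcome trait carries its own instruments; exposure causes outcome
        # (a = 0.5) with no reverse path
        cfg = m.SimulationConfig(n_snps=30, n_exp=100000, gamma_sd=0.05, seed=seed)
        exposure, outcome_trait, _, _ = m.simulate_mediation_stats(
            cfg, a=0.5, b=0.0, c=0.0, n_med=8143, n_snps_mediator=30, delta_sd=0.3
        )
        return exposure, outcome_trait

    def test_strict_selection_threshold(self):
        exposure, outcome = self.make_reverse_pair(61)
        outcome = outcome.copy()
        outcome["P"] = 6e-8  # just above genome-wide significance
        with pytest.raises(m.InsufficientInstrumentsError):
            m.reverse_mr(outcome, exposure, None, n_boot=100, seed=1)

    def test_no_reverse_path_gives_null_estimates(self):
        covered = 0
        for i in range(100):
            exposure, outcome = self.make_reverse_pair(700 + i)
            try:
                rev = m.reverse_mr(outcome, exposure, None, n_boot=50, seed=i)
            except m.InsufficientInstrumentsError:
                continue
            e = rev["ivw"]
            covered += e.ci_low <= 0.0 <= e.ci_high
        assert covered >= 90

    def test_symmetric_null_pvalues_uniform_both_directions(self):
        fwd, rev = [], []
        for i in range(100):
            cfg = m.SimulationConfig(n_snps=30, n_exp=100000, gamma_sd=0.05, seed=900 + i)
            exposure, outcome_trait, _, _ = m.simulate_mediation_stats(
                cfg, a=0.0, b=0.0, c=0.0, n_med=100000, n_snps_mediator=30, delta_sd=0.05
            )
            h_fwd, _, _ = m.select_instruments(exposure, outcome_trait, None)
            if len(h_fwd) >= 2:
                fwd.append(m.ivw(h_fwd, effects="fixed").pval)
            try:
                rev.append(
                    m.reverse_mr(
                        outcome_trait, exposure, None,
                        p_threshold=1e-5, n_boot=50, seed=i,
                    )["ivw_fixed"].pval
                )
            except (m.InsufficientInstrumentsError, KeyError):
                pass
        assert sps.kstest(fwd, "uniform").pvalue >= 0.01
        assert sps.kstest(rev, "uniform").pvalue >= 0.01
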