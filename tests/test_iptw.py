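import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import clustercausal as cc
from clustercausal.iptw import (
    IPTW,
    EstimateResult,
    fit_propensity_logistic,
    stabilized_weights,
    weighted_smd,
)
from clustercausal.parametric import ParametricSimulator
from conftest import randomized_config


class TestStabilizedWeights:
    def test_constant_ps_at_prevalence_gives_unit_weights(self):
        t = np.array([1, 0, 1, 0])
        w = stabilized_weights(np.full(4, 0.5), t)
        assert np.allclose(w, 1.0)

    def test_treated_weight_is_prevalence_over_ps(self):
        t = np.array([1, 0])
        w = stabilized_weights(np.array([0.25, 0.5]), t)
        assert w[0] == pytest.approx(0.5 / 0.25)  # = 2.0

    def test_mean_weight_near_one(self, small_cohort):
        ps = fit_propensity_logistic(small_cohort).clipped()
        w = stabilized_weights(ps, small_cohort["treatment"].to_numpy())
        assert w.mean() == pytest.approx(1.0, abs=3.0 / np.sqrt(len(w)))

    def test_degenerate_ps_rejected_when_unclipped(self):
        with pytest.raises(ValueError):
            stabilized_weights(np.array([0.0, 0.5]), np.array([1, 0]), clip=(0.0, 1.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            stabilized_weights(np.array([0.5]), np.array([1, 0]))


class TestPropensityModel:
    def test_null_model_coefficients_near_zero(self, randomized_cohort):
        ps = fit_propensity_logistic(randomized_cohort)
        assert ps.converged
        for name in ps.covariates:
            assert abs(ps.params[name]) < 3.5 * ps.bse[name], name

    def test_recovers_allocation_coefficients(self):
        cfg = cc.ScenarioConfig(n_clusters=100, mean_cluster_size=100,
                                delta_interaction=0.0, seed=31)
        df = ParametricSimulator(cfg).simulate(0)
        ps = fit_propensity_logistic(df)
        truth = dict(zip(("x1", "x2", "x3", "x4", "x5"), cfg.beta_x_treat))
        truth.update({"z1": cfg.gamma_z, "z2": cfg.gamma_z})
        for name, val in truth.items():
            assert abs(ps.params[name] - val) < 3.5 * ps.bse[name], name

    def test_interaction_omission_attenuates_but_keeps_sign(self):
        cfg = cc.ScenarioConfig(n_clusters=100, mean_cluster_size=100, seed=32)
        df = ParametricSimulator(cfg).simulate(0)
        ps = fit_propensity_logistic(df)  # main effects only
        assert ps.params["z1"] > 0 and ps.params["x1"] > 0

    def test_saturated_two_by_two_matches_cell_means(self):
        rng = np.random.default_rng(0)
        x = np.repeat([0, 1], 200)
        t = np.concatenate([(rng.random(200) < 0.3), (rng.random(200) < 0.7)]).astype(int)
        df = pd.DataFrame({"x1": x, "treatment": t})
        ps = fit_propensity_logistic(df, covariates=["x1"])
        for lvl in (0, 1):
            cell = t[x == lvl].mean()
            assert np.allclose(ps.fitted[x == lvl], cell, atol=1e-6)

    def test_missing_covariate_rejected(self, small_cohort):
        with pytest.raises(KeyError):
            fit_propensity_logistic(small_cohort, covariates=["nope"])


class TestIPTWEstimation:
    def test_randomized_treatment_recovers_conditional_logor(self):
        cfg = randomized_config(total_target=4000, seed=41)
        df = ParametricSimulator(cfg).simulate(0)
        res = IPTW(df).fit()
        assert res.converged
        assert abs(res.estimate - 0.4055) < 3 * res.se

    def test_weighting_reduces_confounding_bias_under_null(self):
        cfg = cc.ScenarioConfig(n_clusters=30, mean_cluster_size=100,
                                total_target=3000, tau=0.0, gamma_z=0.9163, seed=43)
        sim = ParametricSimulator(cfg)
        wins, naive_abs, iptw_abs = 0, [], []
        n_reps = 20
        for rep in range(n_reps):
            df = sim.simulate(rep)
            naive = sm.Logit(df["outcome"], sm.add_constant(df["treatment"])).fit(disp=0)
            res = IPTW(df).fit()
            naive_abs.append(abs(naive.params["treatment"]))
            iptw_abs.append(abs(res.estimate))
            wins += abs(res.estimate) < abs(naive.params["treatment"])
        assert np.mean(iptw_abs) < np.mean(naive_abs)
        assert wins >= int(0.7 * n_reps)

    def test_correctly_specified_iptw_stable_across_sample_sizes(self):
        """With the interaction included the PS model is correct; the weighted
        random-intercept logit then converges to a partially marginalized
        log-OR a few percent below tau.  Check the 1/sqrt(n) shrinkage of the
        spread and that the large-n estimate stays within that estimand gap."""
        emp_se, means = {}, {}
        for total, m in ((2000, 20), (10_000, 100), (50_000, 500)):
            cfg = cc.ScenarioConfig(n_clusters=m, mean_cluster_size=total // m,
                                    total_target=total, gamma_z=0.4055, seed=77)
            sim = ParametricSimulator(cfg)
            ests = [IPTW(sim.simulate(cc.derived_seed(9, 0, rep)),
                         include_interaction=True).fit().estimate
                    for rep in range(6)]
            emp_se[total] = np.std(ests, ddof=1)
            means[total] = np.mean(ests)
        assert emp_se[50_000] < emp_se[10_000] < emp_se[2_000]
        assert abs(means[50_000] - 0.4055) < 0.08

    def test_weighted_balance_below_point_one(self):
        cfg = cc.ScenarioConfig(n_clusters=50, mean_cluster_size=200, seed=44)
        df = ParametricSimulator(cfg).simulate(0)
        res = IPTW(df).fit()
        assert res.balance().mean() < 0.1

    def test_weighting_improves_balance(self, small_cohort):
        res = IPTW(small_cohort).fit()
        raw = weighted_smd(small_cohort, res.model.covariates, np.ones(len(small_cohort)))
        assert res.balance().mean() < raw.mean()

    def test_single_cluster_rejected(self, small_cohort):
        df = small_cohort.copy()
        df["cluster_id"] = 0
        with pytest.raises(ValueError):
            IPTW(df)

    def test_summary_mentions_estimate(self, small_cohort):
        res = IPTW(small_cohort).fit()
        assert "treatment log-OR" in res.summary()


class TestEstimateResult:
    def test_wald_interval_construction(self):
        r = EstimateResult.from_wald(0.5, 0.1, estimator="CF")
        assert r.ci_low == pytest.approx(0.5 - 1.96 * 0.1)
        assert r.ci_high == pytest.approx(0.5 + 1.96 * 0.1)
        assert r.ci_low < r.estimate < r.ci_high
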