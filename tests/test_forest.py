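import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import clustercausal as cc
from clustercausal.forest import (
    CausalForest,
    ForestOptions,
    _influence_se,
    aipw_ate,
    fit_nuisance_forests,
)
from clustercausal.parametric import ParametricSimulator
from conftest import collapsible_randomized_config, randomized_config


def _make_cohort(n, seed, effect_by_x1=0.0, base_rate=0.3):
    """Hand-built cohort: randomized T, optional risk-difference effect by x1."""
    rng = np.random.default_rng(seed)
    x = pd.DataFrame({
        "x1": (rng.random(n) < 0.5).astype(int),
        "x2": rng.standard_normal(n),
        "x3": rng.standard_normal(n),
    })
    t = (rng.random(n) < 0.5).astype(int)
    p = base_rate + effect_by_x1 * t * x["x1"]
    y = (rng.random(n) < p).astype(int)
    df = x.copy()
    df["cluster_id"] = np.arange(n) % 10
    df["treatment"] = t
    df["outcome"] = y
    return df


class TestNuisanceForests:
    def test_null_signal_propensity_is_flat(self):
        cfg = randomized_config(total_target=10_000, mean_cluster_size=500, seed=51)
        df = ParametricSimulator(cfg).simulate(0)
        e_hat, y_hat = fit_nuisance_forests(
            df, cc.CONFOUNDERS, ForestOptions(seed=1, n_nuisance_trees=200))
        assert abs(e_hat.mean() - 0.5) < 0.03
        assert e_hat.std() < 0.05
        assert np.all((e_hat >= 0.02) & (e_hat <= 0.98))

    def test_step_function_outcome_learned(self):
        rng = np.random.default_rng(3)
        n = 10_000
        df = pd.DataFrame({
            "x4": rng.standard_normal(n),
            "x5": rng.standard_normal(n),
        })
        df["treatment"] = (rng.random(n) < 0.5).astype(int)
        df["outcome"] = (df["x4"] > 0).astype(int)
        _, y_hat = fit_nuisance_forests(df, ["x4", "x5"], ForestOptions(seed=2))
        assert np.mean((y_hat - df["outcome"]) ** 2) < 0.02


class TestHonestForest:
    def test_homogeneous_effect_shows_no_spurious_heterogeneity(self):
        """Constant effect, pure-noise covariates: CATE spread stays at the
        leaf-estimation noise floor (measured with oracle nuisances)."""
        cfg = collapsible_randomized_config(total_target=10_000,
                                            mean_cluster_size=500, seed=53)
        sim = ParametricSimulator(cfg)
        df = sim.simulate(0)
        n = len(df)
        l0 = sim.intercepts[1]
        m_true = 0.5 * (expit(l0 + cfg.tau) + expit(l0))
        oracle = CausalForest(df, options=ForestOptions(
            n_trees=200, seed=3,
            external_ps=np.full(n, 0.5), external_y_hat=np.full(n, m_true))).fit()
        floor = np.nanstd(oracle.cate_)
        cf = CausalForest(df, options=ForestOptions(n_trees=200, seed=3)).fit()
        assert np.nanstd(cf.cate_) < 1.25 * floor
        assert np.nanstd(cf.cate_) < 0.06
        true_rd = sim.true_effect("risk_difference")
        assert abs(np.nanmean(cf.cate_) - true_rd) < 0.02

    def test_two_subgroup_heterogeneity_recovered(self):
        df = _make_cohort(10_000, seed=5, effect_by_x1=0.2)
        cf = CausalForest(df, covariates=["x1", "x2", "x3"],
                          options=ForestOptions(n_trees=100, seed=4)).fit()
        x1 = df["x1"].to_numpy()
        assert abs(cf.cate_[x1 == 1].mean() - 0.2) < 0.05
        assert abs(cf.cate_[x1 == 0].mean() - 0.0) < 0.05

    def test_cluster_subsampling_keeps_whole_clusters(self, small_cohort):
        opts = ForestOptions(n_trees=10, seed=5)
        cf = CausalForest(small_cohort, options=opts, cluster_col="cluster_id").fit()
        codes = small_cohort["cluster_id"].to_numpy()
        counts = pd.Series(codes).value_counts()
        for ht in cf.trees:
            sub = pd.Series(codes[ht.subsample]).value_counts()
            for cl, k in sub.items():
                assert k == counts[cl]

    def test_honest_splits_ignore_estimate_half_outcomes(self, small_cohort):
        n = len(small_cohort)
        ext = ForestOptions(n_trees=1, seed=6,
                            external_ps=np.full(n, 0.5),
                            external_y_hat=np.zeros(n))
        cf1 = CausalForest(small_cohort, options=ext).fit()
        est_row = cf1.trees[0].estimate_rows[0]
        perturbed = small_cohort.copy()
        perturbed.loc[est_row, "outcome"] = 1 - perturbed.loc[est_row, "outcome"]
        cf2 = CausalForest(perturbed, options=ext).fit()
        t1, t2 = cf1.trees[0].tree.tree_, cf2.trees[0].tree.tree_
        assert np.array_equal(t1.feature, t2.feature)
        assert np.array_equal(t1.threshold, t2.threshold)

    def test_external_ps_equal_to_internal_reproduces_cf(self, small_cohort):
        opts = ForestOptions(n_trees=20, seed=7)
        cf = CausalForest(small_cohort, options=opts).fit()
        opts2 = ForestOptions(n_trees=20, seed=7, external_ps=cf.e_hat,
                              external_y_hat=cf.y_hat)
        cf2 = CausalForest(small_cohort, options=opts2).fit()
        assert cf.ate("risk_difference") == pytest.approx(cf2.ate("risk_difference"))

    def test_deterministic_under_seed(self, small_cohort):
        opts = ForestOptions(n_trees=15, seed=8)
        a = CausalForest(small_cohort, options=opts).fit()
        b = CausalForest(small_cohort, options=opts).fit()
        assert a.ate("marginal_logor") == b.ate("marginal_logor")
        assert np.array_equal(a.cate_, b.cate_)

    def test_single_arm_cohort_rejected(self, small_cohort):
        df = small_cohort.copy()
        df["treatment"] = 1
        with pytest.raises(ValueError):
            CausalForest(df)


class TestPrediction:
    def test_prediction_is_weighted_average_of_tree_leaf_effects(self, small_cohort):
        cf = CausalForest(small_cohort, options=ForestOptions(n_trees=5, seed=9)).fit()
        X = small_cohort[cf.model.covariates].to_numpy(float)[:20]
        vals = np.array([ht.node_values[ht.tree.apply(X)] for ht in cf.trees])
        wts = np.array([ht.node_den[ht.tree.apply(X)] for ht in cf.trees])
        manual = (vals * wts).sum(axis=0) / wts.sum(axis=0)
        assert np.allclose(cf.predict_cate(small_cohort.head(20)), manual)
        # prediction lies inside the envelope of per-tree leaf effects
        assert np.all(cf.predict_cate(small_cohort.head(20)) <= vals.max(axis=0) + 1e-12)
        assert np.all(cf.predict_cate(small_cohort.head(20)) >= vals.min(axis=0) - 1e-12)

    def test_single_tree_prediction_equals_leaf_value(self, small_cohort):
        cf = CausalForest(small_cohort, options=ForestOptions(n_trees=1, seed=10)).fit()
        ht = cf.trees[0]
        X = small_cohort[cf.model.covariates].to_numpy(float)[:5]
        leaves = ht.tree.apply(X)
        assert np.allclose(cf.predict_cate(small_cohort.head(5)), ht.node_values[leaves])

    def test_permutation_equivariance(self, small_cohort):
        cf = CausalForest(small_cohort, options=ForestOptions(n_trees=5, seed=11)).fit()
        rows = small_cohort.head(50)
        perm = np.random.default_rng(0).permutation(50)
        assert np.allclose(cf.predict_cate(rows)[perm],
                           cf.predict_cate(rows.iloc[perm]))


class TestAIPW:
    def test_oracle_nuisances_give_unbiased_ate(self):
        cfg = cc.ScenarioConfig(n_clusters=20, mean_cluster_size=100,
                                total_target=2000, seed=55)
        sim = ParametricSimulator(cfg)
        a0, l0 = sim.intercepts
        truth = sim.true_effect("risk_difference")
        ests = []
        for rep in range(100):
            df = sim.simulate(rep)
            z1, z2 = df["z1"].to_numpy(), df["z2"].to_numpy()
            cov = {k: df[k].to_numpy() for k in
                   ("x1", "x2", "x3", "x4", "x5", "x6", "x7")}
            e = expit(a0 + sim._lp_treatment(cov, z1, z2))
            lpy = sim._lp_outcome_base(cov, z1, z2)
            p1, p0 = expit(l0 + cfg.tau + lpy), expit(l0 + lpy)
            m = e * p1 + (1 - e) * p0
            res = aipw_ate(df["outcome"], df["treatment"],
                           np.clip(e, 0.02, 0.98), m, p1 - p0)
            ests.append(res.ate_rd)
        ests = np.asarray(ests)
        mcse = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - truth) < 3 * mcse

    def test_constant_scores_give_zero_se(self):
        n = 50
        y = np.zeros(n)
        t = np.tile([0, 1], 25).astype(float)
        res = aipw_ate(y, t, np.full(n, 0.5), np.zeros(n), np.full(n, 0.0))
        assert res.se_rd == 0.0
        assert res.ate_rd == 0.0

    def test_null_effect_calibration(self):
        cfg = cc.ScenarioConfig(n_clusters=15, mean_cluster_size=100,
                                total_target=1500, tau=0.0, seed=57)
        sim = ParametricSimulator(cfg)
        hits = 0
        n_reps = 60
        for rep in range(n_reps):
            df = sim.simulate(rep)
            cf = CausalForest(df, options=ForestOptions(
                n_trees=50, n_nuisance_trees=25, seed=rep)).fit()
            rd, se = cf.ate("risk_difference")
            hits += abs(rd) < 3 * se
        assert hits / n_reps >= 0.85

    def test_degenerate_prevalence_leaves_logor_undefined(self):
        n = 100
        y = np.ones(n)
        t = np.tile([0, 1], 50).astype(float)
        res = aipw_ate(y, t, np.full(n, 0.5), np.ones(n) * 1.2, np.full(n, 0.5))
        assert np.isnan(res.logor)
        assert np.isfinite(res.ate_rd)

    def test_cluster_robust_se_exceeds_iid_on_correlated_scores(self):
        rng = np.random.default_rng(12)
        clusters = np.repeat(np.arange(20), 50)
        psi = rng.standard_normal(20)[clusters] + 0.3 * rng.standard_normal(1000)
        assert _influence_se(psi, clusters) > _influence_se(psi, None)


class TestForestOptions:
    @pytest.mark.parametrize("bad", [
        dict(honesty_fraction=0.0),
        dict(honesty_fraction=1.0),
        dict(subsample_fraction=0.0),
        dict(external_ps=np.array([0.0, 0.5])),
    ])
    def test_invalid_options_rejected(self, bad):
        with pytest.raises(ValueError):
            ForestOptions(**bad)
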