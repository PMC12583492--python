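"""Honest causal forests with doubly robust average-treatment-effect estimation.

The forest follows the orthogonalized ("residual-on-residual") construction:
regression forests first estimate the treatment propensity e(x) = E[T|X=x]
and the marginal outcome m(x) = E[Y|X=x] out-of-bag; each causal tree is then
grown on the centred data (Y - m̂, T - ê).  Trees are *honest double-sample*
trees: every tree draws a subsample without replacement, splits it into a
split half and an estimate half, chooses its splits using the split half only
and populates its leaf treatment effects from the estimate half only.  This
separation removes the adaptive-selection bias of fitting and evaluating
effects on the same rows, at the price of using half the data per task.

Within a node the orthogonalized effect estimate is

    tau_node = sum(Tt_i Yt_i) / sum(Tt_i^2),     Tt = T - ê,  Yt = Y - m̂,

and splits maximise the between-child heterogeneity sum_child w_child
tau_child^2.  This criterion is implemented exactly as a weighted
least-squares split search on the pseudo-outcome r_i = Yt_i / Tt_i with
weights Tt_i^2 (the weighted node mean of r is tau_node and weighted-MSE
improvement equals the heterogeneity gain), which lets each tree use
sklearn's exhaustive axis-aligned splitter.

Variants
--------
* default ("CF"): internal regression-forest nuisances;
* cluster subsampling ("CF-clusterID"): tree subsamples are unions of whole
  clusters and the ATE variance uses cluster-summed influence functions;
* external propensity ("CF-PS"): a user-supplied propensity vector (e.g. from
  the IPTW logistic model) replaces the internal ê everywhere.

The ATE is the mean of the doubly robust (AIPW) scores

    G_i = taû(x_i) + (T_i - ê_i)/(ê_i (1 - ê_i)) (Y_i - m̂_i - (T_i - ê_i) taû(x_i)),

reported on the risk-difference scale or, after transforming the AIPW
potential-outcome prevalences, as a marginal log odds ratio with a
delta-method standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.tree import DecisionTreeRegressor

from .config import CONFOUNDERS, derived_seed
from .iptw import EstimateResult

#: Propensity clipping bounds used inside the forest machinery.
FOREST_PS_CLIP = (0.02, 0.98)


@dataclass
class ForestOptions:
    """Tuning parameters of the causal forest.

    ``n_trees`` (200) and ``honesty_fraction`` (0.5, the fraction of each
    subsample used for determining splits) are the two settings the study
    design fixes; the rest are kept at conventional forest defaults.
    ``variance_group_size`` is the tree-group size for grouped variance
    estimation and has no effect on point estimates.
    """

    n_trees: int = 200
    subsample_fraction: float = 0.5
    honesty_fraction: float = 0.5
    min_leaf_size: int = 5
    max_depth: int | None = None
    cluster_ids: np.ndarray | None = None
    external_ps: np.ndarray | None = None
    external_y_hat: np.ndarray | None = None
    seed: int = 0
    ps_clip: tuple = FOREST_PS_CLIP
    n_nuisance_trees: int | None = None
    nuisance_max_features: int | None = None
    variance_group_size: int = 50

    def __post_init__(self):
        if not 0.0 < self.honesty_fraction < 1.0:
            raise ValueError("honesty_fraction must lie strictly inside (0, 1)")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.external_ps is not None:
            eps = np.asarray(self.external_ps, dtype=float)
            if np.any(eps <= 0.0) or np.any(eps >= 1.0):
                raise ValueError("external_ps must lie strictly inside (0, 1)")
            self.external_ps = eps


def fit_nuisance_forests(cohort: pd.DataFrame, covariates, options: ForestOptions):
    """Out-of-bag regression-forest predictions of propensity and outcome.

    Each row's prediction uses only trees whose bootstrap sample excluded it.
    The propensity predictions are clipped to ``options.ps_clip`` before use.
    """
    X = cohort[list(covariates)].to_numpy(dtype=float)
    t = cohort["treatment"].to_numpy(dtype=float)
    y = cohort["outcome"].to_numpy(dtype=float)
    n_trees = options.n_nuisance_trees or _default_nuisance_trees(options.n_trees)
    e_hat = _oob_regression_forest(X, t, n_trees, options, derived_seed(options.seed, 0),
                                   cluster_ids=options.cluster_ids)
    y_hat = _oob_regression_forest(X, y, n_trees, options, derived_seed(options.seed, 1),
                                   cluster_ids=options.cluster_ids)
    e_hat = np.clip(e_hat, options.ps_clip[0], options.ps_clip[1])
    return e_hat, y_hat


def _default_nuisance_trees(n_trees: int) -> int:
    # smaller forests suffice for the orthogonalization targets; their OOB
    # noise is absorbed by the doubly robust correction
    return max(50, int(n_trees) // 4)


def _draw_subsample_halves(rng: np.random.Generator, n: int, options: ForestOptions,
                           cluster_codes: np.ndarray | None):
    """Split-half and estimate-half row indices for one tree.

    Rows (or whole clusters, when ``cluster_codes`` is given) are subsampled
    without replacement at ``subsample_fraction``; the subsample is then
    divided into the split half (fraction ``honesty_fraction``) and the
    estimate half.
    """
    if cluster_codes is not None:
        m = int(cluster_codes.max()) + 1
        n_sub = max(2, int(round(options.subsample_fraction * m)))
        chosen = rng.choice(m, size=min(n_sub, m), replace=False)
        n_split = min(max(1, int(round(options.honesty_fraction * len(chosen)))),
                      len(chosen) - 1)
        split_cl = np.zeros(m, dtype=bool)
        split_cl[chosen[:n_split]] = True
        est_cl = np.zeros(m, dtype=bool)
        est_cl[chosen[n_split:]] = True
        return np.flatnonzero(split_cl[cluster_codes]), np.flatnonzero(est_cl[cluster_codes])
    n_sub = max(4, int(round(options.subsample_fraction * n)))
    sub = rng.choice(n, size=min(n_sub, n), replace=False)
    n_split = min(max(2, int(round(options.honesty_fraction * len(sub)))), len(sub) - 2)
    return sub[:n_split], sub[n_split:]


def _node_means_with_fallback(tree, X_est, target_est):
    """Per-node estimate-half means; empty nodes inherit the parent's mean."""
    tr = tree.tree_
    n_nodes = tr.node_count
    path = tree.decision_path(X_est)
    cnt = np.asarray(path.sum(axis=0)).ravel()
    tot = np.asarray(path.T @ target_est).ravel()
    valid = cnt > 0
    raw = np.where(valid, tot / np.maximum(cnt, 1), np.nan)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    internal = np.flatnonzero(tr.children_left != -1)
    parent[tr.children_left[internal]] = internal
    parent[tr.children_right[internal]] = internal
    resolved = np.empty(n_nodes)
    for node in range(n_nodes):
        j = node
        while j != -1 and not valid[j]:
            j = parent[j]
        resolved[node] = raw[j] if j != -1 else np.nan
    return resolved


def _oob_regression_forest(X, target, n_trees, options: ForestOptions, seed,
                           cluster_ids=None) -> np.ndarray:
    """Honest subsampled regression forest with out-of-bag prediction.

    Each tree chooses its splits on the split half and sets its leaf values
    from the estimate half; a row's prediction averages only trees whose
    subsample excluded it.  With ``cluster_ids``, subsampling and the
    out-of-bag rule operate on whole clusters: a row is predicted only by
    trees that never saw its cluster, so shared cluster-level covariate
    values cannot be interpolated from the row's own cluster.
    """
    target = np.asarray(target, dtype=float)
    n = len(target)
    codes = None
    if cluster_ids is not None:
        _, codes = np.unique(np.asarray(cluster_ids), return_inverse=True)
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n)
    for b in range(int(n_trees)):
        rng = np.random.default_rng(derived_seed(seed, b))
        split_rows, est_rows = _draw_subsample_halves(rng, n, options, codes)
        tree = DecisionTreeRegressor(
            min_samples_leaf=max(5, options.min_leaf_size),
            max_depth=options.max_depth,
            max_features=options.nuisance_max_features,
            random_state=int(derived_seed(seed, 10_000 + b)),
        )
        tree.fit(X[split_rows], target[split_rows])
        values = _node_means_with_fallback(tree, X[est_rows], target[est_rows])
        oob = np.ones(n, dtype=bool)
        oob[split_rows] = False
        oob[est_rows] = False
        pred_sum[oob] += values[tree.apply(X[oob])]
        pred_cnt[oob] += 1
    out = np.where(pred_cnt > 0, pred_sum / np.maximum(pred_cnt, 1), np.nan)
    bad = ~np.isfinite(out)
    if bad.any():
        out[bad] = float(target.mean())
    return out


# ---------------------------------------------------------------------------
# AIPW average treatment effect
# ---------------------------------------------------------------------------

@dataclass
class AIPWEstimate:
    """AIPW potential-outcome means and influence-function SEs."""

    mu1: float
    mu0: float
    ate_rd: float
    se_rd: float
    logor: float
    se_logor: float
    n: int


def _influence_se(psi: np.ndarray, clusters=None) -> float:
    n = psi.size
    psi = psi - psi.mean()
    if clusters is None:
        return float(np.sqrt(np.sum(psi**2) / (n - 1)) / np.sqrt(n))
    _, codes = np.unique(np.asarray(clusters), return_inverse=True)
    cluster_sums = np.bincount(codes, weights=psi)
    return float(np.sqrt(np.sum(cluster_sums**2)) / n)


def aipw_ate(y, t, e_hat, y_hat, tau_hat, clusters=None) -> AIPWEstimate:
    """Doubly robust ATE from nuisances and CATE predictions.

    With the true nuisances supplied this is unbiased regardless of taû;
    with consistent forest nuisances it inherits their double robustness.
    ``clusters`` switches the influence-function variance to cluster sums.
    """
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    e = np.asarray(e_hat, float)
    m = np.asarray(y_hat, float)
    tau = np.asarray(tau_hat, float)
    mu1_x = m + (1.0 - e) * tau
    mu0_x = m - e * tau
    g1 = mu1_x + t * (y - mu1_x) / e
    g0 = mu0_x + (1.0 - t) * (y - mu0_x) / (1.0 - e)
    mu1 = float(g1.mean())
    mu0 = float(g0.mean())
    rd = mu1 - mu0
    se_rd = _influence_se(g1 - g0, clusters)
    if 0.0 < mu1 < 1.0 and 0.0 < mu0 < 1.0:
        lor = float(logit(mu1) - logit(mu0))
        psi_lor = (g1 - mu1) / (mu1 * (1.0 - mu1)) - (g0 - mu0) / (mu0 * (1.0 - mu0))
        se_lor = _influence_se(psi_lor, clusters)
    else:
        # log-OR undefined off the probability scale; error deferred until
        # a caller actually asks for that scale
        lor, se_lor = np.nan, np.nan
    return AIPWEstimate(mu1, mu0, rd, se_rd, lor, se_lor, n=y.size)


# ---------------------------------------------------------------------------
# Honest double-sample causal trees
# ---------------------------------------------------------------------------

@dataclass
class _HonestTree:
    tree: DecisionTreeRegressor       # grown on the split half only
    node_num: np.ndarray              # per-node sum of Tt*Yt from the estimate half
    node_den: np.ndarray              # per-node sum of Tt^2 from the estimate half
    subsample: np.ndarray             # all row indices used by this tree
    split_rows: np.ndarray
    estimate_rows: np.ndarray
    valid: bool                       # root had both arms in the estimate half

    @property
    def node_values(self) -> np.ndarray:
        """Per-node effect estimates tau = sum(Tt Yt) / sum(Tt^2)."""
        return self.node_num / np.maximum(self.node_den, 1e-300)


def _grow_honest_tree(X, rt, ry, t, split_rows, est_rows, options, seed) -> _HonestTree:
    pseudo = ry[split_rows] / rt[split_rows]
    w = rt[split_rows] ** 2
    tree = DecisionTreeRegressor(
        criterion="squared_error",
        splitter="best",
        # min_leaf_size is a per-arm minimum; with ~balanced arms this is
        # enforced as 2x that many observations per child overall
        min_samples_leaf=2 * options.min_leaf_size,
        max_depth=options.max_depth,
        max_features=None,
        random_state=int(seed),
    )
    tree.fit(X[split_rows], pseudo, sample_weight=w)
    num, den, valid = _estimate_half_moments(tree, X[est_rows], rt[est_rows],
                                             ry[est_rows], t[est_rows])
    return _HonestTree(
        tree=tree,
        node_num=num,
        node_den=den,
        subsample=np.concatenate([split_rows, est_rows]),
        split_rows=split_rows,
        estimate_rows=est_rows,
        valid=valid,
    )


def _estimate_half_moments(tree, X_est, rt_est, ry_est, t_est):
    """Per-node orthogonalized moments from the estimate half.

    For every node the estimate-half members contribute sum(Tt Yt) and
    sum(Tt^2); the node effect is their ratio, and forest predictions pool
    these moments across trees before dividing (a forest-weighted average of
    leaf effects with weight Tt^2 mass).  A node is valid when its
    estimate-half members include both treatment arms with positive weight;
    an invalid leaf inherits the moments of its nearest valid ancestor.  If
    even the root is invalid the tree is flagged unusable.
    """
    tr = tree.tree_
    n_nodes = tr.node_count
    path = tree.decision_path(X_est)          # sparse (n_est, n_nodes)
    sw = np.asarray(path.T @ (rt_est**2)).ravel()
    swr = np.asarray(path.T @ (rt_est * ry_est)).ravel()
    n1 = np.asarray(path.T @ t_est).ravel()
    n0 = np.asarray(path.T @ (1.0 - t_est)).ravel()
    valid = (n1 >= 1.0) & (n0 >= 1.0) & (sw > 1e-12)

    parent = np.full(n_nodes, -1, dtype=np.int64)
    cl, cr = tr.children_left, tr.children_right
    internal = np.flatnonzero(cl != -1)
    parent[cl[internal]] = internal
    parent[cr[internal]] = internal

    num = np.empty(n_nodes)
    den = np.empty(n_nodes)
    for node in range(n_nodes):
        j = node
        while j != -1 and not valid[j]:
            j = parent[j]
        if j == -1:
            num[node], den[node] = np.nan, 0.0
        else:
            num[node], den[node] = swr[j], sw[j]
    return num, den, bool(valid[0])


class CausalForest:
    """Honest double-sample causal forest for a clustered binary-outcome cohort.

    Parameters
    ----------
    cohort : DataFrame with ``treatment``, ``outcome`` and covariate columns.
    covariates : feature columns for nuisances and splitting (default: the
        patient- and cluster-level confounders).
    options : :class:`ForestOptions`; ``options.cluster_ids`` switches to
        whole-cluster subsampling, ``options.external_ps`` to an external
        propensity vector.
    cluster_col : convenience — read cluster ids from this cohort column.
    """

    def __init__(self, cohort: pd.DataFrame, covariates=None,
                 options: ForestOptions | None = None,
                 cluster_col: str | None = None):
        self.cohort = cohort
        self.covariates = list(covariates) if covariates is not None else list(CONFOUNDERS)
        options = options if options is not None else ForestOptions()
        if cluster_col is not None:
            options = dc_replace(options, cluster_ids=cohort[cluster_col].to_numpy())
        self.options = options
        t = cohort["treatment"].to_numpy()
        if t.min() == t.max():
            raise ValueError("both treatment arms must be present")

    def fit(self) -> "CausalForestResults":
        opts = self.options
        X = self.cohort[self.covariates].to_numpy(dtype=float)
        y = self.cohort["outcome"].to_numpy(dtype=float)
        t = self.cohort["treatment"].to_numpy(dtype=float)
        n = y.size

        e_internal, y_hat = self._fit_nuisances()
        if opts.external_ps is not None:
            e_used = np.clip(np.asarray(opts.external_ps, float),
                             opts.ps_clip[0], opts.ps_clip[1])
        else:
            e_used = e_internal
        n_clipped = int(np.sum((e_used <= opts.ps_clip[0]) | (e_used >= opts.ps_clip[1])))

        rt = t - e_used
        ry = y - y_hat

        codes = None
        if opts.cluster_ids is not None:
            _, codes = np.unique(np.asarray(opts.cluster_ids), return_inverse=True)
        trees: list[_HonestTree] = []
        pred_num = np.zeros(n)
        pred_den = np.zeros(n)
        n_skipped = 0
        for b in range(opts.n_trees):
            rng = np.random.default_rng(derived_seed(opts.seed, 100, b))
            split_rows, est_rows = _draw_subsample_halves(rng, n, opts, codes)
            ht = _grow_honest_tree(X, rt, ry, t, split_rows, est_rows, opts,
                                   seed=derived_seed(opts.seed, 200, b))
            if not ht.valid:
                n_skipped += 1
                continue
            trees.append(ht)
            leaf = ht.tree.apply(X)
            oob = np.ones(n, dtype=bool)
            oob[ht.subsample] = False
            pred_num[oob] += ht.node_num[leaf[oob]]
            pred_den[oob] += ht.node_den[leaf[oob]]
        if not trees:
            raise RuntimeError("no usable trees (every root lacked a treatment arm)")

        cate = np.where(pred_den > 0, pred_num / np.maximum(pred_den, 1e-300), np.nan)
        never_oob = ~np.isfinite(cate)
        if never_oob.any():
            # fall back to the all-trees prediction for rows in every subsample
            num = np.zeros(int(never_oob.sum()))
            den = np.zeros_like(num)
            for ht in trees:
                leaf = ht.tree.apply(X[never_oob])
                num += ht.node_num[leaf]
                den += ht.node_den[leaf]
            cate[never_oob] = num / np.maximum(den, 1e-300)

        aipw = aipw_ate(y, t, e_used, y_hat, cate, clusters=opts.cluster_ids)
        return CausalForestResults(
            model=self, trees=trees, cate=cate,
            e_hat=e_used, y_hat=y_hat, aipw=aipw,
            n_trees_skipped=n_skipped, n_ps_clipped=n_clipped,
        )

    # -- internals --------------------------------------------------------
    def _fit_nuisances(self):
        opts = self.options
        X = self.cohort[self.covariates].to_numpy(dtype=float)
        y = self.cohort["outcome"].to_numpy(dtype=float)
        t = self.cohort["treatment"].to_numpy(dtype=float)
        n_trees = opts.n_nuisance_trees or _default_nuisance_trees(opts.n_trees)
        if opts.external_y_hat is not None:
            y_hat = np.asarray(opts.external_y_hat, dtype=float)
        else:
            y_hat = _oob_regression_forest(X, y, n_trees, opts, derived_seed(opts.seed, 1),
                                           cluster_ids=opts.cluster_ids)
        if opts.external_ps is not None:
            return None, y_hat
        e_hat = _oob_regression_forest(X, t, n_trees, opts, derived_seed(opts.seed, 0),
                                       cluster_ids=opts.cluster_ids)
        return np.clip(e_hat, opts.ps_clip[0], opts.ps_clip[1]), y_hat

class CausalForestResults:
    """Fitted causal forest: CATEs, nuisances and the AIPW ATE."""

    def __init__(self, model: CausalForest, trees, cate, e_hat, y_hat,
                 aipw: AIPWEstimate, n_trees_skipped: int, n_ps_clipped: int):
        self.model = model
        self.trees = trees
        self.cate_ = cate              # out-of-bag CATE per training row (RD scale)
        self.e_hat = e_hat
        self.y_hat = y_hat
        self.aipw = aipw
        self.n_trees_skipped = n_trees_skipped
        self.n_ps_clipped = n_ps_clipped

    def predict_cate(self, rows) -> np.ndarray:
        """Forest-weighted average of leaf effects (risk-difference scale).

        The leaf moments sum(Tt Yt) and sum(Tt^2) are pooled over all trees
        and divided once, i.e. each tree's leaf effect enters with weight
        proportional to its orthogonalized Tt^2 mass.
        """
        if isinstance(rows, pd.DataFrame):
            X = rows[self.model.covariates].to_numpy(dtype=float)
        else:
            X = np.asarray(rows, dtype=float)
        num = np.zeros(X.shape[0])
        den = np.zeros(X.shape[0])
        for ht in self.trees:
            leaf = ht.tree.apply(X)
            num += ht.node_num[leaf]
            den += ht.node_den[leaf]
        return num / np.maximum(den, 1e-300)

    def ate(self, scale: str = "marginal_logor") -> tuple[float, float]:
        """(estimate, SE) on the requested scale."""
        if scale == "risk_difference":
            return self.aipw.ate_rd, self.aipw.se_rd
        if scale == "marginal_logor":
            if not np.isfinite(self.aipw.logor):
                raise ValueError(
                    f"AIPW potential-outcome prevalence outside (0,1): "
                    f"mu1={self.aipw.mu1:.4f}, mu0={self.aipw.mu0:.4f}; "
                    "log-OR undefined"
                )
            return self.aipw.logor, self.aipw.se_logor
        raise ValueError(f"unknown scale {scale!r}")

    def as_estimate(self, scale: str = "marginal_logor",
                    estimator: str = "CF", **kw) -> EstimateResult:
        est, se = self.ate(scale)
        return EstimateResult.from_wald(
            est, se, estimator=estimator, scale=scale,
            extra={
                "mu1": self.aipw.mu1, "mu0": self.aipw.mu0,
                "n_trees_used": len(self.trees),
                "n_trees_skipped": self.n_trees_skipped,
                "n_ps_clipped": self.n_ps_clipped,
            }, **kw,
        )

    def summary(self) -> str:
        rd, se_rd = self.ate("risk_difference")
        lor, se_lor = self.ate("marginal_logor")
        opts = self.model.options
        variant = ("CF-PS" if opts.external_ps is not None
                   else "CF-clusterID" if opts.cluster_ids is not None else "CF")
        return "\n".join([
            f"Honest causal forest ({variant}, {len(self.trees)} trees, "
            f"{self.n_trees_skipped} skipped)",
            f"  ATE risk difference : {rd:.4f}  (SE {se_rd:.4f})",
            f"  ATE marginal log-OR : {lor:.4f}  (SE {se_lor:.4f}, 95% CI "
            f"[{lor - 1.96 * se_lor:.4f}, {lor + 1.96 * se_lor:.4f}])",
            f"  AIPW prevalences    : mu1={self.aipw.mu1:.4f}  mu0={self.aipw.mu0:.4f}",
            f"  CATE spread (OOB)   : sd={np.nanstd(self.cate_):.4f}",
            f"  clipped propensities: {self.n_ps_clipped}",
        ])


def fit_causal_forest(cohort: pd.DataFrame, covariates=None,
                      options: ForestOptions | None = None) -> CausalForestResults:
    """Functional wrapper around :class:`CausalForest`."""
    return CausalForest(cohort, covariates=covariates, options=options).fit()


def predict_cate(results: CausalForestResults, rows) -> np.ndarray:
    return results.predict_cate(rows)


def average_treatment_effect(results: CausalForestResults,
                             scale: str = "marginal_logor") -> EstimateResult:
    return results.as_estimate(scale=scale)
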