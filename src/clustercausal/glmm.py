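"""Weighted random-intercept logistic regression via adaptive quadrature.

Model: for observation j in cluster i,

    logit P(Y_ij = 1 | u_i) = x_ij' beta + u_i,      u_i ~ N(0, sigma_u^2),

with per-observation weights w_ij entering the integrated likelihood in
frequency style (each observation's log-likelihood contribution is scaled by
its weight).  The cluster-level integral over u_i is one-dimensional and is
evaluated by adaptive Gauss-Hermite quadrature: the integrand mode is found
by Newton's method (the integrand is log-concave), the quadrature grid is
centred at the mode and scaled by the curvature there, and nodes are combined
by log-sum-exp.  Parameters (beta, log sigma_u) are estimated by maximising
the resulting marginal log-likelihood; standard errors come from the inverse
numerical Hessian (Wald).

This is the outcome model used by stabilized-IPTW estimation on clustered
binary data, where the weights are the stabilized inverse-probability
weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from statsmodels.tools.numdiff import approx_hess1

_LOG_SIGMA_MIN, _LOG_SIGMA_MAX = -8.0, 4.0


@dataclass
class RandomInterceptLogitResults:
    """Fitted weighted random-intercept logit."""

    params: np.ndarray          # fixed effects beta
    bse: np.ndarray             # Wald standard errors of beta
    sigma_u: float              # random-intercept SD
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    method: str                 # optimizer + quadrature description
    cov_params: np.ndarray      # full (beta, log sigma) covariance
    exog_names: list

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return np.column_stack([lo, hi])

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Weighted random-intercept logistic regression",
            f"  n_obs={self.n_obs}  n_groups={self.n_groups}  "
            f"sigma_u={self.sigma_u:.4f}  loglik={self.loglik:.2f}",
            f"  method: {self.method}  converged={self.converged}",
            f"  {'term':<12}{'coef':>10}{'se':>10}{'ci_low':>10}{'ci_high':>10}",
        ]
        for name, b, s, (l, h) in zip(self.exog_names, self.params, self.bse, ci):
            lines.append(f"  {name:<12}{b:>10.4f}{s:>10.4f}{l:>10.4f}{h:>10.4f}")
        return "\n".join(lines)


def _marginal_loglik(beta, log_sigma, y, X, w, gidx, n_groups, gh_x, gh_w,
                     newton_iter: int = 50, newton_tol: float = 1e-9,
                     u_start: np.ndarray | None = None):
    sigma = float(np.exp(np.clip(log_sigma, _LOG_SIGMA_MIN, _LOG_SIGMA_MAX)))
    eta0 = X @ beta
    inv_s2 = 1.0 / sigma**2

    # Newton for per-cluster posterior modes (vectorised over clusters);
    # warm-starting from the previous evaluation's modes cuts iterations.
    u = np.zeros(n_groups) if u_start is None else u_start.copy()
    h = None
    for _ in range(newton_iter):
        eta = eta0 + u[gidx]
        p = expit(eta)
        g = np.bincount(gidx, weights=w * (y - p), minlength=n_groups) - u * inv_s2
        h = -np.bincount(gidx, weights=w * p * (1.0 - p), minlength=n_groups) - inv_s2
        step = g / h
        u = u - step
        if np.max(np.abs(step)) < newton_tol:
            break
    s = 1.0 / np.sqrt(-h)

    # Adaptive GH: integral ~ sqrt(2) s sum_k omega_k exp(t_k^2) f(u_hat + sqrt(2) s t_k)
    K = gh_x.size
    acc = np.empty((n_groups, K))
    log_gh = np.log(gh_w) + gh_x**2
    for k in range(K):
        uk = u + np.sqrt(2.0) * s * gh_x[k]
        eta = eta0 + uk[gidx]
        ll = np.bincount(
            gidx, weights=w * (y * eta - np.logaddexp(0.0, eta)), minlength=n_groups
        )
        acc[:, k] = ll - 0.5 * uk**2 * inv_s2 + log_gh[k]
    llc = logsumexp(acc, axis=1) + 0.5 * np.log(2.0) + np.log(s) - 0.5 * np.log(2.0 * np.pi * sigma**2)
    return float(llc.sum()), u


def fit_random_intercept_logit(
    y,
    X,
    groups,
    weights=None,
    n_quad: int = 15,
    exog_names: list | None = None,
    start_params: np.ndarray | None = None,
) -> RandomInterceptLogitResults:
    """Fit the weighted random-intercept logit by adaptive GH quadrature.

    Parameters
    ----------
    y : binary outcome vector.
    X : design matrix of fixed effects (include the intercept column).
    groups : cluster labels (any hashable dtype).
    weights : optional non-negative per-observation weights (default 1).
    n_quad : number of Gauss-Hermite nodes (default 15).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float).ravel()
    if w.shape != y.shape or np.any(w < 0):
        raise ValueError("weights must be non-negative and match y in length")
    _, gidx = np.unique(np.asarray(groups), return_inverse=True)
    n_groups = int(gidx.max()) + 1
    gh_x, gh_w = np.polynomial.hermite.hermgauss(int(n_quad))
    p = X.shape[1]
    if exog_names is None:
        exog_names = [f"x{j}" for j in range(p)]

    u_cache = {"u": None}

    def nll(theta: np.ndarray) -> float:
        ll, u = _marginal_loglik(theta[:p], theta[p], y, X, w, gidx, n_groups,
                                 gh_x, gh_w, u_start=u_cache["u"])
        u_cache["u"] = u
        return -ll

    if start_params is None:
        # weighted ordinary logit start, diffuse sigma
        import statsmodels.api as sm

        glm = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
        try:
            beta0 = glm.fit().params
        except Exception:
            beta0 = np.zeros(p)
        start_params = np.concatenate([beta0, [np.log(0.5)]])

    res = minimize(nll, np.asarray(start_params, dtype=float), method="BFGS",
                   options={"gtol": 1e-6, "maxiter": 500})
    # "precision loss" at a flat sigma boundary still yields a valid optimum;
    # accept whenever the gradient is essentially zero
    grad_ok = res.jac is not None and np.max(np.abs(res.jac)) < 1e-3 * max(1.0, abs(res.fun))
    converged = bool(res.success or grad_ok)
    method = f"BFGS + adaptive GH({n_quad})"
    if not converged:
        # documented secondary optimizer
        res2 = minimize(nll, res.x, method="Nelder-Mead",
                        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        if res2.fun <= res.fun:
            res = res2
        converged = bool(res2.success)
        method = f"BFGS->Nelder-Mead + adaptive GH({n_quad})"

    theta = res.x
    H = approx_hess1(theta, nll)
    cov = np.full((p + 1, p + 1), np.nan)
    bse = np.full(p, np.nan)
    try:
        cov = np.linalg.inv(H)
        bse = np.sqrt(np.diag(cov)[:p])
    except np.linalg.LinAlgError:
        pass
    if not np.all(np.isfinite(bse)):
        # sigma_u at its boundary flattens the log-sigma direction; fall back
        # to the observed information of beta at the fixed variance
        try:
            cov_b = np.linalg.inv(H[:p, :p])
            bse = np.sqrt(np.diag(cov_b))
            cov[:p, :p] = cov_b
        except np.linalg.LinAlgError:
            pass
    if not np.all(np.isfinite(bse)):
        converged = False

    sigma_u = float(np.exp(np.clip(theta[p], _LOG_SIGMA_MIN, _LOG_SIGMA_MAX)))
    return RandomInterceptLogitResults(
        params=theta[:p].copy(),
        bse=bse,
        sigma_u=sigma_u,
        loglik=-float(res.fun),
        converged=converged,
        n_obs=y.size,
        n_groups=n_groups,
        method=method,
        cov_params=cov,
        exog_names=list(exog_names),
    )
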