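"""Parametric clustered-cohort generator.

Cohorts of ``total_target`` patients nested in ``m`` clusters are simulated
with two cluster-level confounders (z1 ~ N(0,1), z2 ~ Bernoulli(0.5), shared
by all members of a cluster), five patient-level confounders (x1..x3 binary,
x4, x5 standard normal), an instrument x7 (affects treatment only) and a risk
factor x6 (affects outcome only).  Binary treatment and outcome follow
logistic models

    logit P(T=1) = alpha0 + beta_t . x + gamma_z (z1 + z2) + delta z1*x1
    logit P(Y=1) = lambda0 + tau T + beta_y . x + gamma_z_out (z1 + z2)

whose intercepts are calibrated by Monte Carlo root-finding so the marginal
prevalences hit their targets (the coefficient tables fix every slope but no
intercept).  Cluster sizes are Poisson with the structure's mean, adjusted by
single-patient moves so the total is exact.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import COHORT_COLUMNS, ScenarioConfig, derived_seed

_X_COLS = ("x1", "x2", "x3", "x4", "x5", "x6", "x7")


class DegenerateCohortError(RuntimeError):
    """Raised when treatment or outcome is constant even after one redraw."""


def draw_cluster_sizes(m: int, n_mean: int, total_target: int, rng_seed) -> np.ndarray:
    """Draw ``m`` Poisson(``n_mean``) cluster sizes rescaled to an exact total.

    Zero draws are replaced by 1 (every cluster keeps at least one patient);
    the vector is then adjusted by adding/removing single patients at
    uniformly random clusters until it sums to ``total_target`` exactly.
    """
    if m < 1 or n_mean < 1:
        raise ValueError("m and n_mean must be positive")
    if total_target < m:
        raise ValueError("total_target must be >= m (one patient per cluster)")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    sizes = rng.poisson(n_mean, size=m).astype(np.int64)
    sizes[sizes == 0] = 1
    diff = int(total_target - sizes.sum())
    while diff > 0:
        # add patients one at a time; vectorised in chunks for speed
        add = rng.integers(0, m, size=diff)
        np.add.at(sizes, add, 1)
        diff = int(total_target - sizes.sum())
    while diff < 0:
        remove = rng.integers(0, m, size=-diff)
        for c in remove:
            if sizes[c] > 1:
                sizes[c] -= 1
        diff = int(total_target - sizes.sum())
    return sizes


def calibrate_intercept(
    linear_predictor_sampler: Callable[[int], np.ndarray],
    prevalence_target: float,
    tolerance: float = 1e-4,
    n_mc: int = 200_000,
    max_expand: int = 60,
) -> float:
    """Find the intercept matching a marginal prevalence by MC root-finding.

    ``linear_predictor_sampler(n)`` must return ``n`` draws of the
    intercept-free linear predictor.  The returned ``alpha`` satisfies
    ``|mean(expit(alpha + LP)) - target| <= tolerance`` on that MC sample;
    the map is strictly monotone in ``alpha`` so Brent's method applies.
    """
    if not 0.0 < prevalence_target < 1.0:
        raise ValueError("prevalence_target must lie in (0, 1)")
    lp = np.asarray(linear_predictor_sampler(n_mc), dtype=float)

    def gap(alpha: float) -> float:
        return float(expit(alpha + lp).mean() - prevalence_target)

    lo, hi = -1.0, 1.0
    for _ in range(max_expand):
        if gap(lo) < 0.0:
            break
        lo *= 2.0
    for _ in range(max_expand):
        if gap(hi) > 0.0:
            break
        hi *= 2.0
    if not (gap(lo) < 0.0 < gap(hi)):
        raise RuntimeError("intercept calibration failed to bracket the root")
    alpha = brentq(gap, lo, hi, xtol=1e-10)
    if abs(gap(alpha)) > tolerance:
        raise RuntimeError("intercept calibration did not reach tolerance")
    return float(alpha)


def _draw_patient_covariates(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    return {
        "x1": (rng.random(n) < 0.40).astype(np.int8),
        "x2": (rng.random(n) < 0.45).astype(np.int8),
        "x3": (rng.random(n) < 0.50).astype(np.int8),
        "x4": rng.standard_normal(n),
        "x5": rng.standard_normal(n),
        "x6": (rng.random(n) < 0.50).astype(np.int8),
        "x7": (rng.random(n) < 0.50).astype(np.int8),
    }


class ParametricSimulator:
    """Simulator for one scenario; produces cohort tables and true effects.

    Intercepts are calibrated lazily, once per scenario, on an i.i.d.
    calibration sample (sharing z within clusters leaves each patient's
    marginal covariate law unchanged, so i.i.d. draws suffice for marginal
    prevalence calibration).
    """

    def __init__(self, config: ScenarioConfig, calibration_n: int = 200_000):
        self.config = config
        self.calibration_n = int(calibration_n)
        self._alpha0: float | None = None
        self._lambda0: float | None = None

    # -- linear predictors (intercept-free) -------------------------------
    def _lp_treatment(self, cov: dict[str, np.ndarray], z1, z2) -> np.ndarray:
        c = self.config
        bt = c.beta_x_treat
        lp = (
            bt[0] * cov["x1"] + bt[1] * cov["x2"] + bt[2] * cov["x3"]
            + bt[3] * cov["x4"] + bt[4] * cov["x5"]
            + c.beta_instrument * cov["x7"]
            + c.gamma_z * (z1 + z2)
            + c.delta_interaction * z1 * cov["x1"]
        )
        return np.asarray(lp, dtype=float)

    def _lp_outcome_base(self, cov: dict[str, np.ndarray], z1, z2) -> np.ndarray:
        """Outcome linear predictor excluding intercept and treatment term."""
        c = self.config
        by = c.beta_x_out
        lp = (
            by[0] * cov["x1"] + by[1] * cov["x2"] + by[2] * cov["x3"]
            + by[3] * cov["x4"] + by[4] * cov["x5"]
            + c.beta_riskfactor * cov["x6"]
            + c.gamma_z_out * (z1 + z2)
        )
        return np.asarray(lp, dtype=float)

    # -- calibration ------------------------------------------------------
    def _calibrate(self) -> tuple[float, float]:
        if self._alpha0 is not None:
            return self._alpha0, self._lambda0
        c = self.config
        rng = np.random.default_rng(derived_seed(c.seed, 90))
        n = self.calibration_n
        cov = _draw_patient_covariates(rng, n)
        z1 = rng.standard_normal(n)
        z2 = (rng.random(n) < 0.5).astype(np.int8)
        lp_t = self._lp_treatment(cov, z1, z2)
        alpha0 = calibrate_intercept(lambda k: lp_t[:k], c.treat_prevalence_target, n_mc=n)
        t = (rng.random(n) < expit(alpha0 + lp_t)).astype(np.int8)
        lp_y = self._lp_outcome_base(cov, z1, z2) + c.tau * t
        lambda0 = calibrate_intercept(lambda k: lp_y[:k], c.outcome_prevalence_target, n_mc=n)
        self._alpha0, self._lambda0 = alpha0, lambda0
        return alpha0, lambda0

    @property
    def intercepts(self) -> tuple[float, float]:
        """Calibrated (alpha0, lambda0)."""
        return self._calibrate()

    # -- simulation -------------------------------------------------------
    def simulate(self, rep_seed: int) -> pd.DataFrame:
        """Simulate one cohort; identical ``rep_seed`` gives identical tables.

        A degenerate draw (constant treatment or outcome) triggers exactly one
        reseeded redraw, then :class:`DegenerateCohortError`.
        """
        alpha0, lambda0 = self._calibrate()
        for attempt in (0, 1):
            rng = np.random.default_rng(
                [int(self.config.seed), int(rep_seed), attempt]
            )
            df = self._simulate_once(rng, alpha0, lambda0)
            t, y = df["treatment"].to_numpy(), df["outcome"].to_numpy()
            if t.min() != t.max() and y.min() != y.max():
                return df
        raise DegenerateCohortError(
            f"constant treatment or outcome after redraw (scenario "
            f"{self.config.scenario_id}, rep {rep_seed})"
        )

    def _simulate_once(self, rng: np.random.Generator, alpha0: float, lambda0: float) -> pd.DataFrame:
        c = self.config
        m = c.n_clusters
        sizes = draw_cluster_sizes(m, c.mean_cluster_size, c.total_target, rng)
        cluster_id = np.repeat(np.arange(m), sizes)
        z1 = np.repeat(rng.standard_normal(m), sizes)
        z2 = np.repeat((rng.random(m) < 0.5).astype(np.int8), sizes)
        n = int(sizes.sum())
        cov = _draw_patient_covariates(rng, n)
        p_t = expit(alpha0 + self._lp_treatment(cov, z1, z2))
        t = (rng.random(n) < p_t).astype(np.int8)
        p_y = expit(lambda0 + c.tau * t + self._lp_outcome_base(cov, z1, z2))
        y = (rng.random(n) < p_y).astype(np.int8)
        data = {"cluster_id": cluster_id, "z1": z1, "z2": z2}
        data.update({k: cov[k] for k in _X_COLS})
        data["treatment"] = t
        data["outcome"] = y
        return pd.DataFrame(data, columns=list(COHORT_COLUMNS))

    # -- estimands --------------------------------------------------------
    def true_effect(self, scale: str = "conditional_logor",
                    n_mc: int = 200_000, seed: int | None = None) -> float:
        """True treatment effect on the requested scale.

        ``conditional_logor`` is the structural coefficient ``tau`` itself.
        Marginal scales average both potential-outcome probabilities over a
        large MC population (the odds ratio is noncollapsible, so the marginal
        log-OR is attenuated towards zero relative to ``tau`` whenever other
        outcome-model effects are present).
        """
        c = self.config
        if scale == "conditional_logor":
            return float(c.tau)
        if scale not in ("marginal_logor", "risk_difference"):
            raise ValueError(f"unknown scale {scale!r}")
        if n_mc < 10**5:
            raise ValueError("n_mc must be >= 1e5 for marginal scales")
        _, lambda0 = self._calibrate()
        rng = np.random.default_rng(derived_seed(c.seed, 91) if seed is None else seed)
        cov = _draw_patient_covariates(rng, n_mc)
        z1 = rng.standard_normal(n_mc)
        z2 = (rng.random(n_mc) < 0.5).astype(np.int8)
        lp = lambda0 + self._lp_outcome_base(cov, z1, z2)
        mu1 = float(expit(lp + c.tau).mean())
        mu0 = float(expit(lp).mean())
        if scale == "risk_difference":
            return mu1 - mu0
        return float(np.log(mu1 / (1 - mu1)) - np.log(mu0 / (1 - mu0)))


def simulate_cohort(config: ScenarioConfig, rep_seed: int) -> pd.DataFrame:
    """Functional wrapper around :class:`ParametricSimulator`."""
    return ParametricSimulator(config).simulate(rep_seed)


def true_effect(config: ScenarioConfig, scale: str = "conditional_logor",
                n_mc: int = 200_000, seed: int | None = None) -> float:
    return ParametricSimulator(config).true_effect(scale, n_mc=n_mc, seed=seed)
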