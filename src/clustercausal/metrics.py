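"""Simulation-study performance measures with Monte Carlo standard errors.

Per scenario and estimator: average absolute relative bias (Rbias, % of the
true effect), empirical standard error (EmpSE, the SD of the estimates across
replications) and 95% CI coverage, each with its Monte Carlo SE following the
standard simulation-study guidance formulas:

    mcse_bias     = EmpSE / sqrt(n)            (reported in % of |truth|)
    mcse_empse    = EmpSE / sqrt(2 (n - 1))
    mcse_coverage = sqrt(cov (1 - cov) / n)

Rbias is the absolute relative bias *of the mean estimate*,
100 |mean - truth| / |truth|; a per-replication-absolute variant is available
behind ``per_rep_absolute`` since the phrase is ambiguous in common usage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

METRIC_COLUMNS = [
    "scenario_id", "estimator", "n_reps_used", "n_excluded",
    "rbias_pct", "emp_se", "coverage",
    "mcse_bias_pct", "mcse_empse", "mcse_coverage",
]


def relative_bias(estimates, truth: float, per_rep_absolute: bool = False) -> float:
    """Average absolute relative bias in percent of the true effect."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("estimates must be non-empty")
    if truth == 0:
        raise ValueError("relative bias undefined at truth = 0; use absolute bias")
    if per_rep_absolute:
        return float(100.0 * np.mean(np.abs(est - truth)) / abs(truth))
    return float(100.0 * abs(est.mean() - truth) / abs(truth))


def empirical_se(estimates) -> float:
    """Sample standard deviation of the estimates (n-1 denominator)."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("empirical SE needs at least 2 estimates")
    return float(est.std(ddof=1))


def coverage(results, truth: float) -> float:
    """Fraction of 95% CIs containing the truth.

    ``results`` is either a sequence of objects with ``ci_low``/``ci_high``
    or a DataFrame with those columns.
    """
    if isinstance(results, pd.DataFrame):
        lo = results["ci_low"].to_numpy(dtype=float)
        hi = results["ci_high"].to_numpy(dtype=float)
    else:
        results = list(results)
        if not results:
            raise ValueError("empty result list")
        lo = np.array([r.ci_low for r in results], dtype=float)
        hi = np.array([r.ci_high for r in results], dtype=float)
    if lo.size == 0:
        raise ValueError("empty result list")
    return float(np.mean((lo <= truth) & (truth <= hi)))


def summarize_scenario(results: pd.DataFrame, truths,
                       per_rep_absolute: bool = False) -> pd.DataFrame:
    """One metrics row per (scenario, estimator) from a long results table.

    ``results`` columns: scenario_id, rep, estimator, estimate, se, ci_low,
    ci_high, converged.  ``truths`` maps scenario_id -> true effect (or is a
    single float used for all scenarios).  Non-converged replications are
    excluded pairwise per estimator and counted.
    """
    rows = []
    for (sid, est_name), grp in results.groupby(["scenario_id", "estimator"], sort=True):
        truth = truths if np.isscalar(truths) else truths[sid]
        ok = grp[grp["converged"].astype(bool)]
        n_used, n_exc = len(ok), len(grp) - len(ok)
        if n_used < 2:
            rows.append({
                "scenario_id": sid, "estimator": est_name,
                "n_reps_used": n_used, "n_excluded": n_exc,
                "rbias_pct": np.nan, "emp_se": np.nan, "coverage": np.nan,
                "mcse_bias_pct": np.nan, "mcse_empse": np.nan, "mcse_coverage": np.nan,
            })
            import warnings

            warnings.warn(f"cell ({sid}, {est_name}) has <2 converged reps; metrics missing")
            continue
        est = ok["estimate"].to_numpy(dtype=float)
        emp = empirical_se(est)
        cov = coverage(ok, truth)
        rows.append({
            "scenario_id": sid, "estimator": est_name,
            "n_reps_used": n_used, "n_excluded": n_exc,
            "rbias_pct": relative_bias(est, truth, per_rep_absolute=per_rep_absolute),
            "emp_se": emp,
            "coverage": cov,
            "mcse_bias_pct": 100.0 * (emp / np.sqrt(n_used)) / abs(truth),
            "mcse_empse": emp / np.sqrt(2.0 * (n_used - 1)),
            "mcse_coverage": float(np.sqrt(cov * (1.0 - cov) / n_used)),
        })
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def pivot_metrics(metrics: pd.DataFrame, column: str = "rbias_pct") -> pd.DataFrame:
    """Wide scenario-by-estimator view of one metric (for figure tables)."""
    return metrics.pivot(index="scenario_id", columns="estimator", values=column)


def average_over_structures(metrics: pd.DataFrame, column: str = "rbias_pct") -> pd.Series:
    """Unweighted mean of a metric across scenarios, per estimator.

    Used for the "average over cluster structures" figures: the value for an
    estimator equals the plain mean of its per-structure values.
    """
    return metrics.groupby("estimator")[column].mean()
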