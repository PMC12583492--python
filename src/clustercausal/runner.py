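"""Experiment orchestration: scenario grid x replications x estimators.

Within one (scenario, replication) cell every requested estimator sees the
*same* simulated dataset (paired design), so between-estimator contrasts are
free of dataset-level Monte Carlo noise.  Cell seeds are derived from the
root seed and the (scenario index, replication) pair through a stable
SeedSequence scheme, which makes results identical under serial and parallel
execution and lets any single cell be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import __version__
from .config import CONFOUNDERS, ScenarioConfig, derived_seed
from .forest import CausalForest, ForestOptions, fit_nuisance_forests
from .iptw import IPTW, EstimateResult, fit_propensity_logistic
from .metrics import summarize_scenario
from .parametric import ParametricSimulator
from .plasmode import (
    PLASMODE_COVARIATES,
    PlasmodeConfig,
    PlasmodeSimulator,
    generate_synthetic_base_cohort,
    read_base_cohort,
)

DEFAULT_ESTIMATORS = ("PS-IPTW", "CF", "CF-clusterID", "CF-PS")

RESULT_COLUMNS = [
    "scenario_id", "rep", "estimator", "estimate", "se",
    "ci_low", "ci_high", "converged", "scale",
]


@dataclass
class RunManifest:
    """Record of one grid run, written alongside the results."""

    root_seed: int
    scenario_ids: list
    estimators: list
    reps: int
    out_dir: str
    version: str = __version__
    completed: dict = field(default_factory=dict)   # scenario_id -> reps done

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def load(cls, path) -> "RunManifest":
        try:
            with open(path) as fh:
                d = json.load(fh)
            return cls(**d)
        except (json.JSONDecodeError, TypeError, KeyError) as exc:
            raise RuntimeError(f"corrupt manifest at {path}: {exc}") from exc


def run_estimators_on_cohort(
    cohort: pd.DataFrame,
    estimators=DEFAULT_ESTIMATORS,
    covariates=None,
    cluster_col: str = "cluster_id",
    seed: int = 0,
    n_trees: int = 200,
    forest_scale: str = "marginal_logor",
    scenario_id: str = "",
    rep: int = -1,
) -> list[EstimateResult]:
    """Run the requested estimators on one dataset (paired design).

    A failure in one estimator is recorded as a non-converged result and does
    not abort the cell.
    """
    covariates = list(covariates) if covariates is not None else list(CONFOUNDERS)
    forest_seed = derived_seed(seed, 3)
    out: list[EstimateResult] = []

    # Forest variants within a cell share one set of nuisance fits: the
    # variants then differ only in their tree-stage mechanics, which is the
    # contrast the paired design is after.
    nuisances: dict = {}

    def _shared_nuisances(opts: ForestOptions):
        if "fits" not in nuisances:
            nuisances["fits"] = fit_nuisance_forests(cohort, covariates, opts)
        return nuisances["fits"]

    for name in estimators:
        try:
            if name == "PS-IPTW":
                res = IPTW(cohort, covariates=covariates, cluster_col=cluster_col).fit()
                est = res.as_estimate(scenario_id=scenario_id, rep=rep)
            elif name in ("CF", "CF-clusterID", "CF-PS"):
                opts = ForestOptions(n_trees=n_trees, seed=forest_seed)
                kwargs = {}
                if name == "CF-clusterID":
                    # cluster-aware subsampling applies to the nuisance
                    # forests too, so this variant fits its own
                    kwargs["cluster_col"] = cluster_col
                else:
                    e_hat, y_hat = _shared_nuisances(opts)
                    if name == "CF-PS":
                        ps = fit_propensity_logistic(cohort, covariates)
                        ext_ps = np.clip(ps.fitted, 1e-6, 1 - 1e-6)
                    else:
                        ext_ps = e_hat
                    opts = dataclasses.replace(opts, external_ps=ext_ps,
                                               external_y_hat=y_hat)
                cf = CausalForest(cohort, covariates=covariates, options=opts, **kwargs).fit()
                est = cf.as_estimate(scale=forest_scale, estimator=name,
                                     scenario_id=scenario_id, rep=rep)
            else:
                raise ValueError(f"unknown estimator {name!r}")
        except Exception:
            est = EstimateResult(
                estimate=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
                estimator=name, scenario_id=scenario_id, rep=rep, converged=False,
            )
        out.append(est)
    return out


def _results_frame(records: list[EstimateResult]) -> pd.DataFrame:
    rows = [{
        "scenario_id": r.scenario_id, "rep": r.rep, "estimator": r.estimator,
        "estimate": r.estimate, "se": r.se, "ci_low": r.ci_low,
        "ci_high": r.ci_high, "converged": r.converged, "scale": r.scale,
    } for r in records]
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return df.sort_values(["scenario_id", "rep", "estimator"]).reset_index(drop=True)


def _parametric_cell(sim: ParametricSimulator, si: int, rep: int, root_seed: int,
                     estimators, n_trees, forest_scale) -> list[EstimateResult]:
    rep_seed = derived_seed(root_seed, si, rep)
    cohort = sim.simulate(rep_seed)
    return run_estimators_on_cohort(
        cohort, estimators=estimators, covariates=list(CONFOUNDERS),
        cluster_col="cluster_id", seed=derived_seed(root_seed, si, rep, 7),
        n_trees=n_trees, forest_scale=forest_scale,
        scenario_id=sim.config.scenario_id, rep=rep,
    )


def run_grid(
    configs: list[ScenarioConfig],
    out_dir,
    estimators=DEFAULT_ESTIMATORS,
    reps: int | None = None,
    workers: int = 1,
    root_seed: int = 0,
    n_trees: int = 200,
    forest_scale: str = "marginal_logor",
    truth_scale: str = "conditional_logor",
) -> RunManifest:
    """Run the parametric grid and write results.csv / metrics.csv / manifest.

    Partial runs resume: cells already present in ``results.csv`` are kept
    and not recomputed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results_path = out_dir / "results.csv"
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists():
        RunManifest.load(manifest_path)  # raises on corruption

    existing = (pd.read_csv(results_path, float_precision="round_trip")
                if results_path.exists() else pd.DataFrame(columns=RESULT_COLUMNS))
    done = set(zip(existing["scenario_id"], existing["rep"])) if len(existing) else set()

    sims, tasks = [], []
    for si, cfg in enumerate(configs):
        sim = ParametricSimulator(cfg)
        sim.intercepts  # calibrate once in the parent process
        sims.append(sim)
        n_reps = int(reps) if reps is not None else cfg.n_reps
        for rep in range(n_reps):
            if (cfg.scenario_id, rep) not in done:
                tasks.append((si, rep))

    batches = Parallel(n_jobs=workers)(
        delayed(_parametric_cell)(sims[si], si, rep, root_seed,
                                  tuple(estimators), n_trees, forest_scale)
        for si, rep in tasks
    )
    new = _results_frame([r for batch in batches for r in batch])
    if len(existing) and len(new):
        results = pd.concat([existing, new], ignore_index=True)
    else:
        results = existing if len(existing) else new
    results = results.sort_values(["scenario_id", "rep", "estimator"]).reset_index(drop=True)
    results.to_csv(results_path, index=False)

    truths = {
        sim.config.scenario_id: sim.true_effect(truth_scale) for sim in sims
    }
    metrics = summarize_scenario(results, truths)
    metrics.to_csv(out_dir / "metrics.csv", index=False)

    n_reps_out = int(reps) if reps is not None else max(c.n_reps for c in configs)
    manifest = RunManifest(
        root_seed=int(root_seed),
        scenario_ids=[c.scenario_id for c in configs],
        estimators=list(estimators),
        reps=n_reps_out,
        out_dir=str(out_dir),
        completed={
            sid: int(grp["rep"].nunique())
            for sid, grp in results.groupby("scenario_id")
        },
    )
    manifest.save(manifest_path)
    return manifest


#: The four estimator-contrast blocks the package's evaluation focuses on:
#: (tag, cluster structures, gamma_z, estimators).  The first block spans all
#: five structures under strong cluster-level confounding (OR 2.5); the rest
#: probe single structures where the forest variants and IPTW differ most.
STUDY_BLOCKS = (
    ("or2.5_grid",
     ((10, 1000), (50, 200), (100, 100), (200, 50), (500, 20)),
     0.9163, ("CF", "PS-IPTW")),
    ("m10_or1.5", ((10, 1000),), 0.4055, ("CF", "CF-PS")),
    ("m10_or1.25", ((10, 1000),), 0.2231, ("CF", "CF-clusterID")),
    ("m50_or1.25", ((50, 200),), 0.2231, ("PS-IPTW", "CF")),
)


def run_comparison_study(root_seed: int = 0, reps: int = 25, n_trees: int = 200,
                         blocks=STUDY_BLOCKS, verbose: bool = False):
    """Run the estimator-contrast study blocks with paired datasets.

    Returns ``(results, block_of_scenario)``: the long results table and a
    mapping from scenario_id to block tag.  Every quantity is recomputed from
    scratch under seeds derived from ``root_seed``.
    """
    import sys
    import time as _time

    records: list[EstimateResult] = []
    block_of: dict[str, str] = {}
    si = 0
    t0 = _time.time()
    for tag, structures, gamma, estimators in blocks:
        for m, n in structures:
            cfg = ScenarioConfig(n_clusters=m, mean_cluster_size=n, gamma_z=gamma,
                                 seed=derived_seed(root_seed, 300 + si))
            sim = ParametricSimulator(cfg)
            sim.intercepts
            block_of[cfg.scenario_id] = tag
            for rep in range(reps):
                cohort = sim.simulate(derived_seed(root_seed, si, rep))
                records += run_estimators_on_cohort(
                    cohort, estimators=estimators,
                    seed=derived_seed(root_seed, si, rep, 7),
                    n_trees=n_trees, scenario_id=cfg.scenario_id, rep=rep,
                )
            if verbose:
                print(f"[{_time.time() - t0:7.1f}s] {tag} {cfg.scenario_id}: "
                      f"{reps} reps done", file=sys.stderr, flush=True)
            si += 1
    return _results_frame(records), block_of


def _plasmode_cell(sim: PlasmodeSimulator, si: int, rep: int, root_seed: int,
                   estimators, n_trees, forest_scale) -> list[EstimateResult]:
    rep_seed = derived_seed(root_seed, si, rep)
    cohort = sim.simulate(rep_seed)
    return run_estimators_on_cohort(
        cohort, estimators=estimators, covariates=list(PLASMODE_COVARIATES),
        cluster_col="cluster_id", seed=derived_seed(root_seed, si, rep, 7),
        n_trees=n_trees, forest_scale=forest_scale,
        scenario_id=sim.config.scenario_id, rep=rep,
    )


def run_plasmode_grid(
    base,
    out_dir,
    gamma_grid=(0.01, 0.2231, 0.4055, 0.9163),
    estimators=DEFAULT_ESTIMATORS,
    reps: int = 100,
    workers: int = 1,
    root_seed: int = 0,
    n_trees: int = 200,
    forest_scale: str = "marginal_logor",
    base_seed: int = 0,
    tau: float = 0.4055,
) -> RunManifest:
    """Run the plasmode arm over the cluster-confounding OR grid.

    ``base`` is ``"synthetic"`` (generate the stand-in base cohort), a path
    to a base-cohort CSV, or a DataFrame with the base-cohort schema.
    """
    if isinstance(base, pd.DataFrame):
        base_df = base
    elif base == "synthetic":
        base_df = generate_synthetic_base_cohort(seed=base_seed)
    elif base is not None and Path(str(base)).exists():
        base_df = read_base_cohort(base)
    else:
        raise FileNotFoundError(
            f"base cohort {base!r} not found; pass 'synthetic' or a CSV path"
        )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results_path = out_dir / "results.csv"
    existing = (pd.read_csv(results_path, float_precision="round_trip")
                if results_path.exists() else pd.DataFrame(columns=RESULT_COLUMNS))
    done = set(zip(existing["scenario_id"], existing["rep"])) if len(existing) else set()

    sims, tasks = [], []
    for si, g in enumerate(gamma_grid):
        cfg = PlasmodeConfig(gamma_z=float(g), tau=tau, n_reps=reps,
                             seed=derived_seed(root_seed, 500 + si))
        sim = PlasmodeSimulator(base_df, cfg)
        sims.append(sim)
        for rep in range(reps):
            if (cfg.scenario_id, rep) not in done:
                tasks.append((si, rep))

    batches = Parallel(n_jobs=workers)(
        delayed(_plasmode_cell)(sims[si], si, rep, root_seed,
                                tuple(estimators), n_trees, forest_scale)
        for si, rep in tasks
    )
    new = _results_frame([r for batch in batches for r in batch])
    if len(existing) and len(new):
        results = pd.concat([existing, new], ignore_index=True)
    else:
        results = existing if len(existing) else new
    results = results.sort_values(["scenario_id", "rep", "estimator"]).reset_index(drop=True)
    results.to_csv(results_path, index=False)

    metrics = summarize_scenario(results, tau)
    metrics.to_csv(out_dir / "metrics.csv", index=False)

    manifest = RunManifest(
        root_seed=int(root_seed),
        scenario_ids=[sim.config.scenario_id for sim in sims],
        estimators=list(estimators),
        reps=int(reps),
        out_dir=str(out_dir),
        completed={
            sid: int(grp["rep"].nunique())
            for sid, grp in results.groupby("scenario_id")
        },
    )
    manifest.save(out_dir / "manifest.json")
    return manifest
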