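"""Scenario configuration for the clustered-data simulation study.

A scenario fixes the cluster structure (number of clusters ``m`` and mean
cluster size ``n``), the strength of cluster-level confounding on treatment
allocation (``gamma_z``, a log odds ratio), and the coefficient vectors of the
treatment-allocation and outcome models.  The canonical study grid crosses
five cluster structures with four values of ``gamma_z`` (odds ratios 1.01,
1.25, 1.5 and 2.5), i.e. twenty scenarios in total.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

#: Cluster-confounder log-OR grid for treatment allocation: OR 1.01, 1.25, 1.5, 2.5.
CANONICAL_GAMMA_GRID: tuple[float, ...] = (0.01, 0.2231, 0.4055, 0.9163)

#: (m, n) cluster structures: m clusters with Poisson(n) patients each.
CANONICAL_STRUCTURES: tuple[tuple[int, int], ...] = (
    (10, 1000),
    (50, 200),
    (100, 100),
    (200, 50),
    (500, 20),
)

#: Column order of a simulated cohort table.
COHORT_COLUMNS: tuple[str, ...] = (
    "cluster_id", "z1", "z2",
    "x1", "x2", "x3", "x4", "x5", "x6", "x7",
    "treatment", "outcome",
)

#: Confounders entering the propensity-score model (instrument x7 and pure
#: risk factor x6 excluded).
CONFOUNDERS: tuple[str, ...] = ("x1", "x2", "x3", "x4", "x5", "z1", "z2")


@dataclass(frozen=True)
class ScenarioConfig:
    """One parametric simulation scenario.

    Parameters
    ----------
    n_clusters : int
        Number of clusters ``m`` (hospitals / surgeons).
    mean_cluster_size : int
        Poisson mean ``n`` of patients per cluster.
    total_target : int
        Fixed total sample size; cluster sizes are rescaled so they sum to
        this exactly (default 10 000).
    gamma_z : float
        Log-OR of each cluster confounder (z1, z2) on treatment allocation.
    beta_x_treat, beta_x_out : tuple of 5 floats
        Log-OR of the patient confounders x1..x5 on treatment and outcome.
        The fifth confounder carries no printed effect and defaults to 0.
    gamma_z_out : float
        Log-OR of each cluster confounder on the outcome (default 0.4055).
    beta_instrument : float
        Log-OR of the instrument x7 on treatment (no direct outcome effect).
    beta_riskfactor : float
        Log-OR of the risk factor x6 on the outcome (no treatment effect).
    delta_interaction : float
        Log-OR of the cross-level interaction z1*x1 on treatment.
    tau : float
        True conditional treatment log-OR (default 0.4055, OR = 1.5).
    treat_prevalence_target, outcome_prevalence_target : float
        Marginal prevalences that the calibrated intercepts aim for.
    n_reps : int
        Monte Carlo replications for this scenario.
    seed : int
        Scenario-level seed; replication seeds are derived from it.
    """

    n_clusters: int = 100
    mean_cluster_size: int = 100
    total_target: int = 10_000
    gamma_z: float = 0.4055
    beta_x_treat: tuple[float, ...] = (0.35, 0.4, 0.45, 0.55, 0.0)
    beta_x_out: tuple[float, ...] = (0.35, 0.4, 0.45, 0.55, 0.0)
    gamma_z_out: float = 0.4055
    beta_instrument: float = 0.5
    beta_riskfactor: float = 0.5
    delta_interaction: float = 0.4055
    tau: float = 0.4055
    treat_prevalence_target: float = 0.5
    outcome_prevalence_target: float = 0.5
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.mean_cluster_size < 2:
            raise ValueError("mean_cluster_size must be >= 2")
        if self.total_target < self.n_clusters:
            raise ValueError("total_target must allow one patient per cluster")
        for name in ("treat_prevalence_target", "outcome_prevalence_target"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly inside (0, 1)")
        for name in ("beta_x_treat", "beta_x_out"):
            v = tuple(float(b) for b in getattr(self, name))
            if len(v) != 5:
                raise ValueError(f"{name} must have exactly 5 entries (x1..x5)")
            object.__setattr__(self, name, v)
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")

    @property
    def scenario_id(self) -> str:
        orr = float(np.exp(self.gamma_z))
        return f"m{self.n_clusters}_n{self.mean_cluster_size}_or{orr:.2f}"

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["beta_x_treat"] = list(d["beta_x_treat"])
        d["beta_x_out"] = list(d["beta_x_out"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("beta_x_treat", "beta_x_out"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def derived_seed(root_seed: int, *key: int) -> int:
    """Stable derived seed: SeedSequence(root, spawn_key=key), folded below 2**31."""
    ss = np.random.SeedSequence(int(root_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


def make_scenario_grid(
    defaults: ScenarioConfig | None = None,
    structures: tuple[tuple[int, int], ...] | None = None,
    gamma_grid: tuple[float, ...] | None = None,
) -> list[ScenarioConfig]:
    """Build the scenario grid: cluster structures crossed with ``gamma_z``.

    With the canonical structures and gamma grid this yields the full
    twenty-scenario study design.  Each scenario receives a distinct seed
    derived from ``defaults.seed``.
    """
    defaults = defaults or ScenarioConfig()
    structures = tuple(structures) if structures is not None else CANONICAL_STRUCTURES
    gamma_grid = tuple(gamma_grid) if gamma_grid is not None else CANONICAL_GAMMA_GRID
    grid = []
    idx = 0
    for m, n in structures:
        for g in gamma_grid:
            grid.append(
                defaults.replace(
                    n_clusters=int(m),
                    mean_cluster_size=int(n),
                    gamma_z=float(g),
                    seed=derived_seed(defaults.seed, idx),
                )
            )
            idx += 1
    return grid


def grid_to_yaml(configs: list[ScenarioConfig], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"scenarios": [c.to_dict() for c in configs]}, fh, sort_keys=False)


def grid_from_yaml(path) -> list[ScenarioConfig]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [ScenarioConfig.from_dict(d) for d in payload["scenarios"]]
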