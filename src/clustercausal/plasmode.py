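"""Plasmode simulation against a hospital pancreatectomy-style base cohort.

Plasmode simulation resamples the joint covariate rows of a real cohort with
replacement (preserving the empirical covariate dependence structure) and
then generates treatment and outcome from investigator-specified logistic
models with a known true effect.  The real base cohort this emulates — a US
hospital all-payer cohort of 9981 adult pancreatectomy admissions across 341
hospitals (2015-2019) — is not publicly available, so the module ships a
seeded *synthetic* stand-in with the same shape: patient age, sex and
Charlson comorbidity index; hospital teaching status, size (>= 500 beds) and
yearly procedure volume; roughly 30 patients per hospital.  Any user-supplied
CSV with the same schema is accepted interchangeably.

Continuous covariates are standardized (base-cohort mean/SD) before
receiving coefficients so the odds-ratio grid is comparable with the
parametric arm; the hospital-level covariates carry the cluster-confounding
coefficient ``gamma_z`` on the treatment model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, poisson, truncnorm

from .config import derived_seed
from .parametric import DegenerateCohortError, calibrate_intercept

BASE_COHORT_COLUMNS = (
    "patient_id", "hospital_id", "age", "sex", "charlson",
    "teaching", "large_hospital", "annual_volume",
)

#: Patient-level covariates (standardized where continuous) and their
#: hospital-level counterparts in the simulated design.
PATIENT_COVARIATES = ("age_std", "sex", "charlson_std")
HOSPITAL_COVARIATES = ("teaching", "large_hospital", "volume_std")
PLASMODE_COVARIATES = PATIENT_COVARIATES + HOSPITAL_COVARIATES


def generate_synthetic_base_cohort(n_patients: int = 9981, n_hospitals: int = 341,
                                   seed: int = 0) -> pd.DataFrame:
    """Seeded synthetic base cohort with the published cohort's shape.

    Hospital sizes are multinomial around ~30 patients each; age is truncated
    Normal(65, 12) floored at 18; Charlson is a Poisson(2)-marginal count
    rank-correlated with age (~0.3); hospital yearly volume tracks the
    hospital's cohort share, and teaching / large-hospital status are more
    likely at high-volume centres.
    """
    if n_patients < n_hospitals:
        raise ValueError("need at least one patient per hospital")
    rng = np.random.default_rng(seed)
    m = int(n_hospitals)

    # hospital sizes: heterogeneous multinomial, every hospital >= 1 patient
    raw_w = rng.lognormal(mean=0.0, sigma=0.6, size=m)
    sizes = rng.multinomial(n_patients - m, raw_w / raw_w.sum()) + 1

    volume_latent = sizes / 5.0  # five accrual years
    annual_volume = np.maximum(
        1, np.round(volume_latent * rng.lognormal(0.0, 0.15, size=m))
    ).astype(int)
    vol_std = (annual_volume - annual_volume.mean()) / annual_volume.std()
    teaching = (rng.random(m) < expit(-0.8 + 1.2 * vol_std)).astype(np.int8)
    large = (rng.random(m) < expit(-0.4 + 1.0 * vol_std)).astype(np.int8)

    n = int(sizes.sum())
    hospital_id = np.repeat(np.arange(m), sizes)
    a, b = (18.0 - 65.0) / 12.0, np.inf
    age = truncnorm.rvs(a, b, loc=65.0, scale=12.0, size=n, random_state=rng)
    sex = (rng.random(n) < 0.5).astype(np.int8)
    # Gaussian-copula coupling of Charlson to age, rank correlation ~ 0.3
    age_z = (age - age.mean()) / age.std()
    latent = 0.31 * age_z + np.sqrt(1.0 - 0.31**2) * rng.standard_normal(n)
    charlson = poisson(2.0).ppf(norm.cdf(latent)).astype(int)

    return pd.DataFrame({
        "patient_id": np.arange(n),
        "hospital_id": hospital_id,
        "age": age,
        "sex": sex,
        "charlson": charlson,
        "teaching": np.repeat(teaching, sizes),
        "large_hospital": np.repeat(large, sizes),
        "annual_volume": np.repeat(annual_volume, sizes),
    })


def read_base_cohort(path) -> pd.DataFrame:
    base = pd.read_csv(path)
    missing = [c for c in BASE_COHORT_COLUMNS if c not in base.columns]
    if missing:
        raise ValueError(f"base cohort is missing columns: {missing}")
    return base


def write_base_cohort(base: pd.DataFrame, path) -> None:
    base.to_csv(path, index=False)


@dataclass
class PlasmodeConfig:
    """Exposure/outcome generation settings for the plasmode arm.

    The exposure and outcome coefficient values of the original study live in
    an inaccessible supplement; the defaults here are declared package
    choices mirroring the parametric arm's coefficient magnitudes, with
    ``gamma_z`` applied to every hospital-level covariate on the treatment
    model and 0.4055 on the outcome model.
    """

    n_sim: int | None = None          # default: base cohort size
    gamma_z: float = 0.4055
    tau: float = 0.4055
    exposure_coefs: dict = field(default_factory=lambda: {
        "age_std": 0.35, "sex": 0.4, "charlson_std": 0.45,
    })
    outcome_coefs: dict = field(default_factory=lambda: {
        "age_std": 0.35, "sex": 0.4, "charlson_std": 0.45,
        "teaching": 0.4055, "large_hospital": 0.4055, "volume_std": 0.4055,
    })
    treat_prevalence_target: float = 0.5
    outcome_prevalence_target: float = 0.5
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self):
        for name in ("treat_prevalence_target", "outcome_prevalence_target"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie strictly inside (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")

    @property
    def scenario_id(self) -> str:
        return f"plasmode_or{np.exp(self.gamma_z):.2f}"


def plasmode_resample(base: pd.DataFrame, n_sim: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Bootstrap rows of the base cohort with replacement (joint covariates)."""
    if len(base) == 0:
        raise ValueError("base cohort is empty")
    n_sim = int(n_sim) if n_sim is not None else len(base)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(base), size=n_sim)
    out = base.iloc[idx].reset_index(drop=True)
    out["patient_id"] = np.arange(n_sim)
    out["source_row"] = idx
    return out


def standardize_covariates(df: pd.DataFrame, base: pd.DataFrame) -> pd.DataFrame:
    """Add standardized continuous columns using base-cohort moments."""
    out = df.copy()
    for col, std_col in (("age", "age_std"), ("charlson", "charlson_std"),
                         ("annual_volume", "volume_std")):
        mu, sd = float(base[col].mean()), float(base[col].std())
        out[std_col] = (out[col] - mu) / (sd if sd > 0 else 1.0)
    return out


class PlasmodeSimulator:
    """Plasmode generator over a base cohort (statsmodels-style simulator)."""

    def __init__(self, base: pd.DataFrame, config: PlasmodeConfig):
        if len(base) == 0:
            raise ValueError("base cohort is empty")
        self.base = base
        self.config = config

    def _linear_predictors(self, df: pd.DataFrame):
        c = self.config
        lp_t = np.zeros(len(df))
        for col, coef in c.exposure_coefs.items():
            lp_t += coef * df[col].to_numpy(dtype=float)
        for col in HOSPITAL_COVARIATES:
            lp_t += c.gamma_z * df[col].to_numpy(dtype=float)
        lp_y = np.zeros(len(df))
        for col, coef in c.outcome_coefs.items():
            lp_y += coef * df[col].to_numpy(dtype=float)
        return lp_t, lp_y

    def simulate(self, rep_seed: int) -> pd.DataFrame:
        """One plasmode replication: resample covariates, generate T and Y."""
        c = self.config
        for attempt in (0, 1):
            seed = derived_seed(c.seed, rep_seed, attempt)
            rng = np.random.default_rng(seed)
            res = plasmode_resample(self.base, c.n_sim, seed=derived_seed(c.seed, rep_seed, 10 + attempt))
            df = standardize_covariates(res, self.base)
            lp_t, lp_y = self._linear_predictors(df)
            alpha0 = calibrate_intercept(lambda k: lp_t, c.treat_prevalence_target,
                                         n_mc=len(df))
            t = (rng.random(len(df)) < expit(alpha0 + lp_t)).astype(np.int8)
            lp_y_full = lp_y + c.tau * t
            lambda0 = calibrate_intercept(lambda k: lp_y_full, c.outcome_prevalence_target,
                                          n_mc=len(df))
            y = (rng.random(len(df)) < expit(lambda0 + lp_y_full)).astype(np.int8)
            if t.min() != t.max() and y.min() != y.max():
                out = df[["patient_id"]].copy()
                out["cluster_id"] = df["hospital_id"].to_numpy()
                for col in PLASMODE_COVARIATES:
                    out[col] = df[col].to_numpy()
                out["treatment"] = t
                out["outcome"] = y
                return out
        raise DegenerateCohortError(
            f"constant treatment or outcome after redraw (plasmode rep {rep_seed})"
        )


def plasmode_simulate(base: pd.DataFrame, config: PlasmodeConfig, rep_seed: int) -> pd.DataFrame:
    """Functional wrapper around :class:`PlasmodeSimulator`."""
    return PlasmodeSimulator(base, config).simulate(rep_seed)
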