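"""Cohort table I/O: CSV by default, Parquet when the path says so."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .config import COHORT_COLUMNS


def write_cohort(cohort: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix in (".parquet", ".pq"):
        cohort.to_parquet(path, index=False)
    else:
        cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_parquet(path) if path.suffix in (".parquet", ".pq") else pd.read_csv(path)
    missing = [c for c in ("cluster_id", "treatment", "outcome") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing required columns: {missing}")
    return df


def validate_cohort(df: pd.DataFrame) -> None:
    """Check the parametric cohort schema and its structural invariants."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing cohort columns: {missing}")
    for col in ("treatment", "outcome"):
        vals = set(df[col].unique())
        if not vals <= {0, 1}:
            raise ValueError(f"{col} must be binary 0/1")
    for col in ("z1", "z2"):
        if df.groupby("cluster_id")[col].nunique().max() > 1:
            raise ValueError(f"{col} must be constant within clusters")
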