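"""Metric panels: Rbias / EmpSE / coverage by scenario and estimator."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_PANELS = (
    ("rbias_pct", "Average absolute relative bias (%)"),
    ("emp_se", "Empirical SE"),
    ("coverage", "95% CI coverage"),
)


def plot_metrics(metrics: pd.DataFrame, out_dir, fmt: str = "png") -> list[str]:
    """Write one grouped-bar panel per metric; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    scenarios = sorted(metrics["scenario_id"].unique())
    estimators = sorted(metrics["estimator"].unique())
    for col, label in _PANELS:
        fig, ax = plt.subplots(figsize=(1.4 + 1.1 * len(scenarios), 4.0))
        width = 0.8 / max(len(estimators), 1)
        for k, est in enumerate(estimators):
            sub = metrics[metrics["estimator"] == est].set_index("scenario_id")
            vals = [sub[col].get(s, float("nan")) for s in scenarios]
            ax.bar([i + k * width for i in range(len(scenarios))], vals,
                   width=width, label=est)
        if col == "coverage":
            ax.axhline(0.95, color="grey", ls="--", lw=0.8)
        ax.set_xticks([i + 0.4 - width / 2 for i in range(len(scenarios))])
        ax.set_xticklabels(scenarios, rotation=30, ha="right", fontsize=8)
        ax.set_ylabel(label)
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out_dir / f"{col}.{fmt}"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(str(path))
    return paths
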