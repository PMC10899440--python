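"""Cosmetic figures: learning curves, parameter distributions, age scatters.

None of these are contract-bearing; the pipeline's numeric artifacts are the
record of results.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .curves import LearningCurveFit


def plot_learning_curves(curves: pd.DataFrame, fit: Optional[LearningCurveFit] = None,
                         path: str | Path = "learning_curves.png") -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    for ns, sub in curves.groupby("set_size"):
        ax.plot(sub["iteration"], sub["mean_correct"], marker="o", label=f"ns={ns}")
    if fit is not None:
        ts = np.linspace(1, curves["iteration"].max(), 100)
        ax.plot(ts, fit.predict(ts), "--", color="goldenrod", label="growth fit")
    ax.set_xlabel("presentation index")
    ax.set_ylabel("proportion correct")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_parameter_distributions(table: pd.DataFrame,
                                 path: str | Path = "parameters.png") -> Path:
    params = ["alpha", "phi", "rho", "epsilon"]
    fig, axes = plt.subplots(1, 4, figsize=(12, 3), sharey=False)
    groups = sorted(table["group"].dropna().unique())
    for ax, p in zip(axes, params):
        data = [table.loc[table["group"] == g, p] for g in groups]
        ax.violinplot(data, showmeans=True)
        ax.set_xticks(range(1, len(groups) + 1), groups, rotation=30, fontsize=7)
        ax.set_title(p)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_age_scatter(values, ages, label: str,
                     path: str | Path = "age_scatter.png") -> Path:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(ages, values, s=12, alpha=0.7)
    slope, intercept = np.polyfit(ages, values, 1)
    xs = np.linspace(min(ages), max(ages), 10)
    ax.plot(xs, slope * xs + intercept, color="crimson")
    ax.set_xlabel("age (years)")
    ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
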