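"""File-based plots: RMR response curves and beta interval panels.

Everything renders straight to files (Agg backend) so analyses are
reproducible in headless runs; nothing ever opens a window.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .stats import GroupSummary

__all__ = ["plot_rmr_curves", "plot_beta_intervals"]


def plot_rmr_curves(
    summaries: Sequence[GroupSummary],
    path: str | Path,
    title: str = "Relative movement ratio",
) -> Path:
    """Mean RMR vs time with 95% CI error bars, one line per group."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for s in summaries:
        ax.errorbar(
            s.times, s.mean, yerr=s.ci_half, marker="o", capsize=3, label=s.group
        )
    ax.axhline(1.0, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("time after treatment (min)")
    ax.set_ylabel("mean RMR")
    ax.set_title(title)
    ax.legend(fontsize=8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_beta_intervals(beta_summary: pd.DataFrame, path: str | Path) -> Path:
    """Mean beta with 95% CI per group (columns: group, mean_beta, ci_half)."""
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(beta_summary) + 1.5))
    ax.errorbar(
        beta_summary["mean_beta"],
        range(len(beta_summary)),
        xerr=beta_summary["ci_half"],
        fmt="o",
        capsize=3,
    )
    ax.set_yticks(range(len(beta_summary)))
    ax.set_yticklabels(beta_summary["group"], fontsize=8)
    ax.set_xlabel("beta (−slope of WI vs transformed time)")
    ax.axvline(0, color="gray", lw=0.8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
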