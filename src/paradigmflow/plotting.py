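"""Figure glue: trajectory panels and mean shift-time curves.

Plots are qualitative instruments (regime shapes, migration patterns),
not pixel artifacts; they are rendered with the Agg backend so they work
headless.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dynamics import TrajectoryRecord

__all__ = ["plot_trajectories", "plot_sweep"]


def plot_trajectories(
    records: dict[float, TrajectoryRecord], path: str | Path
) -> Path:
    """Panel of agent-position-vs-time plots, one panel per alpha.

    The canonical four-panel layout uses alpha in {0, 0.15, 0.7, 1}: a
    linear, uncoordinated migration at alpha=0 versus the stepped
    "pioneers then swift collective migration" pattern at small positive
    alpha.
    """
    if not records:
        raise ValueError("no trajectory records to plot")
    for alpha, rec in records.items():
        if rec.sample_times.size == 0:
            raise ValueError(
                f"record for alpha={alpha} has no sampled positions "
                "(was it run with record_every=0?)"
            )
    k = len(records)
    ncols = 2 if k > 1 else 1
    nrows = (k + ncols - 1) // ncols
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(5.5 * ncols, 3.4 * nrows), squeeze=False
    )
    for ax, (alpha, rec) in zip(axes.ravel(), sorted(records.items())):
        ax.plot(rec.sample_times, rec.position_matrix, lw=0.6, alpha=0.8)
        ax.set_xlabel("t")
        ax.set_ylabel("agent position x")
        ax.set_title(f"alpha = {alpha:g}")
    for ax in axes.ravel()[k:]:
        ax.set_visible(False)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_sweep(table: pd.DataFrame, path: str | Path) -> Path:
    """Mean shift time vs alpha, one curve per community size, with SE bars."""
    required = {"alpha", "n", "mean_ts", "se_ts"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"sweep table is missing column(s) {sorted(missing)}")
    if table.empty:
        raise ValueError("sweep table is empty")
    fig, ax = plt.subplots(figsize=(6.5, 4.2))
    for n, sub in table.groupby("n"):
        sub = sub.sort_values("alpha")
        ax.errorbar(
            sub["alpha"], sub["mean_ts"], yerr=sub["se_ts"],
            marker="o", ms=3, capsize=2, lw=1, label=f"n = {n}",
        )
    ax.set_xlabel("alpha (weight on social influence)")
    ax.set_ylabel("mean time to paradigm shift")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
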