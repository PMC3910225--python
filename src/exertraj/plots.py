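"""Optional figure rendering (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def _pyplot():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "plotting requires matplotlib (install exertraj[plots])"
        ) from exc
    return plt


def plot_rmse_differences(
    differences: Mapping[tuple[str, str], pd.DataFrame],
    path: "str | Path",
) -> None:
    """Panel per family pair: RMSE difference vs. estimated delay with the
    loess trend."""
    plt = _pyplot()
    pairs = list(differences)
    fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 3.5),
                             squeeze=False)
    for ax, pair in zip(axes[0], pairs):
        frame = differences[pair]
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.scatter(frame["delay"], frame["delta_rmse"], s=14, alpha=0.7)
        if "smooth" in frame.columns:
            ax.plot(frame["delay"], frame["smooth"], color="crimson")
        ax.set_xlabel("estimated delay (fraction of Wmax)")
        ax.set_ylabel(f"RMSE {pair[0]} - RMSE {pair[1]}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cluster_panels(
    cohort: Sequence,
    labels: Mapping[str, int],
    mean_curves: pd.DataFrame,
    path: "str | Path",
    n_cols: int = 3,
) -> None:
    """One panel per cluster: member trajectories plus the cluster mean."""
    plt = _pyplot()
    clusters = sorted(set(labels.values()))
    n_rows = int(np.ceil(len(clusters) / n_cols))
    fig, axes = plt.subplots(n_rows, n_cols,
                             figsize=(3.2 * n_cols, 2.6 * n_rows),
                             squeeze=False, sharex=True, sharey=True)
    for ax, cluster in zip(axes.ravel(), clusters):
        for traj in cohort:
            if labels.get(traj.subject_id) == cluster:
                ax.plot(traj.x, traj.y, color="grey", alpha=0.4, lw=0.8)
        mc = mean_curves[mean_curves["cluster"] == cluster]
        ax.plot(mc["x"], mc["mean_rating"], color="crimson", lw=1.6)
        ax.set_title(f"cluster {cluster}", fontsize=9)
    for ax in axes.ravel()[len(clusters):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
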