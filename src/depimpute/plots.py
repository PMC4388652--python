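"""Quick-look figures for study reports (RMSE vs k; TPR/FDR per grid cell)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_k_sweep", "plot_study"]


def plot_k_sweep(sweep: pd.DataFrame, path: str | Path) -> None:
    """Mean RMSE against neighbor count k."""
    agg = sweep.groupby("k")["rmse"].mean()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(agg.index, agg.values, marker="o")
    ax.set_xlabel("number of neighbors k")
    ax.set_ylabel("RMSE")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_study(report: pd.DataFrame, path: str | Path, alpha: float = 0.05) -> None:
    """Mean TPR and FDR per (N, missing %) cell, one line per method."""
    agg = (
        report.groupby(["N", "missing_pct", "method"])[["tpr", "fdr"]]
        .mean()
        .reset_index()
    )
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for metric, ax in zip(("tpr", "fdr"), axes):
        for method, sub in agg.groupby("method"):
            labels = sub["N"].astype(str) + "/" + sub["missing_pct"].astype(str) + "%"
            ax.plot(labels, sub[metric], marker="o", label=method)
        ax.set_ylabel(metric.upper())
        ax.tick_params(axis="x", rotation=45)
    axes[1].axhline(alpha, color="red", linestyle=":")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
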