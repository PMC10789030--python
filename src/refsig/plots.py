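"""Trajectory and mean-ROC figures for reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .refs import RefsResult
from .validation import FPR_GRID, ValidationReport

__all__ = ["plot_trajectory", "plot_mean_roc"]


def plot_trajectory(result: RefsResult, path: str | Path) -> None:
    """Accuracy vs feature count for the reported REFS run."""
    n = [s.n_features for s in result.trajectory]
    acc = [s.mean_accuracy for s in result.trajectory]
    std = [s.accuracy_std for s in result.trajectory]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(n, acc, yerr=std, marker="o", markersize=3, lw=1, capsize=2)
    best = result.selected.size
    ax.axvline(best, color="crimson", ls="--", lw=1, label=f"selected: {best} features")
    ax.set_xscale("log")
    ax.set_xlabel("number of features")
    ax.set_ylabel("mean ensemble accuracy")
    ax.set_title("REFS elimination trajectory")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mean_roc(report: ValidationReport, path: str | Path) -> None:
    """Vertically averaged ROC per classifier, with +/- 1 std bands."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for perf in report.per_classifier:
        if perf.mean_tpr is None:
            continue
        ax.plot(FPR_GRID, perf.mean_tpr, lw=1.5,
                label=f"{perf.name} (AUC {perf.mean_auc:.2f})")
        ax.fill_between(
            FPR_GRID,
            np.clip(perf.mean_tpr - perf.tpr_std, 0, 1),
            np.clip(perf.mean_tpr + perf.tpr_std, 0, 1),
            alpha=0.15,
        )
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"{report.dataset_name}: {report.n_features_used} features")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
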