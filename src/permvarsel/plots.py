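"""Standard graphics for importance profiles and model-choice summaries.

All functions draw on a provided axes (or create one) and return the axes,
so they compose with any matplotlib workflow; the ``save_*`` helpers write
the usual multi-panel reports to disk.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .importance import ImportanceResult
from .modelchoice import ChoiceSummary
from .selection import SelectionResult

__all__ = [
    "vi_boxplots",
    "sorted_means_plot",
    "mse_boxplots",
    "size_barplots",
    "occurrence_barplots",
    "save_importance_report",
    "save_choice_report",
]


def _axes(ax):
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    return ax


def vi_boxplots(imp: ImportanceResult, ax=None):
    """Per-covariate boxplots of the VI replications; baseline MSE as a line."""
    ax = _axes(ax)
    cols = [imp.vi[:, j][~np.isnan(imp.vi[:, j])] for j in range(imp.p)]
    ax.boxplot(cols, tick_labels=list(imp.names))
    ax.axhline(imp.baseline_mse, color="red", linestyle="--", label="baseline MSE")
    ax.set_ylabel("variable importance (VI)")
    ax.tick_params(axis="x", rotation=90)
    ax.legend()
    return ax


def sorted_means_plot(imp: ImportanceResult, selection: SelectionResult | None = None, ax=None):
    """Mean VI sorted decreasingly; optional change-point and baseline lines."""
    ax = _axes(ax)
    means = imp.means
    order = np.argsort(-means, kind="stable")
    ax.plot(range(1, imp.p + 1), means[order], "o-")
    ax.axhline(imp.baseline_mse, color="red", linestyle="--", label="baseline MSE")
    if selection is not None and selection.rule == "changepoint" and not selection.diagnostics.get("no_change", True):
        ax.axvline(selection.threshold_value + 0.5, color="blue", label="change point")
    ax.set_xticks(range(1, imp.p + 1))
    ax.set_xticklabels([imp.names[j] for j in order], rotation=90)
    ax.set_ylabel("mean VI (sorted)")
    ax.legend()
    return ax


def mse_boxplots(summary: ChoiceSummary, ax=None):
    """Parallel boxplots of MSE_test, one per regression method."""
    ax = _axes(ax)
    cols = [
        summary.mse_matrix[:, k][~np.isnan(summary.mse_matrix[:, k])]
        for k in range(len(summary.methods))
    ]
    ax.boxplot(cols, tick_labels=list(summary.methods))
    ax.set_ylabel("MSE_test")
    return ax


def size_barplots(summary: ChoiceSummary, method: str, ax=None):
    """Barplot of the number of covariates selected in the M final models."""
    ax = _axes(ax)
    dist = summary.size_distribution()[method]
    sizes = sorted(dist)
    total = sum(dist.values())
    ax.bar([str(s) for s in sizes], [100.0 * dist[s] / total for s in sizes])
    ax.set_xlabel("selected model size")
    ax.set_ylabel("% of replications")
    ax.set_title(method)
    return ax


def occurrence_barplots(summary: ChoiceSummary, method: str, ax=None):
    """Barplot of each covariate's selection frequency across replications."""
    ax = _axes(ax)
    occ = summary.occurrence()[method]
    ax.bar(occ.index, 100.0 * occ.to_numpy())
    ax.set_ylabel("% occurrence in final model")
    ax.tick_params(axis="x", rotation=90)
    ax.set_title(method)
    return ax


def save_importance_report(
    imp: ImportanceResult, selection: SelectionResult | None, path: str | Path
) -> None:
    """Two-panel report: VI boxplots and the sorted-means/threshold plot."""
    fig, axes = plt.subplots(1, 2, figsize=(13, 5))
    vi_boxplots(imp, ax=axes[0])
    sorted_means_plot(imp, selection, ax=axes[1])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_choice_report(summary: ChoiceSummary, path: str | Path) -> None:
    """MSE boxplots plus per-method size and occurrence barplots."""
    k = len(summary.methods)
    fig, axes = plt.subplots(k, 3, figsize=(15, 4 * k), squeeze=False)
    for row, method in enumerate(summary.methods):
        mse_boxplots(summary, ax=axes[row][0])
        size_barplots(summary, method, ax=axes[row][1])
        occurrence_barplots(summary, method, ax=axes[row][2])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
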