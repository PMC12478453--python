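"""Minimal plotting helpers (volcano, heatmap, ROC, embedding).

Each function draws onto a provided or fresh matplotlib Axes and returns
it; figure styling is left to the caller.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends
import matplotlib.pyplot as plt


def volcano_plot(volcano: pd.DataFrame, ax=None, alpha: float = 0.05):
    """log2 fold change vs -log10 p, significant features highlighted."""
    ax = ax or plt.subplots()[1]
    sig = volcano["significant"].to_numpy(bool)
    x = volcano["log2_fc"]
    y = -np.log10(volcano["p_value"])
    ax.scatter(x[~sig], y[~sig], s=12, c="0.6", label="ns")
    ax.scatter(x[sig], y[sig], s=14, c="crimson", label=f"p < {alpha:g}")
    ax.axhline(-np.log10(alpha), ls="--", lw=0.8, c="0.4")
    ax.axvline(0, ls=":", lw=0.8, c="0.4")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    return ax


def correlation_heatmap(r: pd.DataFrame, ax=None):
    """Pearson r matrix as a +/-1 diverging image with labelled axes."""
    ax = ax or plt.subplots()[1]
    im = ax.imshow(r.to_numpy(float), vmin=-1, vmax=1, cmap="RdBu_r",
                   aspect="auto")
    ax.set_xticks(range(r.shape[1]), [str(c) for c in r.columns],
                  rotation=90, fontsize=6)
    ax.set_yticks(range(r.shape[0]), [str(i) for i in r.index], fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="Pearson r")
    return ax


def roc_curve_plot(scores, labels, ax=None, label: str | None = None):
    """Empirical ROC curve from scores and binary labels."""
    ax = ax or plt.subplots()[1]
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    order = np.argsort(-scores, kind="mergesort")
    tps = np.cumsum(labels[order])
    fps = np.cumsum(~labels[order])
    tpr = np.r_[0, tps / labels.sum()]
    fpr = np.r_[0, fps / (~labels).sum()]
    ax.plot(fpr, tpr, label=label)
    ax.plot([0, 1], [0, 1], ls=":", c="0.5", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if label:
        ax.legend(frameon=False, fontsize=8)
    return ax


def embedding_plot(coordinates: pd.DataFrame, groups: pd.Series, ax=None):
    """2D embedding scatter coloured by group."""
    ax = ax or plt.subplots()[1]
    groups = groups.reindex(coordinates.index)
    for g, sub in coordinates.groupby(groups):
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], s=16, label=str(g))
    ax.set_xlabel(coordinates.columns[0])
    ax.set_ylabel(coordinates.columns[1])
    ax.legend(frameon=False, fontsize=8)
    return ax
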