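"""Thin matplotlib plumbing for the standard diagnostic plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .evaluate import NullDistribution, RocResult
from .scoring import RiskGrouping, ScoreTable


def plot_roc(roc: RocResult, ax: "plt.Axes | None" = None, label: str | None = None):
    """ROC step curve with the chance diagonal."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    fpr = np.r_[0.0, 1.0 - roc.specificity]
    sens = np.r_[0.0, roc.sensitivity]
    ax.plot(fpr, sens, drawstyle="steps-post",
            label=label or f"AUC = {roc.auc:.2f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", frameon=False)
    return ax


def plot_null_density(null: NullDistribution, ax: "plt.Axes | None" = None):
    """Histogram of null AUC-sum draws with the observed value marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.hist(null.draws, bins=40, density=True, alpha=0.6, label=f"random k={null.k}")
    if np.isfinite(null.observed):
        ax.axvline(null.observed, color="red",
                   label=f"observed = {null.observed:.2f} (p = {null.empirical_p:.3g})")
    ax.set_xlabel("AUC sum")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    return ax


def plot_score_groups(
    table: ScoreTable, grouping: RiskGrouping, ax: "plt.Axes | None" = None
):
    """Violin-style summary of scores by risk group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.5, 4))
    frame = pd.DataFrame({"score": table.scores, "group": grouping.groups})
    groups = sorted(frame["group"].unique())
    data = [frame.loc[frame["group"] == g, "score"].to_numpy() for g in groups]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(groups) + 1), groups)
    ax.axhline(grouping.threshold, ls=":", c="grey", lw=0.8)
    ax.set_ylabel("survival score")
    return ax
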