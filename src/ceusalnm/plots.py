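"""Figure helpers: ROC curves, decision curves and score box plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.stats import mannwhitneyu

from .evaluation import NetBenefitCurve, roc_auc


def plot_roc(y_true, y_score, label: str = "model", path=None, ax=None):
    """ROC curve with the AUC in the legend and the chance diagonal."""
    area, fpr, tpr = roc_auc(y_true, y_score)
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(fpr, tpr, label=f"{label} (AUC = {area:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="random guess (AUC = 0.5)")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_decision_curve(curve: NetBenefitCurve, label: str = "model", path=None, ax=None):
    """Net benefit against threshold probability with treat-all/none refs."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.thresholds, curve.net_benefit, label=label)
    ax.plot(curve.thresholds, curve.treat_all, ":", label="treat all")
    ax.plot(curve.thresholds, curve.treat_none, "k-", lw=0.8, label="treat none")
    ax.set_ylim(bottom=min(-0.05, float(curve.net_benefit.min()) - 0.02))
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend(fontsize=8)
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_score_box(y_true, y_score, path=None, ax=None):
    """Per-class box plot of predicted scores with a Mann-Whitney p-value."""
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    groups = [y_score[y_true == 0], y_score[y_true == 1]]
    if ax is None:
        _, ax = plt.subplots(figsize=(3.5, 4))
    ax.boxplot(groups, tick_labels=["non-metastatic", "metastatic"])
    if len(groups[0]) and len(groups[1]):
        p = mannwhitneyu(groups[0], groups[1], alternative="two-sided").pvalue
        ax.set_title(f"Mann-Whitney p = {p:.2e}", fontsize=9)
    ax.set_ylabel("metastatic-class probability")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
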