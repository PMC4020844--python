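"""Plotting helpers for size-performance, stability and ROC curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first
import matplotlib.pyplot as plt


def plot_size_curve(curve, ax=None):
    """Mean out-of-bag ROC vs. signature size with SD whiskers."""
    ax = ax or plt.gca()
    agg = curve.aggregate()
    ax.errorbar(agg["size"], agg["mean_roc"], yerr=agg["sd_roc"].fillna(0.0),
                marker="o", capsize=3)
    ax.set_xlabel("number of informative genes")
    ax.set_ylabel("mean out-of-bag ROC score")
    ax.set_ylim(0, 1.05)
    return ax


def plot_stability_curve(stability_frame, ax=None):
    """Mean Kuncheva index vs. signature size, one line per method."""
    ax = ax or plt.gca()
    for method, group in stability_frame.groupby("method"):
        ax.plot(group["size"], group["mean_ki"], marker="o", label=method)
    ax.set_xlabel("number of informative genes")
    ax.set_ylabel("mean Kuncheva index")
    ax.set_ylim(-1.05, 1.05)
    ax.legend()
    return ax


def plot_roc(report, ax=None):
    """Threshold-averaged ROC curve per classifier from an EvaluationReport."""
    ax = ax or plt.gca()
    for name, ev in report.per_classifier.items():
        if ev.averaged_curve is None:
            continue
        c = ev.averaged_curve
        ax.plot(c.fpr, c.tpr, label=f"{name} (AUC {c.auc:.2f})")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    return ax
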