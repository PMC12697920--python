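"""Basic Bland-Altman and ROC figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .comparison_stats import BlandAltmanResult


def bland_altman_plot(values_a, values_b, result: BlandAltmanResult, ax=None, title: str = ""):
    """Scatter of pair differences vs means with MD and 95% limits of agreement."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    means = (a + b) / 2.0
    ax.scatter(means, a - b, s=12, alpha=0.6)
    ax.axhline(result.mean_difference, color="k", lw=1, label=f"MD={result.mean_difference:.2f}")
    for y, lab in ((result.loa_low, "LoA low"), (result.loa_high, "LoA high")):
        ax.axhline(y, color="r", ls="--", lw=1, label=f"{lab}={y:.2f}")
    ax.set_xlabel(f"mean of methods ({result.metric})")
    ax.set_ylabel("difference (actigraphy - PSG)")
    ax.set_title(title or f"{result.method_pair[0]} vs {result.method_pair[1]}")
    ax.legend(fontsize=7)
    return ax


def roc_plot(roc_results: dict, ax=None):
    """Overlayed ROC curves; ``roc_results`` maps algorithm name -> ROCResult."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for name, res in roc_results.items():
        ax.plot(res.fpr, res.tpr, lw=1, label=f"{name} (AUC={res.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate (1 - specificity)")
    ax.set_ylabel("true positive rate (sensitivity)")
    ax.legend(fontsize=7)
    return ax
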