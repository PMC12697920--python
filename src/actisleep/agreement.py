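"""Epoch-by-epoch agreement between actigraphy and polysomnography.

PSG is the actual class and actigraphy the predicted class, with sleep=1
as the positive class throughout (so sensitivity measures sleep
detection).  Degenerate metrics (zero denominators, e.g. MCC for a
constant predictor) are reported as NaN together with a reason code,
never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .epoch_io import BINARY, EpochSeries, ValidationError
from .scoring import ScoreSeries

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1", "kappa", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with sleep as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class AgreementResult:
    """Derived agreement metrics for one participant-night and method.

    ``undefined`` maps metric name -> reason code for metrics whose
    denominator is degenerate; those metrics are NaN.
    """

    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    kappa: float
    mcc: float
    undefined: dict[str, str] = field(default_factory=dict)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    undefined: str | None = None


def confusion(pred: EpochSeries, actual: EpochSeries) -> ConfusionCounts:
    """Count TP/FP/TN/FN for predicted vs actual binary sleep-wake series."""
    if pred.kind != BINARY or actual.kind != BINARY:
        raise ValidationError("confusion requires binary sleep-wake series")
    if len(pred) != len(actual):
        raise ValidationError(f"length mismatch: {len(pred)} vs {len(actual)}")
    p = pred.values.astype(bool)
    a = actual.values.astype(bool)
    return ConfusionCounts(
        tp=int((p & a).sum()),
        fp=int((p & ~a).sum()),
        tn=int((~p & ~a).sum()),
        fn=int((~p & a).sum()),
    )


def agreement_metrics(c: ConfusionCounts) -> AgreementResult:
    """Standard confusion-matrix metrics plus Cohen kappa and MCC.

    kappa uses chance agreement from the marginals; MCC is
    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    if c.total <= 0:
        raise ValidationError("empty confusion table")
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    n = float(c.total)
    undefined: dict[str, str] = {}

    def ratio(num: float, den: float, name: str, reason: str) -> float:
        if den == 0:
            undefined[name] = reason
            return math.nan
        return num / den

    accuracy = (tp + tn) / n
    sensitivity = ratio(tp, tp + fn, "sensitivity", "no actual-sleep epochs")
    specificity = ratio(tn, tn + fp, "specificity", "no actual-wake epochs")
    precision = ratio(tp, tp + fp, "precision", "no predicted-sleep epochs")
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "f1", "no sleep epochs in either series")

    p_obs = accuracy
    p_chance = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
    if p_chance == 1.0:
        undefined["kappa"] = "both raters constant"
        kappa = math.nan
    else:
        kappa = (p_obs - p_chance) / (1.0 - p_chance)

    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        undefined["mcc"] = "constant predictor or constant truth"
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom2)

    return AgreementResult(c, accuracy, sensitivity, specificity, precision, f1, kappa, mcc, undefined)


def roc_auc(
    raw_scores: ScoreSeries, actual: EpochSeries, orientation: str = "low_is_sleep"
) -> ROCResult:
    """ROC curve and AUC of raw algorithm scores against binary PSG truth.

    ``orientation`` declares the score direction: the linear scorers emit
    low values during sleep (``low_is_sleep``, scores are negated for the
    sweep), while Sadeh's probability-of-sleep is used as-is
    (``high_is_sleep``).  Sleep is the positive class; the sweep covers
    every distinct score value; AUC is the trapezoidal integral.
    """
    if actual.kind != BINARY:
        raise ValidationError("truth must be a binary sleep-wake series")
    if len(raw_scores) != len(actual):
        raise ValidationError("score/truth length mismatch")
    if orientation not in ("low_is_sleep", "high_is_sleep"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    y = actual.values
    if y.min() == y.max():
        return ROCResult(np.array([]), np.array([]), np.array([]), math.nan, "single-class truth")
    s = raw_scores.values if orientation == "high_is_sleep" else -raw_scores.values
    fpr, tpr, thresholds = _sk_roc_curve(y, s, pos_label=1)
    return ROCResult(thresholds, tpr, fpr, float(_sk_auc(fpr, tpr)))


def weighted_summary(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Weight-proportional mean and SD (frequency weights).

    NaN entries (undefined per-participant metrics) are dropped together
    with their weights before pooling.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0 or v.size != w.size:
        raise ValidationError("values and weights must be non-empty and aligned")
    if np.any(w < 0) or w.sum() == 0:
        raise ValidationError("weights must be nonnegative with positive sum")
    keep = ~np.isnan(v)
    v, w = v[keep], w[keep]
    if v.size == 0:
        return math.nan, math.nan
    mean = float(np.average(v, weights=w))
    sd = float(math.sqrt(np.average((v - mean) ** 2, weights=w)))
    return mean, sd
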