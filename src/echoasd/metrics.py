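"""Evaluation: confusion-matrix metrics, Dice overlap, ROC/AUC, Youden cut-point.

Conventions: a score equal to the threshold counts as a positive call
(">= threshold"), matching the decision rule used at the 0.95 confidence
cut-off.  Metrics with a zero denominator are reported as ``None``
(undefined), never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import ConfusionCounts

__all__ = [
    "classification_metrics",
    "f1_from_precision_recall",
    "dsc",
    "roc_auc",
    "youden_cutpoint",
    "wilson_interval",
    "mcnemar_test",
    "RocCurve",
]


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def classification_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, recall (sensitivity), precision, specificity and F1.

    accuracy    = (TP+TN) / (TP+FP+FN+TN)
    recall      = TP / (TP+FN)
    precision   = TP / (TP+FP)
    specificity = TN / (TN+FP)
    F1          = harmonic mean of precision and recall
    """
    if c.total == 0:
        raise ValueError("cannot evaluate metrics on empty counts")
    precision = _safe_div(c.tp, c.tp + c.fp)
    recall = _safe_div(c.tp, c.tp + c.fn)
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": _safe_div(c.tp + c.tn, c.total),
        "recall": recall,
        "precision": precision,
        "specificity": _safe_div(c.tn, c.tn + c.fp),
        "f1": f1,
    }


def f1_from_precision_recall(precision: float, recall: float) -> float:
    if precision + recall == 0:
        raise ValueError("F1 undefined when precision + recall == 0")
    return 2 * precision * recall / (precision + recall)


def dsc(a: np.ndarray, b: np.ndarray) -> float | None:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two binary masks.

    Symmetric; returns ``None`` (undefined) when both masks are empty.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share the same grid")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return None
    return 2.0 * int((a & b).sum()) / denom


@dataclass
class RocCurve:
    """Threshold sweep: (threshold, sensitivity, 1-specificity) per point,
    sorted so the curve runs from (0, 0) to (1, 1), plus trapezoidal AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    fpr: np.ndarray  # 1 - specificity
    auc: float


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve over the unique scores with trapezoidal AUC.

    ``labels`` are booleans (positive class = True); both classes must be
    present. Ties at a threshold are called positive ("score >= threshold").
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes to be present")

    # sweep thresholds from above the maximum (nothing called positive)
    # down through every unique score (everything called positive at the end)
    uniq = np.unique(scores)[::-1]
    thresholds = np.concatenate([[np.inf], uniq])
    sens = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        called = scores >= t
        sens[i] = (called & labels).sum() / n_pos
        fpr[i] = (called & ~labels).sum() / n_neg
    auc = float(np.trapezoid(sens, fpr))
    return RocCurve(thresholds, sens, fpr, auc)


def youden_cutpoint(curve: RocCurve) -> tuple[float, float]:
    """Threshold maximizing Youden's index J = sensitivity + specificity - 1.

    Ties are broken toward the higher threshold. Returns (threshold, J).
    The leading infinite pseudo-threshold is never returned; if it is the
    unique maximizer the highest finite threshold is reported instead.
    """
    j = curve.sensitivity - curve.fpr
    finite = np.isfinite(curve.thresholds)
    if not finite.any():
        raise ValueError("degenerate ROC curve")
    j_fin = np.where(finite, j, -np.inf)
    # thresholds are stored in descending order, so the first index within
    # rounding error of the maximum is the highest tied threshold
    best = int(np.argmax(j_fin >= j_fin.max() - 1e-12))
    return float(curve.thresholds[best]), float(j[best])


def wilson_interval(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Used as the package's 95% CI for reported rates; this is one standard
    construction among several and is documented as such.
    """
    if n == 0:
        raise ValueError("n must be positive")
    from scipy.stats import norm

    z = norm.ppf(0.5 + confidence / 2)
    p = successes / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def mcnemar_test(b: int, c: int) -> float:
    """McNemar's exact test p-value for paired binary decisions.

    ``b`` and ``c`` are the discordant-pair counts (method A right / B wrong
    and vice versa).  Appropriate for comparing calls before vs after
    refinement on the same frames.
    """
    from scipy.stats import binom

    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    p = 2 * binom.cdf(k, n, 0.5)
    return min(1.0, float(p))
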