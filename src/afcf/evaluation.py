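"""Diagnostic evaluation with AFib as the positive class everywhere.

Confusion-matrix counts, the five standard screening metrics
(sensitivity, specificity, PPV, NPV, F1), ROC / precision-recall curves
and trapezoidal AUC for continuous scorers, and single operating points
for categorical-only algorithms.  Undefined ratios (zero denominators)
are reported as ``nan`` sentinels; they never propagate into metrics
whose own denominator is fine (F1 is computed from counts).

Threshold convention: a record is called positive when its score is >= t,
with t swept over the distinct scores plus infinite sentinels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve

from .meta_table import RhythmLabel

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics",
           "roc_auc", "pr_curve", "operating_point"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary counts with AFib positive: TP+FN = #AFib, FP+TN = #non-AFib."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """The five screening metrics at full precision (round only to print).

    ``fnr``/``fpr`` are the complements of sensitivity/specificity.  AUC
    is attached only for continuous scorers.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    auc: float | None = None

    @property
    def fnr(self) -> float:
        return 1.0 - self.sensitivity

    @property
    def fpr(self) -> float:
        return 1.0 - self.specificity

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        out = {
            k: round(getattr(self, k), ndigits)
            for k in ("sensitivity", "specificity", "ppv", "npv", "f1")
        }
        if self.auc is not None:
            out["auc"] = round(self.auc, ndigits)
        return out


def _as_binary(values, what: str) -> np.ndarray:
    out = np.empty(len(values), dtype=int)
    for i, v in enumerate(values):
        if isinstance(v, RhythmLabel):
            if v == RhythmLabel.NOISY:
                raise ValueError(
                    f"{what}[{i}] is noisy; map noisy labels to a binary "
                    "class upstream before evaluation"
                )
            out[i] = int(v == RhythmLabel.AFIB)
        elif v in (0, 1, False, True):
            out[i] = int(v)
        else:
            raise ValueError(f"{what}[{i}] is not a binary symbol: {v!r}")
    return out


def confusion(labels, predictions) -> ConfusionMatrix:
    """Count TP/FN/FP/TN from aligned binary label/prediction sequences."""
    if len(labels) != len(predictions):
        raise ValueError(
            f"length mismatch: {len(labels)} labels vs {len(predictions)} predictions"
        )
    y = _as_binary(labels, "labels")
    p = _as_binary(predictions, "predictions")
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Sensitivity, specificity, PPV, NPV and F1 from counts.

    F1 = 2TP/(2TP+FP+FN), algebraically identical to the harmonic mean of
    PPV and sensitivity but defined whenever any of TP/FP/FN is nonzero.
    """
    f1_den = 2 * cm.tp + cm.fp + cm.fn
    return MetricsReport(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        f1=_ratio(2 * cm.tp, f1_den),
    )


def _check_scores(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    y = _as_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    if y.size != s.size:
        raise ValueError("labels and scores differ in length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.min(initial=1) == 1 or y.max(initial=0) == 0:
        raise ValueError("need at least one positive and one negative label")
    return y, s


def roc_auc(labels, scores) -> tuple[float, np.ndarray]:
    """Trapezoidal AUC and the full ROC staircase (fpr, tpr) points.

    The trapezoidal area over the complete threshold sweep equals the
    pairwise concordance statistic P(s+ > s-) + 0.5 P(s+ = s-).
    """
    y, s = _check_scores(labels, scores)
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def pr_curve(labels, scores) -> np.ndarray:
    """(recall, precision) points at each distinct score threshold."""
    y, s = _check_scores(labels, scores)
    precision, recall, _ = precision_recall_curve(y, s)
    return np.column_stack([recall, precision])


def operating_point(labels, predictions) -> tuple[float, float]:
    """(sensitivity, specificity) of a categorical algorithm — its single
    point on the ROC plane."""
    rep = metrics(confusion(labels, predictions))
    return rep.sensitivity, rep.specificity
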