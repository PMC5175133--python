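"""Binary-classification evaluation: Sn, Sp, Acc, MCC and rank-based ROC AUC.

Conventions: the positive class is the protein family of interest, so TP
counts family members correctly predicted and TN counts non-members
correctly predicted. MCC is defined as 0 whenever a factor under its square
root vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FN/FP/TN counts for a binary classifier."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def swapped(self) -> "ConfusionMatrix":
        """The matrix with the class labels exchanged."""
        return ConfusionMatrix(tp=self.tn, fn=self.fp, fp=self.fn, tn=self.tp)

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive=1) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos = y_true == positive
        hit = y_pred == y_true
        return cls(
            tp=int(np.count_nonzero(pos & hit)),
            fn=int(np.count_nonzero(pos & ~hit)),
            fp=int(np.count_nonzero(~pos & ~hit)),
            tn=int(np.count_nonzero(~pos & hit)),
        )

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fn + other.fn, self.fp + other.fp, self.tn + other.tn
        )


def sensitivity(cm: ConfusionMatrix) -> float:
    """Sn = TP / (TP + FN)."""
    if cm.tp + cm.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive instances")
    return cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """Sp = TN / (TN + FP)."""
    if cm.tn + cm.fp == 0:
        raise ZeroDivisionError("specificity undefined: no negative instances")
    return cm.tn / (cm.tn + cm.fp)


def accuracy(cm: ConfusionMatrix) -> float:
    """Acc = (TP + TN) / total."""
    return (cm.tp + cm.tn) / cm.total


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when a root factor is 0."""
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)


def metrics_report(cm: ConfusionMatrix) -> dict:
    """All four metrics, as fractions and as one-decimal percentages."""
    sn, sp, acc, m = sensitivity(cm), specificity(cm), accuracy(cm), mcc(cm)
    return {
        "tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn,
        "sensitivity": sn, "specificity": sp, "accuracy": acc, "mcc": m,
        "sensitivity_pct": round(100 * sn, 1),
        "specificity_pct": round(100 * sp, 1),
        "accuracy_pct": round(100 * acc, 1),
    }


def roc_auc(scores, labels, positive=1) -> float:
    """ROC area by the rank-sum identity: P(s_pos > s_neg) + 0.5 P(tie).

    Midranks handle ties, so the value equals tie-aware trapezoidal
    integration of the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_curve(scores, labels, positive=1) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC curve (FPR, TPR) at every distinct score threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels) == positive
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    scores = scores[order]
    tps = np.cumsum(labels)
    fps = np.cumsum(~labels)
    # keep only the last point of each tied-score run
    keep = np.r_[scores[1:] != scores[:-1], True]
    tpr = np.r_[0.0, tps[keep] / tps[-1]]
    fpr = np.r_[0.0, fps[keep] / fps[-1]]
    return fpr, tpr
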