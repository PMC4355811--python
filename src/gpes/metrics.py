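"""Evaluation measures: two-point AUC, micro-averaged F-score, average accuracy.

The AUC here is the hard-label two-point formula — the half-sum of
sensitivity and specificity (balanced accuracy) — appropriate for committees
that emit hard votes rather than scores. For multiclass problems the
micro-averaged precision/recall/F-score and the average per-class accuracy
(AAc) are computed from per-class one-vs-rest confusion counts; AAc penalises
a classifier that sacrifices a small "hard" class, which plain accuracy hides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix

__all__ = [
    "ConfusionCounts",
    "binary_confusion",
    "multiclass_confusion",
    "auc_binary",
    "micro_fscore",
    "average_accuracy",
]


@dataclass
class ConfusionCounts:
    """Per-class confusion counts; binary problems use a single class entry.

    ``tp[i], tn[i], fp[i], fn[i]`` are the one-vs-rest counts for class i;
    each quadruple sums to the sample count.
    """

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        self.tp = np.atleast_1d(np.asarray(self.tp, dtype=int))
        self.tn = np.atleast_1d(np.asarray(self.tn, dtype=int))
        self.fp = np.atleast_1d(np.asarray(self.fp, dtype=int))
        self.fn = np.atleast_1d(np.asarray(self.fn, dtype=int))
        totals = self.tp + self.tn + self.fp + self.fn
        if np.any(totals != totals[0]):
            raise ValueError("per-class counts must all sum to the sample count")
        if min(self.tp.min(), self.tn.min(), self.fp.min(), self.fn.min()) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_classes(self) -> int:
        return self.tp.size


def binary_confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Counts for a -1/+1 problem; +1 is the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    cm = confusion_matrix(y_true, y_pred, labels=[1, -1])
    tp, fn, fp, tn = cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1]
    return ConfusionCounts(tp=[tp], tn=[tn], fp=[fp], fn=[fn])


def multiclass_confusion(
    y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray | None = None
) -> ConfusionCounts:
    """Per-class one-vs-rest counts from single-label predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    n = cm.sum()
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = n - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def auc_binary(cc: ConfusionCounts) -> float:
    """Two-point AUC: (sensitivity + specificity) / 2 from hard labels."""
    if cc.n_classes != 1:
        raise ValueError("auc_binary expects binary confusion counts")
    tp, tn, fp, fn = cc.tp[0], cc.tn[0], cc.fp[0], cc.fn[0]
    if tp + fn == 0 or tn + fp == 0:
        raise ZeroDivisionError("one class is empty; AUC is undefined")
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def micro_fscore(cc: ConfusionCounts, beta: float = 1.0) -> tuple[float, float, float]:
    """Micro-averaged (precision, recall, F_beta) over classes.

    For single-label multiclass predictions the total false positives equal
    the total false negatives (every error is both), so micro precision,
    micro recall and hence the micro F-score all equal overall accuracy.
    """
    tp, fp, fn = cc.tp.sum(), cc.fp.sum(), cc.fn.sum()
    if tp + fp == 0 or tp + fn == 0:
        raise ZeroDivisionError("micro precision/recall denominator is zero")
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    denom = beta**2 * precision + recall
    if denom == 0:
        raise ZeroDivisionError("F-score denominator is zero")
    fscore = (beta**2 + 1) * precision * recall / denom
    return float(precision), float(recall), float(fscore)


def average_accuracy(cc: ConfusionCounts) -> float:
    """Mean over classes of the per-class one-vs-rest binary accuracy."""
    totals = cc.tp + cc.tn + cc.fp + cc.fn
    if np.any(totals == 0):
        raise ZeroDivisionError("empty confusion table")
    return float(np.mean((cc.tp + cc.tn) / totals))
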