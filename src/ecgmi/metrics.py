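"""Classification metrics: confusion counts, accuracy/sensitivity/
specificity, ROC, and stratified splits.

Myocardial infarction ("MI") is the positive class throughout.  Rates are
computed in exact rational arithmetic and rounded half-up to two decimals
on the percentage scale for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import List, Optional, Tuple

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

POSITIVE = "MI"
NEGATIVE = "HC"


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true, y_pred, positive: str = POSITIVE) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with the given positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = set(np.unique(y_true)) | set(np.unique(y_pred))
    if len(labels) > 2:
        raise ValueError(f"binary labels expected, got {sorted(map(str, labels))}")
    t_pos = y_true == positive
    p_pos = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t_pos & p_pos)),
        tn=int(np.sum(~t_pos & ~p_pos)),
        fp=int(np.sum(~t_pos & p_pos)),
        fn=int(np.sum(t_pos & ~p_pos)),
    )


def _rate(num: int, den: int, name: str) -> float:
    if den == 0:
        raise ZeroDivisionError(f"{name} undefined: zero denominator")
    return float(Fraction(num, den))


def accuracy(c: ConfusionCounts) -> float:
    return _rate(c.tp + c.tn, c.total, "accuracy")


def sensitivity(c: ConfusionCounts) -> float:
    """True positive rate tp/(tp+fn)."""
    return _rate(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    """True negative rate tn/(tn+fp)."""
    return _rate(c.tn, c.tn + c.fp, "specificity")


def as_percent(fraction_value: float, decimals: int = 2) -> float:
    """Display rounding: half-up on the percentage scale (0.91563 -> 91.56)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(fraction_value * 100)).quantize(q, rounding=ROUND_HALF_UP))


def roc(y_true, scores, positive: str = POSITIVE) -> Tuple[np.ndarray, np.ndarray, float]:
    """ROC points (FPR, TPR) including (0,0) and (1,1), plus trapezoid AUC.

    ``scores`` are probabilities of the positive class in [0, 1].
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if np.any(scores < 0) or np.any(scores > 1):
        raise ValueError("scores must lie in [0, 1]")
    if np.unique(y_true).size < 2:
        raise ValueError("ROC needs both classes present in y_true")
    fpr, tpr, _ = _sk_roc_curve(y_true, scores, pos_label=positive)
    if fpr[0] != 0 or tpr[0] != 0:
        fpr, tpr = np.r_[0.0, fpr], np.r_[0.0, tpr]
    if fpr[-1] != 1 or tpr[-1] != 1:
        fpr, tpr = np.r_[fpr, 1.0], np.r_[tpr, 1.0]
    return fpr, tpr, float(_sk_auc(fpr, tpr))


def split(labels, mode: str, value, seed: int = 0):
    """Stratified splits.

    ``mode='kfold'``: ``value`` is k; yields k (train, test) index pairs,
    disjoint test folds covering all rows.  ``mode='learning_pct'``:
    ``value`` is the training fraction p in (0, 1); yields one pair.
    """
    labels = np.asarray(labels)
    idx = np.arange(labels.size)
    if mode == "kfold":
        k = int(value)
        if k < 2:
            raise ValueError(f"k must be >= 2, got {k}")
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < k:
            raise ValueError(f"smallest class ({counts.min()}) has fewer rows than k={k}")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in skf.split(idx, labels)]
    if mode == "learning_pct":
        p = float(value)
        if not (0 < p < 1):
            raise ValueError(f"learning fraction must lie in (0, 1), got {p}")
        tr, te = train_test_split(idx, train_size=p, stratify=labels, random_state=seed)
        return [(tr, te)]
    raise ValueError(f"unknown split mode {mode!r}")


@dataclass
class MetricsReport:
    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    roc_points: Optional[List[Tuple[float, float]]] = None
    auc: Optional[float] = None
    convergence: Optional[List[float]] = None
    split_descriptor: str = ""
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_predictions(cls, y_true, y_pred, scores=None, convergence=None,
                         split_descriptor: str = "") -> "MetricsReport":
        c = confusion_counts(y_true, y_pred)
        roc_pts, auc_val = None, None
        if scores is not None:
            fpr, tpr, auc_val = roc(y_true, scores)
            roc_pts = list(zip(fpr.tolist(), tpr.tolist()))
        return cls(
            counts=c,
            accuracy=accuracy(c),
            sensitivity=sensitivity(c),
            specificity=specificity(c),
            roc_points=roc_pts,
            auc=auc_val,
            convergence=list(convergence) if convergence is not None else None,
            split_descriptor=split_descriptor,
        )

    def to_dict(self) -> dict:
        return {
            "counts": {"tp": self.counts.tp, "tn": self.counts.tn,
                       "fp": self.counts.fp, "fn": self.counts.fn},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy_pct": as_percent(self.accuracy),
            "sensitivity_pct": as_percent(self.sensitivity),
            "specificity_pct": as_percent(self.specificity),
            "auc": self.auc,
            "roc_points": self.roc_points,
            "convergence": self.convergence,
            "split": self.split_descriptor,
            **self.extras,
        }

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
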