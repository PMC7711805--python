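"""Confusion-matrix performance measures and ROC/AUC.

The positive class is the unfavorable driving state (UDS): TP counts UDS
epochs classified UDS, TN counts NUDS classified NUDS.  The four measures,
reported as percentages, are

    SEN = TP / (TP + FN)            (sensitivity, recall on UDS)
    SPE = TN / (TN + FP)            (specificity, recall on NUDS)
    PRE = TP / (TP + FP)            (precision)
    ACC = (TP + TN) / total

A ratio with a zero denominator is undefined and reported as NaN with its
name flagged, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .profiles import NUDS, UDS

__all__ = ["ConfusionMatrix", "MetricSet", "ROCCurve", "compute_metrics", "roc_auc"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = UDS."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fn + other.fn,
            self.fp + other.fp, self.tn + other.tn,
        )

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionMatrix":
        yt = np.asarray(y_true, dtype=object)
        yp = np.asarray(y_pred, dtype=object)
        return cls(
            tp=int(((yt == UDS) & (yp == UDS)).sum()),
            fn=int(((yt == UDS) & (yp == NUDS)).sum()),
            fp=int(((yt == NUDS) & (yp == UDS)).sum()),
            tn=int(((yt == NUDS) & (yp == NUDS)).sum()),
        )


@dataclass(frozen=True)
class MetricSet:
    """ACC/SEN/SPE/PRE in percent; undefined entries are NaN and flagged."""

    acc: float
    sen: float
    spe: float
    pre: float
    undefined: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.acc, "SEN": self.sen, "SPE": self.spe, "PRE": self.pre}


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Percent metrics from a confusion matrix; zero denominators flagged."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    undefined: list[str] = []

    def ratio(name: str, num: int, den: int) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return 100.0 * num / den

    sen = ratio("SEN", cm.tp, cm.tp + cm.fn)
    spe = ratio("SPE", cm.tn, cm.tn + cm.fp)
    pre = ratio("PRE", cm.tp, cm.tp + cm.fp)
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    return MetricSet(acc=acc, sen=sen, spe=spe, pre=pre, undefined=tuple(undefined))


@dataclass
class ROCCurve:
    """ROC points (monotone from (0,0) to (1,1)) and trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve over the unique-score thresholds and its trapezoidal area.

    ``scores`` are continuous classifier outputs oriented so larger means
    more UDS-like; tied scores collapse onto one curve vertex.  Both
    classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    y = (labels == UDS).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)
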