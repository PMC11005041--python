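"""Binary-classification performance statistics.

Five statistics summarise a confusion table: precision = TP/(TP+FP),
recall (sensitivity) = TP/(TP+FN), specificity = TN/(TN+FP),
accuracy = (TP+TN)/N and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC = 1 is a perfect classification, 0 random, -1 complete disagreement.
When a factor of the MCC denominator is zero the coefficient is reported as
0 (the usual convention); a zero denominator in precision/recall/specificity
yields NaN, which ranking treats as undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    specificity: float
    accuracy: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {"precision": self.precision, "recall": self.recall,
                "specificity": self.specificity, "accuracy": self.accuracy,
                "mcc": self.mcc}


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Count TP/TN/FP/FN from two equal-length binary label sequences.

    Toxic compounds are the positive class (label 1): FP counts nontoxic
    compounds predicted toxic, FN toxic compounds predicted nontoxic.
    """
    y = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError(f"label sequences must be equal-length 1-d, "
                         f"got shapes {y.shape} and {p.shape}")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary (0/1)")
    y = y.astype(int)
    p = p.astype(int)
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Evaluate the five statistics from a confusion table."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on an empty sample")
    tp, tn, fp, fn = (float(c.tp), float(c.tn), float(c.fp), float(c.fn))
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom2) if denom2 > 0 else 0.0
    return MetricsReport(
        precision=_ratio(tp, tp + fp),
        recall=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        accuracy=(tp + tn) / c.total,
        mcc=mcc,
    )


def evaluate(true_labels, predicted_labels) -> MetricsReport:
    """Convenience: confusion counts followed by the five statistics."""
    return compute_metrics(confusion(true_labels, predicted_labels))
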