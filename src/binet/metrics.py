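"""Binary-classification evaluation.

    Accuracy    = (TP + TN) / (TP + FP + TN + FN)
    Sensitivity = TP / (TP + FN)          (recall R)
    Specificity = TN / (TN + FP)
    Precision   = TP / (TP + FP)
    F1          = 2·P·R / (P + R)

Zero denominators yield 0 with a logged warning, so a report is always total.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("at least one observation required")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    def as_row(self) -> str:
        """Human-readable row in the conventional column order."""
        return (f"Accuracy {self.accuracy:.4f}  Sensitivity {self.sensitivity:.4f}  "
                f"Specificity {self.specificity:.4f}  F1 {self.f1:.4f}")


def confusion(preds: Sequence, truth: Sequence, positive_label=1) -> ContingencyCounts:
    """Count TP/TN/FP/FN for binary label sequences."""
    preds = np.asarray(preds)
    truth = np.asarray(truth)
    if preds.shape != truth.shape or preds.ndim != 1 or preds.size < 1:
        raise ValueError("preds and truth must be equal-length 1-D sequences")
    labels = set(np.unique(preds)) | set(np.unique(truth))
    if len(labels - {positive_label}) > 1:
        raise ValueError(f"labels are not binary: {sorted(map(str, labels))}")
    p = preds == positive_label
    t = truth == positive_label
    return ContingencyCounts(
        tp=int(np.sum(p & t)), tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)), fn=int(np.sum(~p & t)))


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("zero denominator for %s; reporting 0", name)
        return 0.0
    return num / den


def report(c: ContingencyCounts) -> MetricsReport:
    """Evaluate all metrics from a contingency table."""
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    if precision + recall == 0:
        logger.warning("zero denominator for f1; reporting 0")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.total, "accuracy"),
        sensitivity=recall,
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity"),
        precision=precision,
        f1=f1)
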