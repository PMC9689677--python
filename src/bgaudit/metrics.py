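"""Confusion-matrix classification metrics, global and per class.

Accuracy = (TP+TN)/(TP+FP+TN+FN); Precision = TP/(TP+FP);
Recall = TP/(TP+FN); F1 = 2TP/(2TP+FN+FP).  Precision, recall, and F1
are reported twice, once with each class treated as positive, matching
the "F1 (Healthy)" / "F1 (Sick)" reporting convention.  A metric whose
denominator vanishes is reported as 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    degenerate: bool = False  # a zero denominator was reported as 0


@dataclass
class MetricsReport:
    accuracy: float
    healthy: ClassMetrics
    sick: ClassMetrics

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision_healthy": self.healthy.precision,
            "recall_healthy": self.healthy.recall,
            "f1_healthy": self.healthy.f1,
            "precision_sick": self.sick.precision,
            "recall_sick": self.sick.recall,
            "f1_sick": self.sick.f1,
        }


def confusion_counts(y_true, y_pred, positive: int) -> ConfusionCounts:
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(np.sum((t == positive) & (p == positive))),
        TN=int(np.sum((t != positive) & (p != positive))),
        FP=int(np.sum((t != positive) & (p == positive))),
        FN=int(np.sum((t == positive) & (p != positive))),
    )


def _class_metrics(c: ConfusionCounts) -> ClassMetrics:
    degenerate = False

    def ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    precision = ratio(c.TP, c.TP + c.FP)
    recall = ratio(c.TP, c.TP + c.FN)
    f1 = ratio(2 * c.TP, 2 * c.TP + c.FN + c.FP)
    return ClassMetrics(precision, recall, f1, degenerate)


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """Accuracy plus per-class precision/recall/F1 for labels in {0, 1}."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    if t.size == 0:
        raise ValueError("empty input")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be 0 or 1")
    accuracy = float(np.mean(t == p))
    return MetricsReport(
        accuracy=accuracy,
        healthy=_class_metrics(confusion_counts(t, p, positive=0)),
        sick=_class_metrics(confusion_counts(t, p, positive=1)),
    )
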