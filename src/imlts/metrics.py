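"""Confusion-matrix evaluation: sensitivity, specificity, precision, accuracy,
F-score and error rate, all reported in percent.

The positive class is *malignant*.  A metric whose denominator is zero is
reported as NaN (an undefined-metric marker), never an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ConfusionCounts", "confusion", "compute_metrics", "MetricReport"]

POSITIVE = "malignant"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """All six rates in percent (NaN marks an undefined rate)."""

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f_score: float
    error_rate: float

    def to_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "f_score": self.f_score,
            "error_rate": self.error_rate,
        }


def confusion(predicted, truth, positive: str = POSITIVE) -> ConfusionCounts:
    """Tally TP/TN/FP/FN for two equal-length label sequences."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError(
            f"label lists differ in length: {len(predicted)} vs {len(truth)}"
        )
    tp = tn = fp = fn = 0
    for p, t in zip(predicted, truth):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def _rate(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else math.nan


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Rates in percent.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    precision = TP/(TP+FP); accuracy = (TP+TN)/total;
    f_score = harmonic mean of precision and sensitivity;
    error_rate = 100 - accuracy.
    """
    if c.total == 0:
        raise ValueError("cannot compute rates on zero counts")
    sens = _rate(c.tp, c.tp + c.fn)
    spec = _rate(c.tn, c.tn + c.fp)
    prec = _rate(c.tp, c.tp + c.fp)
    acc = _rate(c.tp + c.tn, c.total)
    if math.isnan(prec) or math.isnan(sens) or (prec + sens) == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    err = 100.0 - acc if not math.isnan(acc) else math.nan
    return MetricReport(sens, spec, prec, acc, f1, err)
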