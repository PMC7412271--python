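"""Binary-classification performance measures and the source reduction rate.

Class +1 is the positive class throughout.  All measures are kept as exact
percentages internally and rounded to two decimals only for display.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import LabelError, ParameterError

__all__ = ["PerformanceReport", "score", "geo_mean", "reduction_rate"]


def geo_mean(sensitivity_pct: float, specificity_pct: float) -> float:
    """Geometric mean of sensitivity and specificity, both in percent."""
    return math.sqrt(sensitivity_pct * specificity_pct)


@dataclass
class PerformanceReport:
    """Confusion counts plus accuracy/sensitivity/specificity/geo-mean (%).

    ``degenerate`` flags reports where a class was absent and the undefined
    ratio was reported as 0 instead of raising, so elimination curves never
    crash on pathological subsets.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    geo_mean: float
    degenerate: bool = False

    @property
    def n_samples(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "geo_mean": self.geo_mean,
            "degenerate": self.degenerate,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def csv_row(self) -> str:
        # two-decimal display rounding
        return ",".join(
            [str(self.tp), str(self.tn), str(self.fp), str(self.fn)]
            + [f"{v:.2f}" for v in (self.accuracy, self.sensitivity,
                                    self.specificity, self.geo_mean)]
        )

    def __str__(self) -> str:
        return (
            f"accuracy={self.accuracy:.2f}% sensitivity={self.sensitivity:.2f}% "
            f"specificity={self.specificity:.2f}% geo-mean={self.geo_mean:.2f}%"
        )


def score(y_true, y_pred) -> PerformanceReport:
    """Confusion counts and the four performance measures, class +1 positive."""
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    if y_true.shape != y_pred.shape:
        raise LabelError("y_true and y_pred must have equal length")
    for v in (y_true, y_pred):
        if not set(np.unique(v)) <= {-1, 1}:
            raise LabelError("labels must lie in {-1,+1}")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == -1) & (y_pred == -1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))
    n = y_true.size
    accuracy = 100.0 * (tp + tn) / n
    degenerate = False
    if tp + fn > 0:
        sensitivity = 100.0 * tp / (tp + fn)
    else:
        sensitivity, degenerate = 0.0, True
    if tn + fp > 0:
        specificity = 100.0 * tn / (tn + fp)
    else:
        specificity, degenerate = 0.0, True
    return PerformanceReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        geo_mean=geo_mean(sensitivity, specificity), degenerate=degenerate,
    )


def reduction_rate(n_selected: int, n_total: int) -> float:
    """1 - n_selected/n_total: fraction of sources discarded."""
    if n_total < 1 or not 0 <= n_selected <= n_total:
        raise ParameterError(
            f"need 0 <= n_selected <= n_total >= 1, got {n_selected}/{n_total}"
        )
    return 1.0 - n_selected / n_total
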