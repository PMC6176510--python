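"""Confusion-matrix metrics and ROC/AUC for seizure (positive) vs non-seizure
(negative) window predictions.

A metric whose denominator is zero is reported as ``None`` — an explicit
undefined marker, never a silent 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.stats import rankdata

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "metrics", "roc_auc"]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    sensitivity: Union[float, None]
    specificity: Union[float, None]
    accuracy: Union[float, None]
    precision: Union[float, None]
    g_mean: Union[float, None]
    f_measure: Union[float, None]
    beta: float = 1.0
    auc: Union[float, None] = None

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "g_mean": self.g_mean,
            "f_measure": self.f_measure,
            "beta": self.beta,
            "auc": self.auc,
        }


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """2x2 tally; label/prediction 1 = seizure (positive), 0 = non-seizure."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: int, den: int) -> Union[float, None]:
    return num / den if den > 0 else None


def metrics(counts: ConfusionCounts, beta: float = 1.0) -> MetricsReport:
    """The six confusion-derived scores (AUC left unset).

    G-mean is the square root of sensitivity x specificity; the F-measure is
    the standard beta-squared-weighted harmonic combination of precision and
    sensitivity (beta = 1 gives F1).
    """
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    acc = _ratio(counts.tp + counts.tn, counts.total)
    prec = _ratio(counts.tp, counts.tp + counts.fp)
    g_mean = math.sqrt(sens * spec) if sens is not None and spec is not None else None
    f_measure = None
    if prec is not None and sens is not None:
        den = beta * beta * prec + sens
        f_measure = (1 + beta * beta) * prec * sens / den if den > 0 else None
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        precision=prec,
        g_mean=g_mean,
        f_measure=f_measure,
        beta=beta,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic with
    midrank tie handling; constant scores give exactly 0.5."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    return float(
        (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )
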