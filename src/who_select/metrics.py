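"""Binary diagnostic metrics and repeated-run fitness statistics.

Conventions: class 1 is the positive (disease) class.  A metric whose
denominator is zero is reported as ``None`` (an explicit undefined marker)
rather than 0 or an exception.

Two deliberate, documented quirks of the metric suite:

* ``fscore`` is the harmonic mean of specificity and sensitivity (not the
  conventional precision/recall F1).
* ``compute_metrics(..., strict_literal=True)`` switches the accuracy
  denominator to ``FP + TP + TP + FN`` for auditing; the default uses the
  standard ``TP + TN + FP + FN``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RunStats",
    "confusion",
    "compute_metrics",
    "run_statistics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    acc: Optional[float]
    sns: Optional[float]
    spc: Optional[float]
    fscore: Optional[float]
    dice: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "sns": self.sns,
            "spc": self.spc,
            "fscore": self.fscore,
            "dice": self.dice,
            "ppv": self.ppv,
            "npv": self.npv,
        }


@dataclass(frozen=True)
class RunStats:
    fit_avg: float
    std: Optional[float]
    fit_best: float
    fit_worst: float
    best_acc: Optional[float]
    m: int
    values: tuple

    def to_dict(self) -> dict:
        return {
            "fit_avg": self.fit_avg,
            "std": self.std,
            "fit_best": self.fit_best,
            "fit_worst": self.fit_worst,
            "best_acc": self.best_acc,
            "m": self.m,
            "values": list(self.values),
        }


def confusion(predicted: Sequence[int], actual: Sequence[int]) -> ConfusionCounts:
    """Tally the 2x2 confusion table; class 1 is positive."""
    pred = np.asarray(predicted)
    act = np.asarray(actual)
    if pred.shape != act.shape or pred.ndim != 1:
        raise ValueError("predicted and actual must be 1-D vectors of equal length")
    if pred.size < 1:
        raise ValueError("empty prediction vector")
    pred = pred.astype(int)
    act = act.astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (act == 1))),
        tn=int(np.sum((pred == 0) & (act == 0))),
        fp=int(np.sum((pred == 1) & (act == 0))),
        fn=int(np.sum((pred == 0) & (act == 1))),
    )


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def compute_metrics(c: ConfusionCounts, strict_literal: bool = False) -> MetricsReport:
    """Derive the seven diagnostic metrics from confusion counts.

    ``strict_literal`` reproduces the idiosyncratic printed accuracy
    denominator (FP + 2*TP + FN) instead of the standard total count.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    if strict_literal:
        acc = _ratio(tp + tn, fp + tp + tp + fn)
    else:
        acc = _ratio(tp + tn, tp + tn + fp + fn)
    sns = _ratio(tp, tp + fn)
    spc = _ratio(tn, fp + tn)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    dice = _ratio(2 * tp, fp + tp + tp + fn)
    if sns is None or spc is None:
        fscore = None
    else:
        fscore = _ratio(2 * spc * sns, spc + sns)
    return MetricsReport(acc=acc, sns=sns, spc=spc, fscore=fscore,
                         dice=dice, ppv=ppv, npv=npv)


def run_statistics(
    values: Sequence[float],
    acc_values: Optional[Sequence[float]] = None,
) -> RunStats:
    """Aggregate per-run fitness values: min / max / mean and sample
    standard deviation (the m-1 denominator).

    With a single value the std is reported as ``None`` (a reduced result);
    an empty sequence is a contract error.
    """
    vals = [float(v) for v in values]
    m = len(vals)
    if m < 1:
        raise ValueError("run_statistics requires at least one value")
    fit_avg = sum(vals) / m
    if m >= 2:
        std = math.sqrt(sum((v - fit_avg) ** 2 for v in vals) / (m - 1))
    else:
        std = None
    best_acc = None
    if acc_values is not None:
        accs = [float(a) for a in acc_values]
        if accs:
            best_acc = max(accs)
    return RunStats(
        fit_avg=fit_avg,
        std=std,
        fit_best=min(vals),
        fit_worst=max(vals),
        best_acc=best_acc,
        m=m,
        values=tuple(vals),
    )
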