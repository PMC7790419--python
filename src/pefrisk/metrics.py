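"""Confusion-matrix metrics and cohort-level aggregation.

The positive class is the red zone (label 0): a true positive is a red-zone
day predicted red. Derived metrics:

* sensitivity (recall on red days)      = TP / (TP + FN)
* specificity (recall on safe days)     = TN / (TN + FP)
* precision                             = TP / (TP + FP)
* balanced accuracy                     = (sensitivity + specificity) / 2
* F1                                    = harmonic mean of sensitivity and
                                          precision

A zero denominator leaves the metric *undefined* (NaN), never silently 0;
aggregation across folds or patients drops undefined values and reports how
many were dropped. Cohort summaries are medians with interquartile ranges,
computed with the same linear-interpolation quantile convention as the
zoning cutoffs. Paired with/without-IS runs are compared as per-patient
after/before ratios, summarized the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "METRIC_NAMES",
    "EvalResult",
    "confusion",
    "aggregate_folds",
    "MetricSummary",
    "summarize",
    "summarize_ratio",
]

METRIC_NAMES = ("balanced_accuracy", "sensitivity", "precision", "f1")


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts for one evaluation, red zone (0) positive."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> float:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    @property
    def f1(self) -> float:
        s, p = self.sensitivity, self.precision
        if np.isnan(s) or np.isnan(p):
            return float("nan")
        if s + p == 0:
            return 0.0
        return 2.0 * s * p / (s + p)

    def as_dict(self) -> dict[str, float]:
        d = {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}
        for m in METRIC_NAMES:
            d[m] = getattr(self, m)
        return d


def confusion(labels, predictions) -> EvalResult:
    """Count the confusion matrix with red zone (label 0) as positive."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise DataError("labels and predictions must have equal length")
    if not np.all(np.isin(y, (0, 1))) or not np.all(np.isin(p, (0, 1))):
        raise DataError("labels and predictions must be 0 (red) or 1 (safe)")
    return EvalResult(
        tp=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 0) & (p == 1))),
        fp=int(np.sum((y == 1) & (p == 0))),
        tn=int(np.sum((y == 1) & (p == 1))),
    )


def aggregate_folds(results: Sequence[EvalResult]) -> dict[str, float]:
    """Mean of each metric over folds, skipping undefined (NaN) values."""
    out: dict[str, float] = {"n_folds": float(len(results))}
    for m in METRIC_NAMES:
        vals = np.array([getattr(r, m) for r in results], dtype=float)
        defined = vals[~np.isnan(vals)]
        out[m] = float(np.mean(defined)) if defined.size else float("nan")
        out[f"{m}_n_undefined"] = float(np.isnan(vals).sum())
    return out


@dataclass(frozen=True)
class MetricSummary:
    """Median and quartiles of one metric across patients."""

    median: float
    p25: float
    p75: float
    n_defined: int
    n_undefined: int


def _summary(values: np.ndarray) -> MetricSummary:
    values = np.asarray(values, dtype=float)
    defined = values[~np.isnan(values)]
    if defined.size == 0:
        nan = float("nan")
        return MetricSummary(nan, nan, nan, 0, int(values.size))
    p25, med, p75 = np.quantile(defined, [0.25, 0.5, 0.75], method="linear")
    return MetricSummary(
        median=float(med),
        p25=float(p25),
        p75=float(p75),
        n_defined=int(defined.size),
        n_undefined=int(values.size - defined.size),
    )


def summarize(per_patient: Mapping[str, Sequence[float]] | pd.DataFrame) -> dict[str, MetricSummary]:
    """Cohort summary: per metric, the median/IQR across patients."""
    if isinstance(per_patient, pd.DataFrame):
        per_patient = {c: per_patient[c].to_numpy() for c in per_patient.columns}
    if not per_patient:
        raise DataError("nothing to summarize")
    return {name: _summary(np.asarray(vals)) for name, vals in per_patient.items()}


def summarize_ratio(after: Sequence[float], before: Sequence[float]) -> MetricSummary:
    """Median/IQR of per-patient after/before ratios (paired runs).

    Pairs where either side is undefined or the denominator is zero are
    dropped and counted as undefined.
    """
    a = np.asarray(after, dtype=float)
    b = np.asarray(before, dtype=float)
    if a.shape != b.shape:
        raise DataError("paired summaries need equal-length sequences")
    ratios = np.full(a.shape, np.nan)
    ok = ~np.isnan(a) & ~np.isnan(b) & (b > 0)
    ratios[ok] = a[ok] / b[ok]
    return _summary(ratios)
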