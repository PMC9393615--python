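"""Confusion-matrix accounting with RT (resistant-treated) as positive.

A misidentified sensitive plant (ST called RT) is the costly error in
resistance screening, so the false positive rate is reported alongside
accuracy/precision/recall/F1.  Metrics with zero denominators are
*undefined* and propagate as NaN — never coerced to 0 — and aggregations
skip them while counting the exclusions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

POSITIVE = "RT"
NEGATIVE = "ST"

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "fpr")


@dataclass(frozen=True)
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


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float
    fpr: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(
    y_true, y_pred, positive: str = POSITIVE, negative: str = NEGATIVE
) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    allowed = {positive, negative}
    foreign = (set(np.unique(y_true)) | set(np.unique(y_pred))) - allowed
    if foreign:
        raise ValueError(f"labels outside {allowed}: {sorted(foreign)}")
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred == negative)))
    fp = int(np.sum((y_true == negative) & (y_pred == positive)))
    tn = int(np.sum((y_true == negative) & (y_pred == negative)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean; undefined when either input is undefined or both 0."""
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        return math.nan
    return 2 * precision * recall / (precision + recall)


def metrics(counts: ConfusionCounts) -> MetricSet:
    if counts.total == 0:
        raise ValueError("no samples")
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    recall = _ratio(counts.tp, counts.tp + counts.fn)
    return MetricSet(
        accuracy=(counts.tp + counts.tn) / counts.total,
        precision=precision,
        recall=recall,
        f1=f1_from_precision_recall(precision, recall),
        fpr=_ratio(counts.fp, counts.fp + counts.tn),
    )


def evaluate(y_true, y_pred, positive: str = POSITIVE, negative: str = NEGATIVE) -> MetricSet:
    return metrics(confusion(y_true, y_pred, positive, negative))


def summarize(results: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Mean of each metric per group, skipping undefined values explicitly.

    Adds ``<metric>_n_excluded`` columns counting the NaN rows dropped from
    each mean; a metric undefined in every row stays NaN.
    """
    if results.empty:
        raise ValueError("empty results table")
    present = [m for m in METRIC_NAMES if m in results.columns]
    out = results.groupby(by, sort=True)[present].mean().reset_index()
    excl = (
        results.groupby(by, sort=True)[present]
        .agg(lambda s: int(s.isna().sum()))
        .reset_index()
        .rename(columns={m: f"{m}_n_excluded" for m in present})
    )
    return out.merge(excl, on=by)


def round_for_report(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Display rounding (2 dp, NaN rendered as the literal "NaN")."""
    out = table.copy()
    for m in METRIC_NAMES:
        if m in out.columns:
            out[m] = out[m].round(decimals).astype(object)
            out.loc[out[m].isna(), m] = "NaN"
    return out
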