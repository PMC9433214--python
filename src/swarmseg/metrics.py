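"""Nine-score evaluation suite for binary segmentation masks.

Confusion-count scores (precision, recall, F-measure, accuracy%, error%)
and similarity scores (Matthews correlation coefficient, Dice, Jaccard)
computed per (prediction, truth) pair with foreground as the positive
class, plus wall-time capture and aggregation into method-by-set-size
comparison tables.

Conventions: any 0/0 score is reported as 0 (and logged) so aggregation
stays total; a zero MCC denominator likewise yields 0.  These are the
standard degenerate-table conventions and keep every report finite.
Identities that hold by construction: dice = 2 J / (1 + J) and
accuracy% + error% = 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "score", "aggregate"]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "precision",
    "recall",
    "f_measure",
    "accuracy_pct",
    "error_pct",
    "mcc",
    "dice",
    "jaccard",
    "elapsed_seconds",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    precision: float
    recall: float
    f_measure: float
    accuracy_pct: float
    error_pct: float
    mcc: float
    dice: float
    jaccard: float
    elapsed_seconds: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in METRIC_COLUMNS}


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts with foreground (True) as positive."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs truth {truth.shape}"
        )
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.debug("%s is 0/0; reporting 0 by convention", name)
        return 0.0
    return num / den


def score(counts: ConfusionCounts, elapsed_seconds: float = float("nan")) -> MetricReport:
    """All nine scores from one confusion table."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    total = counts.total
    if total <= 0:
        raise ValueError("confusion table is empty")

    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    f_measure = _ratio(2 * precision * recall, precision + recall, "f_measure")
    accuracy_pct = 100.0 * (tp + tn) / total
    error_pct = 100.0 - accuracy_pct
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _ratio(float(tp) * tn - float(fp) * fn, mcc_den, "mcc")
    dice = _ratio(2.0 * tp, 2.0 * tp + fp + fn, "dice")
    jaccard = _ratio(float(tp), float(tp + fp + fn), "jaccard")
    return MetricReport(
        precision=precision,
        recall=recall,
        f_measure=f_measure,
        accuracy_pct=accuracy_pct,
        error_pct=error_pct,
        mcc=mcc,
        dice=dice,
        jaccard=jaccard,
        elapsed_seconds=elapsed_seconds,
    )


def aggregate(
    reports: pd.DataFrame, group_keys: list[str] | tuple[str, ...] = ("method",)
) -> pd.DataFrame:
    """Per-group arithmetic means of every metric column.

    ``reports`` is a long-format frame with one row per scored image and
    at least the columns in ``METRIC_COLUMNS`` plus the grouping keys
    (typically ``method`` and ``set_size``), as produced by the benchmark
    runner.
    """
    if len(reports) == 0:
        raise ValueError("no reports to aggregate")
    cols = [c for c in METRIC_COLUMNS if c in reports.columns]
    return reports.groupby(list(group_keys), sort=True)[cols].mean().reset_index()


def pivot_table(summary: pd.DataFrame, value: str = "dice") -> pd.DataFrame:
    """Wide comparison table: methods as columns, set sizes as rows."""
    if "set_size" not in summary.columns:
        return summary.set_index("method")[[value]].T
    return summary.pivot(index="set_size", columns="method", values=value)
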