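"""Binary classification metrics and one-vs-one report tables.

Six measures are reported per class pair: sensitivity TP/(TP+FN),
specificity TN/(FP+TN), precision TP/(TP+FP), accuracy
(TP+TN)/(TP+TN+FP+FN), F-measure 2TP/(2TP+FP+FN), and the area under the
ROC curve.  Metrics with a zero denominator are reported as 0 and
flagged, never silently dropped, so table averages stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .thermogram import ValidationError

__all__ = ["ConfusionCounts", "MetricsRow", "metrics_from_counts", "roc_auc",
           "pair_table", "METRIC_COLUMNS"]

METRIC_COLUMNS = ["sensitivity", "specificity", "precision", "accuracy", "f_measure", "auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsRow:
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f_measure: float
    auc: float = float("nan")
    #: names of metrics whose denominator was zero (reported as 0)
    undefined: List[str] = field(default_factory=list)

    def as_dict(self) -> Dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_COLUMNS}


def _ratio(num: int, den: int, name: str, undefined: List[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts, auc: float = float("nan")) -> MetricsRow:
    """The five count-based measures from a confusion matrix.

    AUC needs scores rather than counts; pass it through ``auc`` when
    available (see :func:`roc_auc`).
    """
    if c.total == 0:
        raise ValidationError("all confusion counts are zero")
    und: List[str] = []
    return MetricsRow(
        sensitivity=_ratio(c.tp, c.tp + c.fn, "sensitivity", und),
        specificity=_ratio(c.tn, c.fp + c.tn, "specificity", und),
        precision=_ratio(c.tp, c.tp + c.fp, "precision", und),
        accuracy=(c.tp + c.tn) / c.total,
        f_measure=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f_measure", und),
        auc=auc,
        undefined=und,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> Tuple[float, np.ndarray]:
    """Trapezoidal area under the ROC curve, plus the curve itself.

    Thresholds are taken at every distinct score (ties share one
    threshold, which makes the trapezoid equal to the tied-rank
    Mann-Whitney statistic).  Returns ``(auc, points)`` where ``points``
    is an (m, 2) array of (FPR, TPR) pairs from (0,0) to (1,1).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels differ in length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes present")

    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def pair_table(rows: Dict[Tuple[int, int], MetricsRow]) -> pd.DataFrame:
    """Per-pair metric table with a final Average row of column means."""
    if not rows:
        raise ValidationError("no per-pair rows")
    records = {}
    for (a, b), row in rows.items():
        records[f"{a}-{b}"] = row.as_dict()
    df = pd.DataFrame.from_dict(records, orient="index", columns=METRIC_COLUMNS)
    df.loc["Average"] = df.mean(axis=0)
    return df
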