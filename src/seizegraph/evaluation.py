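"""Classification metrics for imbalanced seizure detection.

Accuracy, sensitivity (recall on seizures) and specificity come from the
confusion counts at a decision threshold; AUC is computed as the
Mann-Whitney rank statistic (midranks for ties), the probability that a
randomly chosen ictal clip scores above a randomly chosen interictal one —
equal to the trapezoidal area under the ROC curve.  Metrics with a zero
denominator are reported as ``None`` rather than 0, and AUC on a
single-class label set raises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "metrics", "auc",
           "youden_threshold", "evaluate", "report_to_csv"]


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
class MetricReport:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    auc: float | None
    threshold: float


def _check(labels, probabilities) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != p.shape:
        raise ValueError("labels and probabilities differ in length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return y.astype(int), p


def confusion(labels, probabilities, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts with predictions ``p >= threshold``."""
    y, p = _check(labels, probabilities)
    pred = p >= threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & (y == 1))),
        TN=int(np.sum(~pred & (y == 0))),
        FP=int(np.sum(pred & (y == 0))),
        FN=int(np.sum(~pred & (y == 1))),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(counts: ConfusionCounts, threshold: float = 0.5,
            auc_value: float | None = None) -> MetricReport:
    """ACC = (TP+TN)/total, SEN = TP/(TP+FN), SPE = TN/(TN+FP)."""
    if counts.total == 0:
        raise ValueError("no observations")
    return MetricReport(
        accuracy=_ratio(counts.TP + counts.TN, counts.total),
        sensitivity=_ratio(counts.TP, counts.TP + counts.FN),
        specificity=_ratio(counts.TN, counts.TN + counts.FP),
        auc=auc_value,
        threshold=threshold,
    )


def auc(labels, scores) -> float:
    """Area under the ROC curve via the midrank Mann-Whitney statistic."""
    y, s = _check(labels, scores)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: labels contain a single class")
    ranks = rankdata(s, method="average")
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def youden_threshold(labels, scores) -> float:
    """Threshold maximizing sensitivity + specificity - 1."""
    y, s = _check(labels, scores)
    best_t, best_j = 0.5, -np.inf
    for t in np.unique(s):
        c = confusion(y, s, t)
        sen = _ratio(c.TP, c.TP + c.FN) or 0.0
        spe = _ratio(c.TN, c.TN + c.FP) or 0.0
        if sen + spe - 1.0 > best_j:
            best_j, best_t = sen + spe - 1.0, float(t)
    return best_t


def evaluate(labels, probabilities, threshold: float = 0.5) -> MetricReport:
    """Full report at one threshold (AUC is threshold-free)."""
    y, p = _check(labels, probabilities)
    try:
        a = auc(y, p)
    except ValueError:
        a = None
    return metrics(confusion(y, p, threshold), threshold, a)


def report_to_csv(rows: list[dict], path) -> None:
    """Table-style report grid: one row per (method, clip length)."""
    import pandas as pd
    cols = ["Method", "Length(s)", "Accuracy", "Sensitivity",
            "Specificity", "AUC"]
    pd.DataFrame(rows)[cols].to_csv(path, index=False)
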