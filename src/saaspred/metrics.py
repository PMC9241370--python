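"""Binary-classification metrics: SEN, SPE, PRE, ACC, MCC and AUC.

All formulas are implemented directly from their confusion-count
definitions; any ratio with a zero denominator is defined as 0 (with a
warning).  AUC is the rank-based (Mann–Whitney) statistic — the probability
that a random positive outscores a random negative, ties counting 1/2 —
which equals trapezoidal integration of the empirical ROC curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy.stats import rankdata

from .records import SaasError

METRIC_ORDER = ("MCC", "ACC", "SEN", "SPE", "PRE", "AUC")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise SaasError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: Sequence[int],
                         y_pred: Sequence[int]) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        if yt.shape != yp.shape:
            raise SaasError("prediction/label length mismatch")
        return cls(tp=int(np.sum((yt == 1) & (yp == 1))),
                   tn=int(np.sum((yt == 0) & (yp == 0))),
                   fp=int(np.sum((yt == 0) & (yp == 1))),
                   fn=int(np.sum((yt == 1) & (yp == 0))))


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, defining the metric as 0")
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> Dict[str, float]:
    """SEN, SPE, PRE, ACC and MCC from confusion counts."""
    if counts.total == 0:
        raise SaasError("no evaluated records")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    mcc_den = math.sqrt(float(tp + fn) * (tp + fp) * (tn + fn) * (tn + fp))
    return {
        "SEN": _ratio(tp, tp + fn, "SEN"),
        "SPE": _ratio(tn, tn + fp, "SPE"),
        "PRE": _ratio(tp, tp + fp, "PRE"),
        "ACC": _ratio(tp + tn, counts.total, "ACC"),
        "MCC": _ratio(tp * tn - fp * fn, mcc_den, "MCC"),
    }


def mcc(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    return compute_metrics(ConfusionCounts.from_predictions(y_true, y_pred))["MCC"]


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC with ties counted 1/2.

    Requires both classes present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise SaasError("scores/labels length mismatch")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise SaasError("AUC undefined with a single class")
    ranks = rankdata(s)  # average ranks handle ties
    rank_sum_pos = float(np.sum(ranks[y == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def full_report(y_true: Sequence[int], scores: Sequence[float],
                threshold: float = 0.5) -> Dict[str, float]:
    """All six metrics from probability scores; class = positive iff the
    score is >= ``threshold`` (default 0.5)."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    preds = (s >= threshold).astype(int)
    report = compute_metrics(ConfusionCounts.from_predictions(y, preds))
    report["AUC"] = roc_auc(s, y)
    return {k: report[k] for k in METRIC_ORDER}
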