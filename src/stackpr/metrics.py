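"""Binary-classification metrics for antagonist/inactive calls.

All threshold metrics are computed from the confusion matrix in exact
rational arithmetic and only converted to float at the end, so that the
three-decimal values quoted in reports are free of intermediate rounding.
ROC AUC uses the rank (Mann-Whitney) statistic with ties counted 1/2,
which is equivalent to trapezoidal integration of the ROC curve.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "accuracy",
    "sensitivity",
    "specificity",
    "mcc",
    "f_value",
    "roc_auc",
    "compare_models",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given input (e.g. one class)."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of true/false positives and negatives.

    Positives are the actives (antagonists), negatives the inactives.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        yt = np.asarray(y_true).astype(int)
        yp = np.asarray(y_pred).astype(int)
        if yt.shape != yp.shape:
            raise ValueError("y_true and y_pred must have the same length")
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
            tn=int(np.sum((yt == 0) & (yp == 0))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
        )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} denominator is zero; returning 0", RuntimeWarning)
        return 0.0
    return float(Fraction(num, den))


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    return _ratio(cm.tp + cm.tn, cm.total, "accuracy")


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN) — recall on the actives."""
    return _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (TN + FP) — recall on the inactives."""
    return _ratio(cm.tn, cm.tn + cm.fp, "specificity")


def f_value(cm: ConfusionMatrix) -> float:
    """2·TP / (2·TP + FP + FN) — the F1 measure."""
    return _ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f_value")


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient.

    (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with the
    conventional value 0 when any factor of the denominator is zero
    (no information).
    """
    num = cm.tp * cm.tn - cm.fp * cm.fn
    den = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if den == 0:
        return 0.0
    return num / math.sqrt(den)


def roc_auc(scores, y_true) -> float:
    """Probability that a random active outranks a random inactive.

    Ties contribute 1/2; computed from the rank-sum statistic.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(y_true).astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC AUC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2 pair-wins
    rank_sum_pos = float(ranks[y == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


@dataclass(frozen=True)
class MetricsReport:
    """The five threshold metrics plus ROC AUC for one model/dataset pair."""

    acc: float
    sn: float
    sp: float
    mcc: float
    f_value: float
    auc: float | None
    cm: ConfusionMatrix

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix, auc: float | None = None) -> "MetricsReport":
        return cls(
            acc=accuracy(cm),
            sn=sensitivity(cm),
            sp=specificity(cm),
            mcc=mcc(cm),
            f_value=f_value(cm),
            auc=auc,
            cm=cm,
        )

    @classmethod
    def from_scores(cls, y_true, scores, threshold: float = 0.5) -> "MetricsReport":
        """Threshold scores at `threshold` (ties -> active) and score AUC."""
        s = np.asarray(scores, dtype=float)
        y_pred = (s >= threshold).astype(int)
        cm = ConfusionMatrix.from_predictions(y_true, y_pred)
        try:
            auc = roc_auc(s, y_true)
        except UndefinedMetricError:
            auc = None
        return cls.from_confusion(cm, auc=auc)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cm"] = asdict(self.cm)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def compare_models(reports: dict[str, MetricsReport], reference: str | None = None) -> pd.DataFrame:
    """Tabulate named reports sorted by MCC (descending).

    Adds percentage differences of each metric against `reference`
    (default: the top-MCC model), mirroring the usual head-to-head
    comparison tables.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    rows = {
        name: {
            "ACC": r.acc,
            "Sn": r.sn,
            "Sp": r.sp,
            "MCC": r.mcc,
            "AUC": np.nan if r.auc is None else r.auc,
            "F-value": r.f_value,
        }
        for name, r in reports.items()
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.sort_values("MCC", ascending=False, kind="mergesort")
    ref = reference if reference is not None else table.index[0]
    if ref not in table.index:
        raise KeyError(f"reference model {ref!r} not among reports")
    for col in ("ACC", "Sn", "Sp", "MCC", "AUC", "F-value"):
        base = table.loc[ref, col]
        with np.errstate(divide="ignore", invalid="ignore"):
            table[f"d{col}%"] = 100.0 * (table[col] - base) / abs(base)
    return table
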