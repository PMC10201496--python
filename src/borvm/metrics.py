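"""Confusion-matrix metrics, ROC AUC, and descriptive cohort statistics.

The positive class throughout is "died". Metrics with a zero denominator
are reported as None (undefined), never silently as 0. Chi-square tests of
independence use the uncorrected Pearson statistic, the convention that
reproduces the published contingency-table statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "classification_metrics",
    "roc_auc",
    "chi_square_independence",
    "spearman_rho",
    "chi_square_battery",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int
    positive_label: object = 1

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "positive_label": self.positive_label,
        }


@dataclass(frozen=True)
class MetricsReport:
    """Derived proportions; any metric with a 0/0 denominator is None."""

    accuracy: float | None
    ppv: float | None
    npv: float | None
    tpr: float | None
    tnr: float | None
    f1: float | None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {k: (None if v is None else float(v)) for k, v in self.__dict__.items()}


def confusion_matrix(y_true, y_pred, positive_label=1) -> ConfusionMatrix:
    """2x2 tally of predictions against truth with the stated positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    if labels.size > 2:
        raise ValueError(f"more than two labels present: {labels.tolist()}")
    if positive_label not in labels and labels.size == 2:
        raise ValueError(f"positive_label {positive_label!r} not among labels {labels.tolist()}")
    tpos = y_true == positive_label
    ppos = y_pred == positive_label
    return ConfusionMatrix(
        tp=int((tpos & ppos).sum()),
        fp=int((~tpos & ppos).sum()),
        fn=int((tpos & ~ppos).sum()),
        tn=int((~tpos & ~ppos).sum()),
        positive_label=positive_label,
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, PPV, NPV, TPR, TNR and F1 from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    tpr = _ratio(cm.tp, cm.tp + cm.fn)
    if ppv is not None and tpr is not None and ppv + tpr > 0:
        f1 = 2 * ppv * tpr / (ppv + tpr)
    else:
        f1 = None
    return MetricsReport(
        accuracy=(cm.tp + cm.tn) / cm.total,
        ppv=ppv,
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        tpr=tpr,
        tnr=_ratio(cm.tn, cm.tn + cm.fp),
        f1=f1,
    )


def roc_auc(y_true, scores, positive_label=1) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted half."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    pos = y_true == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)  # average ranks: ties get half weight
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def chi_square_independence(count_table) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square test on an r x c count table.

    Returns (statistic, degrees of freedom, upper-tail p-value).
    """
    table = np.asarray(count_table, dtype=float)
    if table.ndim != 2:
        raise ValueError("count table must be 2-D")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row or column sum")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero rank variance")
    return float(stats.spearmanr(x, y).statistic)


def chi_square_battery(cohort: pd.DataFrame) -> dict[str, dict]:
    """Chi-square tests of every predictor against outcome and poison type.

    Mirrors the published descriptive analysis: each of the five predictors
    (and poison type itself) crossed with the outcome, and each predictor
    crossed with the poison type. Returns {test name: {statistic, dof,
    p_value}}.
    """
    out = {}
    predictors = ["age_group", "sex", "cholinesterase", "silver_nitrate", "mode"]
    for name in predictors + ["poison_type"]:
        table = pd.crosstab(cohort[name], cohort["outcome"])
        stat, dof, p = chi_square_independence(table.to_numpy())
        out[f"{name}_x_outcome"] = {"statistic": stat, "dof": dof, "p_value": p}
    for name in predictors:
        table = pd.crosstab(cohort[name], cohort["poison_type"])
        stat, dof, p = chi_square_independence(table.to_numpy())
        out[f"{name}_x_poison"] = {"statistic": stat, "dof": dof, "p_value": p}
    return out
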