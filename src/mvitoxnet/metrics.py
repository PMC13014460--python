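"""Evaluation metrics for imbalanced binary toxicity classification.

Implements balanced accuracy, AUROC, AUPRC, recall, F1 and the Matthews
correlation coefficient directly from their definitions (sklearn serves only
as an independent cross-check in the test suite):

* AUROC is computed in its rank (Mann-Whitney) form — the probability that a
  random positive outscores a random negative, ties counting one half — which
  equals trapezoidal integration of the ROC curve.
* AUPRC uses the average-precision step convention: sum of precision at each
  distinct threshold times the recall increment. Trapezoidal interpolation of
  the PR curve is deliberately avoided (it overestimates).

Zero-denominator conventions (stated so tests can be exact): MCC -> 0 when
any factor of the denominator is zero; a BACC class term with no members
contributes 0 with a warning; AUROC/AUPRC on single-class labels are NaN
with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion",
    "bacc",
    "recall",
    "f1",
    "mcc",
    "auroc",
    "auprc",
    "evaluate_all",
    "mean_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvaluationReport:
    """The six headline metrics plus the confusion counts behind them."""

    bacc: float
    auroc: float
    auprc: float
    recall: float
    f1: float
    mcc: float
    confusion: ConfusionCounts | None = None
    threshold: float = 0.5

    METRICS = ("bacc", "auroc", "auprc", "recall", "f1", "mcc")

    def to_dict(self) -> dict:
        d = {m: getattr(self, m) for m in self.METRICS}
        d["threshold"] = self.threshold
        if self.confusion is not None:
            d["confusion"] = asdict(self.confusion)
        return d

    def format_percent(self) -> dict[str, str]:
        """Metrics as percentages to two decimals (reporting style)."""
        return {m: f"{100.0 * getattr(self, m):.2f}" for m in self.METRICS}


def _validate(labels, probabilities) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels, dtype=np.int64)
    p = np.asarray(probabilities, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError(f"labels and probabilities differ in shape: {y.shape} vs {p.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    return y, p


def confusion(labels, probabilities, threshold: float = 0.5) -> ConfusionCounts:
    """Tally TP/TN/FP/FN; a probability exactly at the threshold is positive."""
    y, p = _validate(labels, probabilities)
    pred = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (empty class); contributing 0", UserWarning, stacklevel=3)
        return 0.0
    return num / den


def bacc(c: ConfusionCounts) -> float:
    """Balanced accuracy: mean of sensitivity and specificity."""
    sens = _safe_ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = _safe_ratio(c.tn, c.tn + c.fp, "specificity")
    return 0.5 * (sens + spec)


def recall(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp, c.tp + c.fn, "recall")


def f1(c: ConfusionCounts) -> float:
    den = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / den if den else 0.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, tn, fp, fn = (float(v) for v in (c.tp, c.tn, c.fp, c.fn))
    den_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den_sq == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(den_sq)


def auroc(labels, probabilities) -> float:
    """Rank-form AUROC; ties count one half. NaN + warning on one class."""
    y, p = _validate(labels, probabilities)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUROC undefined for single-class labels", UserWarning, stacklevel=2)
        return float("nan")
    ranks = rankdata(p)  # average rank for ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(labels, probabilities) -> float:
    """Average precision over the PR step curve. NaN + warning with no positives."""
    y, p = _validate(labels, probabilities)
    n_pos = int(y.sum())
    if n_pos == 0:
        warnings.warn("AUPRC undefined without positives", UserWarning, stacklevel=2)
        return float("nan")
    order = np.argsort(-p, kind="stable")
    y_sorted = y[order]
    p_sorted = p[order]
    tp_cum = np.cumsum(y_sorted)
    n_seen = np.arange(1, y.size + 1)
    # evaluate only at the last index of each distinct score (threshold group)
    boundary = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    tp_b = tp_cum[boundary]
    precision = tp_b / n_seen[boundary]
    rec = tp_b / n_pos
    drec = np.diff(np.r_[0.0, rec])
    return float(np.sum(precision * drec))


def evaluate_all(labels, probabilities, threshold: float = 0.5) -> EvaluationReport:
    """All six metrics from one pass over (labels, probabilities)."""
    c = confusion(labels, probabilities, threshold)
    return EvaluationReport(
        bacc=bacc(c),
        auroc=auroc(labels, probabilities),
        auprc=auprc(labels, probabilities),
        recall=recall(c),
        f1=f1(c),
        mcc=mcc(c),
        confusion=c,
        threshold=threshold,
    )


def mean_report(reports: list[EvaluationReport]) -> EvaluationReport:
    """Arithmetic mean per metric across runs (confusion counts dropped)."""
    if not reports:
        raise ValueError("no reports to average")
    return EvaluationReport(
        **{m: float(np.mean([getattr(r, m) for r in reports])) for m in EvaluationReport.METRICS},
        threshold=reports[0].threshold,
    )
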