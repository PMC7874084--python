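"""Multilabel evaluation metrics and the support-vs-performance regression.

Metrics are computed from pooled or per-class confusion counts over the
OTU x class cells of a multihot prediction/truth pair:

* micro-F1 pools TP/FP/FN over all classes before the harmonic mean;
* macro-F1 averages per-class precision and per-class recall first and
  takes the harmonic mean of the two averages (the printed-formula
  variant); the more common mean of per-class F1 scores is available as
  ``macro_f1(..., variant="mean-of-f1")`` and in the per-class table;
* accuracy is elementwise cell agreement (subset accuracy optional);
* ROC-AUC is micro-averaged over pooled (score, label) cells via the
  rank-sum formulation, ties counting one half.

Degenerate cases (no positive cell anywhere, a class never predicted)
yield 0 for the affected precision/recall by convention and NaN for a
metric undefined as a whole; the count of affected classes is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)


def _as_binary(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.ndim == 1:
        pred, truth = pred[:, None], truth[:, None]
    return pred.astype(bool), truth.astype(bool)


def confusion_counts(pred, truth):
    """Per-class (TP, FP, FN, TN) column vectors."""
    p, t = _as_binary(pred, truth)
    tp = (p & t).sum(axis=0)
    fp = (p & ~t).sum(axis=0)
    fn = (~p & t).sum(axis=0)
    tn = (~p & ~t).sum(axis=0)
    return tp, fp, fn, tn


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out


def micro_f1(pred, truth) -> float:
    """Harmonic mean of pooled precision and recall over all cells."""
    tp, fp, fn, _ = confusion_counts(pred, truth)
    TP, FP, FN = tp.sum(), fp.sum(), fn.sum()
    if TP + FP + FN == 0:
        logger.warning("micro-F1 undefined: no positive cell in pred or truth")
        return float("nan")
    precision = TP / (TP + FP) if TP + FP else 0.0
    recall = TP / (TP + FN) if TP + FN else 0.0
    if precision + recall == 0:
        return 0.0
    return float(2 * precision * recall / (precision + recall))


def macro_f1(pred, truth, variant: str = "harmonic-of-means") -> float:
    """Macro-averaged F1.

    ``harmonic-of-means`` (default): average per-class precision and
    per-class recall across classes, then one harmonic mean.
    ``mean-of-f1``: per-class F1 first, then the plain average.
    Classes with a zero denominator contribute 0 to the averages.
    """
    tp, fp, fn, _ = confusion_counts(pred, truth)
    prec_i = _safe_div(tp, tp + fp)
    rec_i = _safe_div(tp, tp + fn)
    n_zero = int(((tp + fp == 0) | (tp + fn == 0)).sum())
    if n_zero:
        logger.debug("%d class(es) with zero-denominator precision/recall", n_zero)
    if variant == "harmonic-of-means":
        P, R = prec_i.mean(), rec_i.mean()
        if P + R == 0:
            return 0.0
        return float(2 * P * R / (P + R))
    if variant == "mean-of-f1":
        f1_i = _safe_div(2 * prec_i * rec_i, prec_i + rec_i)
        return float(f1_i.mean())
    raise ValueError(f"unknown variant {variant!r}")


def accuracy(pred, truth, variant: str = "elementwise") -> float:
    """Fraction of correct cells (default) or of exactly-matched rows."""
    p, t = _as_binary(pred, truth)
    if variant == "elementwise":
        return float((p == t).mean())
    if variant == "subset":
        return float((p == t).all(axis=1).mean())
    raise ValueError(f"unknown variant {variant!r}")


def roc_auc(scores, truth) -> float:
    """Micro-averaged AUC over pooled (score, label) cells.

    Equals the probability that a uniformly random positive cell outscores
    a uniformly random negative cell, ties counting 1/2 (rank-sum form).
    """
    s = np.asarray(scores, dtype=float).ravel()
    t = np.asarray(truth).astype(bool).ravel()
    if s.shape != t.shape:
        raise ValueError("scores and truth must have the same shape")
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        logger.warning("ROC-AUC undefined: labels are all %d", int(t.any()))
        return float("nan")
    ranks = scipy.stats.rankdata(s)  # average ranks handle ties as 1/2
    return float((ranks[t].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def per_class_table(pred, truth, ko_ids, support=None) -> pd.DataFrame:
    """Per-class support, precision, recall and F1.

    ``support`` defaults to the truth column sums; pass training-set
    supports to feed :func:`support_performance_regression`.
    """
    tp, fp, fn, _ = confusion_counts(pred, truth)
    prec_i = _safe_div(tp, tp + fp)
    rec_i = _safe_div(tp, tp + fn)
    f1_i = _safe_div(2 * prec_i * rec_i, prec_i + rec_i)
    if support is None:
        support = np.asarray(truth).sum(axis=0)
    return pd.DataFrame(
        {
            "ko": list(ko_ids),
            "support": np.asarray(support, dtype=int),
            "precision": prec_i,
            "recall": rec_i,
            "f1": f1_i,
        }
    )


def support_performance_regression(per_class: pd.DataFrame,
                                   score_column: str = "f1"):
    """OLS of per-class score on class support.

    Returns ``(slope, intercept, p_value)`` with a two-sided t-test on the
    slope; a positive, significant slope means well-annotated classes are
    predicted better than sparsely annotated ones.
    """
    df = per_class.dropna(subset=[score_column, "support"])
    if len(df) < 3:
        raise ValueError("need at least 3 classes with defined scores")
    x = df["support"].to_numpy(dtype=float)
    y = df[score_column].to_numpy(dtype=float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        # degenerate: flat scores or single support level -> slope 0, p = 1
        return 0.0, float(y.mean()), 1.0
    res = scipy.stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.pvalue)


@dataclass
class MetricsReport:
    """Scalar metrics plus the per-class breakdown."""

    micro_f1: float
    macro_f1: float
    accuracy: float
    roc_auc: float
    per_class: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "micro_f1": self.micro_f1,
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "roc_auc": self.roc_auc,
        }


def evaluate_predictions(scores, binary, truth, ko_ids,
                         train_support=None) -> MetricsReport:
    """All four scalar metrics plus the per-class table in one call."""
    return MetricsReport(
        micro_f1=micro_f1(binary, truth),
        macro_f1=macro_f1(binary, truth),
        accuracy=accuracy(binary, truth),
        roc_auc=roc_auc(scores, truth),
        per_class=per_class_table(binary, truth, ko_ids, train_support),
    )
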