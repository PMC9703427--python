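"""Per-individual classification metrics from test-window predictions.

Confusion counts follow the pair-counting definition
``f(i, j) = #{t : s_t = i and shat_t = j}`` with
``[TP, FP, FN, TN] = [f(1,1), f(0,1), f(1,0), f(0,0)]``, from which

    sensitivity = TP / (TP + FN)        specificity = TN / (FP + TN)
    precision   = TP / (TP + FP)        F1 = 2 * pre * se / (pre + se)

Any ratio with a zero denominator is *undefined* and reported as NaN rather
than coerced to 0 or 1; cohort-level summaries drop NaNs pairwise.  AUC is
the area under the empirical ROC curve, equal to the Mann–Whitney
concordance probability with half credit for ties.
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import InputError, SingleClassError


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class BasicMetrics(NamedTuple):
    sensitivity: float
    specificity: float
    precision: float
    f1: float


def _binary_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional")
    if arr.size and not np.all(np.isin(arr, [0, 1])):
        raise InputError(f"{name} must be binary (0/1)")
    return arr.astype(np.int64)


def confusion_counts(true_states, pred_states) -> ConfusionCounts:
    """Count TP/FP/FN/TN over aligned binary truth and prediction vectors."""
    t = _binary_array(true_states, "true_states")
    p = _binary_array(pred_states, "pred_states")
    if t.size != p.size:
        raise InputError(
            f"length mismatch: {t.size} true states vs {p.size} predictions"
        )
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        tn=int(np.sum((t == 0) & (p == 0))),
    )


def basic_metrics(c: ConfusionCounts) -> BasicMetrics:
    """Sensitivity, specificity, precision and F1 with NaN for 0/0 cases."""
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    sp = c.tn / (c.fp + c.tn) if (c.fp + c.tn) > 0 else math.nan
    pre = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else math.nan
    if math.isnan(se) or math.isnan(pre) or (pre + se) == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * pre * se / (pre + se)
    return BasicMetrics(se, sp, pre, f1)


def roc_auc(scores, true_states) -> float:
    """Area under the ROC curve (Mann–Whitney with half-credit ties).

    Raises
    ------
    SingleClassError
        If the truth vector contains only one class; callers record NaN.
    """
    t = _binary_array(true_states, "true_states")
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1 or s.size != t.size:
        raise InputError("scores and true_states must be 1-D and equal length")
    if t.min(initial=1) == t.max(initial=0) or t.size == 0 or len(np.unique(t)) < 2:
        raise SingleClassError("AUC undefined: truth contains a single class")
    return float(roc_auc_score(t, s))


def evaluate_predictions(true_states, pred_states, scores) -> dict:
    """All five per-individual metrics as a plain dict (NaN where undefined)."""
    counts = confusion_counts(true_states, pred_states)
    se, sp, pre, f1 = basic_metrics(counts)
    try:
        auc = roc_auc(scores, true_states)
    except SingleClassError:
        auc = math.nan
    return {
        "auc": auc,
        "f1": f1,
        "sensitivity": se,
        "specificity": sp,
        "precision": pre,
        "n_test": counts.total,
    }
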