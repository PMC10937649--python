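"""Score thresholding, ROC curves, AUC, threshold selection, cross-entropy.

A classifier that outputs numeric scores is turned into a label classifier
by a threshold (decision rule: score >= t is positive).  Sweeping the
threshold traces the ROC curve — sensitivity against the false positive
rate — which is monotone inside the unit square from (0,0) to (1,1).  The
area under it (AUC) is threshold-free and equals the Mann–Whitney
probability that a random positive instance scores above a random negative
one, with ties counting one half.

Thresholds must be selected on *training* predictions only: tuning the
cut-point on the test set inflates every threshold-level metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .confusion import confusion_from_labels, youden_index, accuracy as _accuracy
from .errors import InputError, UndefinedMetricError

__all__ = [
    "ScoredPredictions",
    "RocCurve",
    "apply_threshold",
    "roc_curve",
    "auc_trapezoid",
    "auc_mann_whitney",
    "select_threshold",
    "cross_entropy",
    "binary_cross_entropy",
]


@dataclass(frozen=True)
class ScoredPredictions:
    """Numeric scores paired with binary ground-truth labels.

    ``role`` tags whether the predictions come from the training or the
    test set; threshold selection refuses test-role inputs.
    """

    scores: np.ndarray
    labels: np.ndarray
    role: Literal["train", "test"] = "test"

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.float64)
        y = np.asarray(self.labels)
        if s.shape != y.shape or s.ndim != 1 or s.size == 0:
            raise InputError("scores and labels must be 1-D, non-empty, equal length")
        if not np.isin(y, (0, 1)).all():
            raise InputError("labels must be 0 or 1")
        if self.role not in ("train", "test"):
            raise InputError(f"role must be 'train' or 'test', got {self.role!r}")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", y.astype(np.int64))

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(self.labels.size - self.labels.sum())

    def require_both_classes(self, op: str) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise UndefinedMetricError(op, "both classes must be present")


@dataclass(frozen=True)
class RocCurve:
    """Ordered ROC points with the thresholds that generate them.

    ``fpr`` and ``tpr`` run from (0,0) to (1,1), both non-decreasing; each
    point carries the smallest threshold achieving it (+inf for (0,0)).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def apply_threshold(sp: ScoredPredictions, t: float) -> np.ndarray:
    """Binary labels under the rule score >= t -> positive."""
    return (sp.scores >= t).astype(np.int64)


def roc_curve(sp: ScoredPredictions) -> RocCurve:
    """Empirical ROC curve, one point per distinct score plus sentinels.

    Ties in the scores are merged into a single point (diagonal segment),
    so the trapezoidal area matches the Mann–Whitney estimator exactly.
    """
    sp.require_both_classes("roc_curve")
    order = np.argsort(-sp.scores, kind="stable")
    scores = sp.scores[order]
    labels = sp.labels[order]
    # cumulative TP/FP after including each prediction, keeping only the
    # last index of each tie block so tied scores collapse to one point
    distinct = np.r_[scores[1:] != scores[:-1], True]
    tps = np.cumsum(labels)[distinct]
    fps = np.cumsum(1 - labels)[distinct]
    thr = scores[distinct]
    tpr = np.r_[0.0, tps / sp.n_pos]
    fpr = np.r_[0.0, fps / sp.n_neg]
    thresholds = np.r_[np.inf, thr]
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr)


def auc_trapezoid(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def auc_mann_whitney(sp: ScoredPredictions) -> float:
    """AUC as the Mann–Whitney statistic: mean over all positive–negative
    pairs of 1 (positive scores higher), 1/2 (tied), or 0."""
    sp.require_both_classes("auc")
    pos = sp.scores[sp.labels == 1]
    neg = sp.scores[sp.labels == 0]
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return float(psi.mean())


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, plus sentinels below
    the minimum and above the maximum."""
    s = np.unique(scores)
    mids = (s[:-1] + s[1:]) / 2.0
    lo = s[0] - 1.0
    hi = s[-1] + 1.0
    return np.r_[lo, mids, hi]


def select_threshold(
    train: ScoredPredictions, criterion: Literal["youden", "accuracy"] = "youden"
) -> float:
    """Cut-point maximising Youden's index or accuracy on training scores.

    Candidates are midpoints between consecutive distinct sorted scores plus
    sentinels; ties in the criterion break toward the smallest threshold.
    Raises on test-role input: the threshold must never be tuned on the
    test set.
    """
    if train.role != "train":
        raise InputError(
            "threshold selection requires training predictions (role='train'); "
            "choosing the cut-point on the test set biases every metric"
        )
    train.require_both_classes("select_threshold")
    if criterion not in ("youden", "accuracy"):
        raise InputError(f"criterion must be 'youden' or 'accuracy', got {criterion!r}")
    crit = youden_index if criterion == "youden" else _accuracy
    best_t = None
    best_v = -np.inf
    for t in _candidate_thresholds(train.scores):
        cm = confusion_from_labels(train.labels, apply_threshold(train, t))
        v = crit(cm)
        if v > best_v:  # strict: ties keep the smaller threshold
            best_v, best_t = v, float(t)
    return best_t


def cross_entropy(p, q) -> float:
    """H(p, q) = -sum_i p_i ln(q_i) over positive-label terms only.

    ``p`` are binary labels, ``q`` scores in (0, 1].  This is the loss as
    commonly printed for binary labels; only instances with p_i = 1
    contribute.  A q_i = 0 paired with p_i = 1 gives infinite loss, which
    is signalled rather than returned.  See :func:`binary_cross_entropy`
    for the full two-term form.
    """
    p_arr = np.asarray(p, dtype=np.float64)
    q_arr = np.asarray(q, dtype=np.float64)
    if p_arr.shape != q_arr.shape or p_arr.ndim != 1 or p_arr.size == 0:
        raise InputError("p and q must be 1-D, non-empty, equal length")
    if not np.isin(p_arr, (0.0, 1.0)).all():
        raise InputError("p must be binary labels")
    if (q_arr <= 0).any() or (q_arr > 1).any():
        if ((q_arr == 0) & (p_arr == 1)).any():
            raise UndefinedMetricError("cross_entropy", "q_i = 0 with p_i = 1 gives infinite loss")
        raise InputError("scores q must lie in (0, 1]")
    with np.errstate(divide="ignore"):
        return float(-(p_arr * np.log(q_arr)).sum())


def binary_cross_entropy(p, q) -> float:
    """Full two-term binary cross-entropy -sum p ln q + (1-p) ln(1-q).

    Convenience companion to :func:`cross_entropy`, which keeps only the
    positive-label term.  Requires q in (0, 1) strictly wherever the
    corresponding term is active.
    """
    p_arr = np.asarray(p, dtype=np.float64)
    q_arr = np.asarray(q, dtype=np.float64)
    if p_arr.shape != q_arr.shape or p_arr.ndim != 1 or p_arr.size == 0:
        raise InputError("p and q must be 1-D, non-empty, equal length")
    if not np.isin(p_arr, (0.0, 1.0)).all():
        raise InputError("p must be binary labels")
    bad_pos = (q_arr <= 0) & (p_arr == 1)
    bad_neg = (q_arr >= 1) & (p_arr == 0)
    if bad_pos.any() or bad_neg.any():
        raise UndefinedMetricError("binary_cross_entropy", "a log term is infinite")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            p_arr == 1, -np.log(q_arr), -np.log1p(-q_arr)
        )
    return float(terms.sum())
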