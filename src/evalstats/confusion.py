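"""Confusion matrices and count-based classification metrics.

Binary, multi-class, and multi-label classifiers are evaluated from counts
of agreement between predicted and true labels.  The binary case uses the
four classic counts TP/TN/FP/FN; the multi-class case uses a k x k count
matrix ``n_ij`` (row = true class, column = predicted class) from which a
one-vs-rest 2x2 matrix is derived per class and aggregated by micro- or
macro-averaging; the multi-label case flattens per-label indicator columns
back onto the binary machinery.

Canonical orientation is rows = true class, columns = predicted class.
Constructors accept an ``orientation`` flag and transpose on ingest, so a
matrix printed Predicted\\True can be loaded without manual transposition.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InputError, UndefinedMetricError

__all__ = [
    "BinaryConfusion",
    "ConfusionMatrixK",
    "MultiLabelSet",
    "BinaryMetricReport",
    "Metric",
    "confusion_from_labels",
    "binary_metrics",
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "youden_index",
    "f1_score",
    "cohen_kappa_binary",
    "mcc_binary",
    "per_class_confusion",
    "macro_average",
    "micro_average",
    "cohen_kappa_multiclass",
    "mcc_multiclass",
    "hamming_loss",
    "multilabel_average",
]


class Metric(str, enum.Enum):
    """Closed set of count-based metric identifiers accepted by averaging."""

    ACCURACY = "accuracy"
    SENSITIVITY = "sensitivity"
    SPECIFICITY = "specificity"
    PRECISION = "precision"
    YOUDEN = "youden"
    F1 = "f1"
    KAPPA = "kappa"
    MCC = "mcc"


@dataclass(frozen=True)
class BinaryConfusion:
    """The four counts of a binary prediction set.

    ``tp`` correctly predicted positives, ``tn`` correctly predicted
    negatives, ``fp`` negatives predicted positive, ``fn`` positives
    predicted negative.  All counts are non-negative and at least one must
    be positive for any metric evaluation.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise InputError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_matrix(self) -> np.ndarray:
        """2x2 array with rows = true class (positive first)."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=np.int64)


@dataclass(frozen=True)
class ConfusionMatrixK:
    """k x k confusion matrix of counts, rows = true, columns = predicted."""

    counts: np.ndarray
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise InputError(f"confusion matrix must be square, got shape {counts.shape}")
        if counts.shape[0] < 2:
            raise InputError("confusion matrix needs k >= 2 classes")
        if (counts < 0).any():
            raise InputError("confusion matrix counts must be non-negative")
        if counts.sum() == 0:
            raise InputError("confusion matrix must contain at least one instance")
        object.__setattr__(self, "counts", counts)
        if self.class_names is not None:
            names = tuple(self.class_names)
            if len(names) != counts.shape[0]:
                raise InputError("class_names length must equal k")
            object.__setattr__(self, "class_names", names)

    @classmethod
    def from_counts(
        cls,
        counts,
        class_names: Sequence[str] | None = None,
        orientation: str = "true_rows",
    ) -> "ConfusionMatrixK":
        """Build a matrix, transposing on ingest if printed Predicted\\True.

        ``orientation`` is ``"true_rows"`` (canonical) or ``"pred_rows"``.
        """
        arr = np.asarray(counts, dtype=np.int64)
        if orientation == "pred_rows":
            arr = arr.T
        elif orientation != "true_rows":
            raise InputError(f"unknown orientation {orientation!r}")
        return cls(arr, tuple(class_names) if class_names is not None else None)

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class MultiLabelSet:
    """Paired n x k binary indicator matrices of true and predicted labels."""

    truth: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.truth, dtype=np.int64)
        p = np.asarray(self.predicted, dtype=np.int64)
        if t.shape != p.shape:
            raise InputError(f"shape mismatch: truth {t.shape} vs predicted {p.shape}")
        if t.ndim != 2 or t.size == 0:
            raise InputError("multi-label matrices must be non-empty and 2-D")
        for name, m in (("truth", t), ("predicted", p)):
            if not np.isin(m, (0, 1)).all():
                raise InputError(f"{name} entries must be 0 or 1")
        object.__setattr__(self, "truth", t)
        object.__setattr__(self, "predicted", p)


@dataclass(frozen=True)
class BinaryMetricReport:
    """The six threshold-level metrics of a binary confusion matrix."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    youden: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "youden": self.youden,
            "f1": self.f1,
        }


# ---------------------------------------------------------------------------
# Binary metrics
# ---------------------------------------------------------------------------

def confusion_from_labels(true_labels, pred_labels) -> BinaryConfusion:
    """Tally TP/TN/FP/FN from paired binary label sequences."""
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.shape != p.shape or t.ndim != 1 or t.size == 0:
        raise InputError("label sequences must be 1-D, non-empty, and equal length")
    for name, arr in (("true", t), ("pred", p)):
        if not np.isin(arr, (0, 1)).all():
            raise InputError(f"{name} labels must be 0 or 1")
    t = t.astype(bool)
    p = p.astype(bool)
    return BinaryConfusion(
        tp=int((t & p).sum()),
        tn=int((~t & ~p).sum()),
        fp=int((~t & p).sum()),
        fn=int((t & ~p).sum()),
    )


def _ratio(num: float, den: float, metric: str, context: str | None = None) -> float:
    if den == 0:
        raise UndefinedMetricError(metric, "zero denominator", context)
    return num / den


def accuracy(cm: BinaryConfusion, *, _ctx: str | None = None) -> float:
    return _ratio(cm.tp + cm.tn, cm.total, "accuracy", _ctx)


def sensitivity(cm: BinaryConfusion, *, _ctx: str | None = None) -> float:
    """Recall / true positive rate: TP / (TP + FN)."""
    return _ratio(cm.tp, cm.tp + cm.fn, "sensitivity", _ctx)


def specificity(cm: BinaryConfusion, *, _ctx: str | None = None) -> float:
    """True negative rate: TN / (TN + FP)."""
    return _ratio(cm.tn, cm.tn + cm.fp, "specificity", _ctx)


def precision(cm: BinaryConfusion, *, _ctx: str | None = None) -> float:
    """Positive predictive value: TP / (TP + FP)."""
    return _ratio(cm.tp, cm.tp + cm.fp, "precision", _ctx)


def youden_index(cm: BinaryConfusion, *, _ctx: str | None = None) -> float:
    """Sensitivity + specificity - 1, weighting both classes equally."""
    return sensitivity(cm, _ctx=_ctx) + specificity(cm, _ctx=_ctx) - 1.0


def f1_score(cm: BinaryConfusion, *, _ctx: str | None = None) -> float:
    """Harmonic mean of precision and recall: 2 TP / (2 TP + FP + FN)."""
    return _ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1", _ctx)


def binary_metrics(cm: BinaryConfusion) -> BinaryMetricReport:
    """All six count metrics at once; raises if any denominator is zero."""
    return BinaryMetricReport(
        accuracy=accuracy(cm),
        sensitivity=sensitivity(cm),
        specificity=specificity(cm),
        precision=precision(cm),
        youden=youden_index(cm),
        f1=f1_score(cm),
    )


def cohen_kappa_binary(cm: BinaryConfusion, *, _ctx: str | None = None) -> float:
    """Chance-corrected agreement kappa = (Acc - p_e) / (1 - p_e).

    The chance agreement p_e is the marginal product formula
    ((TP+FN)(TP+FP) + (TN+FP)(TN+FN)) / total^2.
    """
    n = cm.total
    if n == 0:
        raise UndefinedMetricError("kappa", "empty confusion matrix", _ctx)
    pe = ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.tn + cm.fp) * (cm.tn + cm.fn)) / n**2
    if pe == 1.0:
        raise UndefinedMetricError("kappa", "chance agreement p_e = 1", _ctx)
    acc = (cm.tp + cm.tn) / n
    return (acc - pe) / (1.0 - pe)


def mcc_binary(cm: BinaryConfusion, *, _ctx: str | None = None) -> float:
    """Matthews correlation: (TN*TP - FN*FP) / sqrt of the marginal product."""
    den = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if den == 0:
        raise UndefinedMetricError("mcc", "a marginal sum is zero", _ctx)
    return (cm.tn * cm.tp - cm.fn * cm.fp) / math.sqrt(den)


_METRIC_FUNCS = {
    Metric.ACCURACY: accuracy,
    Metric.SENSITIVITY: sensitivity,
    Metric.SPECIFICITY: specificity,
    Metric.PRECISION: precision,
    Metric.YOUDEN: youden_index,
    Metric.F1: f1_score,
    Metric.KAPPA: cohen_kappa_binary,
    Metric.MCC: mcc_binary,
}


def _binary_metric(metric: Metric | str, cm: BinaryConfusion, ctx: str | None = None) -> float:
    return _METRIC_FUNCS[Metric(metric)](cm, _ctx=ctx)


# ---------------------------------------------------------------------------
# Multi-class metrics
# ---------------------------------------------------------------------------

def per_class_confusion(K: ConfusionMatrixK, i: int) -> BinaryConfusion:
    """One-vs-rest 2x2 matrix for class ``i`` (0-based index).

    TP_i = n_ii, FN_i = rest of row i, FP_i = rest of column i, TN_i =
    everything outside row and column i; the four counts sum to n.
    """
    if not 0 <= i < K.k:
        raise InputError(f"class index {i} out of range for k={K.k}")
    c = K.counts
    tp = int(c[i, i])
    fn = int(c[i, :].sum() - tp)
    fp = int(c[:, i].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)
    return BinaryConfusion(tp=tp, tn=tn, fp=fp, fn=fn)


def macro_average(K: ConfusionMatrixK, metric: Metric | str) -> float:
    """Mean of the per-class metric values (equal weight per class)."""
    values = []
    for i in range(K.k):
        ctx = f"class {K.class_names[i] if K.class_names else i}"
        try:
            values.append(_binary_metric(metric, per_class_confusion(K, i), ctx))
        except UndefinedMetricError as err:
            raise UndefinedMetricError(
                f"macro {Metric(metric).value}", err.reason, err.context
            ) from err
    return float(np.mean(values))


def micro_average(K: ConfusionMatrixK, metric: Metric | str) -> float:
    """Metric evaluated once on the per-class counts summed over classes."""
    parts = [per_class_confusion(K, i) for i in range(K.k)]
    pooled = BinaryConfusion(
        tp=sum(p.tp for p in parts),
        tn=sum(p.tn for p in parts),
        fp=sum(p.fp for p in parts),
        fn=sum(p.fn for p in parts),
    )
    return _binary_metric(metric, pooled, "pooled counts")


def per_class_metrics(K: ConfusionMatrixK, metric: Metric | str) -> list[float]:
    """Per-class one-vs-rest values, in class order."""
    return [
        _binary_metric(metric, per_class_confusion(K, i), f"class {i}")
        for i in range(K.k)
    ]


def cohen_kappa_multiclass(K: ConfusionMatrixK) -> float:
    """kappa = (p0 - pe)/(1 - pe) with p0 the diagonal fraction and
    pe = sum_i n_i. * n_.i / n^2 from the marginals."""
    c = K.counts
    n = K.n
    p0 = float(np.trace(c)) / n
    pe = float(K.row_sums() @ K.col_sums()) / n**2
    if pe == 1.0:
        raise UndefinedMetricError("kappa", "chance agreement p_e = 1")
    return (p0 - pe) / (1.0 - pe)


def mcc_multiclass(K: ConfusionMatrixK) -> float:
    """Matthews correlation generalised to a k x k confusion matrix.

    MCC = (n * trace - sum_i n_i. n_.i)
          / sqrt((n^2 - sum n_i.^2)(n^2 - sum n_.i^2)).
    Reduces to the binary formula at k = 2.
    """
    c = K.counts.astype(np.float64)
    n = float(K.n)
    rows = K.row_sums().astype(np.float64)
    cols = K.col_sums().astype(np.float64)
    num = n * np.trace(c) - rows @ cols
    t_rows = n**2 - (rows**2).sum()
    t_cols = n**2 - (cols**2).sum()
    if t_rows <= 0 or t_cols <= 0:
        raise UndefinedMetricError("mcc", "a marginal variance term is zero")
    return float(num / math.sqrt(t_rows * t_cols))


# ---------------------------------------------------------------------------
# Multi-label metrics
# ---------------------------------------------------------------------------

def hamming_loss(ml: MultiLabelSet) -> float:
    """Mean elementwise disagreement over all n*k label slots; 0 is best."""
    return float(np.abs(ml.truth - ml.predicted).mean())


def multilabel_average(ml: MultiLabelSet, metric: Metric | str, how: str = "micro") -> float:
    """Micro or macro average of a count metric over the k label columns.

    Each label column is a binary classification problem; micro pools the
    per-label confusion counts, macro averages the per-label values.
    """
    k = ml.truth.shape[1]
    parts = [
        confusion_from_labels(ml.truth[:, j], ml.predicted[:, j]) for j in range(k)
    ]
    if how == "micro":
        pooled = BinaryConfusion(
            tp=sum(p.tp for p in parts),
            tn=sum(p.tn for p in parts),
            fp=sum(p.fp for p in parts),
            fn=sum(p.fn for p in parts),
        )
        return _binary_metric(metric, pooled, "pooled labels")
    if how == "macro":
        return float(
            np.mean([_binary_metric(metric, p, f"label {j}") for j, p in enumerate(parts)])
        )
    raise InputError(f"how must be 'micro' or 'macro', got {how!r}")
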