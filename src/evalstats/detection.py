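"""Object-detection matching and mAP; ranked-retrieval precision, AP, DCG.

A detector's predicted bounding boxes are matched to ground-truth boxes of
the same class when their IoU reaches a threshold (commonly 0.5); among
several candidates only the highest-IoU ground truth is matched, and every
surplus prediction is a false positive.  Sweeping the detector's
confidence threshold yields a precision–recall curve whose area is the
average precision (AP); mAP averages AP over classes, and mAP@[0.5:0.95]
additionally averages over IoU thresholds 0.5, 0.55, ..., 0.95.

For ranked retrieval, P@k is the fraction of relevant results in the top
k; AP averages P@k over the ranks of relevant results, normalised by the
total number of relevant documents in the collection; DCG discounts graded
gains by log2(rank + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InputError, UndefinedMetricError

__all__ = [
    "Box",
    "RankedList",
    "MatchResult",
    "box_iou",
    "match_detections",
    "detection_pr_curve",
    "average_precision_detection",
    "map_at",
    "map_range",
    "precision_at_k",
    "average_precision_retrieval",
    "dcg",
    "mean_dcg",
    "DEFAULT_GAINS",
]

# conventional gains for graded relevance: perfect/excellent/good/fair/bad
DEFAULT_GAINS = {"perfect": 10.0, "excellent": 7.0, "good": 3.0, "fair": 0.5, "bad": 0.0}


@dataclass(frozen=True)
class Box:
    """Axis-aligned bounding box with a class label and optional confidence."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    label: str = "object"
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise InputError(
                f"degenerate box: ({self.x_min},{self.y_min})-({self.x_max},{self.y_max})"
            )
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise InputError("confidence must lie in [0, 1]")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass(frozen=True)
class RankedList:
    """Retrieval results ordered by estimated relevance.

    ``relevances`` are binary (0/1) or graded gains; ``total_relevant`` is
    the number of relevant documents in the whole collection (defaults to
    the number of relevant results in the list, i.e. full recall).
    """

    relevances: tuple[float, ...]
    total_relevant: int | None = None

    def __post_init__(self) -> None:
        rel = tuple(float(r) for r in self.relevances)
        if not rel:
            raise InputError("ranked list must be non-empty")
        object.__setattr__(self, "relevances", rel)
        n_rel = sum(1 for r in rel if r > 0)
        if self.total_relevant is not None and self.total_relevant < n_rel:
            raise InputError(
                "total_relevant cannot be smaller than the relevant results retrieved"
            )


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching predictions to ground truths in one image."""

    tp: int
    fp: int
    fn: int
    designations: tuple[str, ...]  # per prediction, "tp" or "fp"
    matched_gt: tuple[int | None, ...]  # index of the matched GT, or None


def box_iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes' areas."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def _sorted_by_confidence(preds: Sequence[Box]) -> list[int]:
    """Indices of predictions in decreasing confidence (stable for ties;
    confidence-less predictions keep their listed order at the end)."""
    keyed = [(-(p.confidence if p.confidence is not None else -np.inf), i) for i, p in enumerate(preds)]
    return [i for _, i in sorted(keyed, key=lambda t: (t[0], t[1]))]


def match_detections(
    preds: Sequence[Box], gts: Sequence[Box], iou_threshold: float = 0.5
) -> MatchResult:
    """Greedy class-partitioned matching of predictions to ground truths.

    Predictions are processed in decreasing confidence; each may match at
    most one unmatched ground truth of the *same class* whose IoU meets
    ``iou_threshold``, taking the highest-IoU candidate (exact ties break
    toward the earlier-listed ground truth).  Unmatched predictions are
    FP, unmatched ground truths FN; tp + fn = #GT and tp + fp = #preds.
    """
    taken = [False] * len(gts)
    designations: list[str] = ["fp"] * len(preds)
    matched: list[int | None] = [None] * len(preds)
    for pi in _sorted_by_confidence(preds):
        p = preds[pi]
        best_iou = 0.0
        best_gi: int | None = None
        for gi, g in enumerate(gts):
            if taken[gi] or g.label != p.label:
                continue
            v = box_iou(p, g)
            if v >= iou_threshold and v > best_iou:
                best_iou, best_gi = v, gi
        if best_gi is not None:
            taken[best_gi] = True
            designations[pi] = "tp"
            matched[pi] = best_gi
    tp = designations.count("tp")
    return MatchResult(
        tp=tp,
        fp=len(preds) - tp,
        fn=len(gts) - tp,
        designations=tuple(designations),
        matched_gt=tuple(matched),
    )


def detection_pr_curve(
    preds: Sequence[Box],
    gts: Sequence[Box],
    iou_threshold: float = 0.5,
) -> list[tuple[float, float, float]]:
    """(confidence cut-off, recall, precision) per distinct confidence.

    Matching is re-evaluated at each cut-off on the predictions whose
    confidence reaches it, from the strictest cut-off down.  Recall is
    non-decreasing along decreasing cut-offs.
    """
    if any(p.confidence is None for p in preds):
        raise InputError("all predictions need a confidence for a PR curve")
    if not gts:
        raise UndefinedMetricError("pr_curve", "no ground-truth boxes (recall undefined)")
    cutoffs = sorted({p.confidence for p in preds}, reverse=True)
    points = []
    for c in cutoffs:
        kept = [p for p in preds if p.confidence >= c]
        m = match_detections(kept, gts, iou_threshold)
        prec = m.tp / (m.tp + m.fp) if (m.tp + m.fp) else 1.0
        rec = m.tp / len(gts)
        points.append((c, rec, prec))
    return points


def average_precision_detection(
    curve: Sequence[tuple[float, float, float]], method: str = "envelope"
) -> float:
    """Area under the detection PR curve.

    ``method="envelope"`` (default) integrates the precision envelope
    p(r) = max precision achieved at recall >= r (every-point
    interpolation), removing the sawtooth ambiguity; ``method="trapezoid"``
    integrates the raw points.  Precision is 0 beyond the largest recall
    achieved.
    """
    if not curve:
        return 0.0
    pts = sorted((r, p) for _, r, p in curve)
    recalls = np.array([r for r, _ in pts])
    precisions = np.array([p for _, p in pts])
    if method == "envelope":
        env = np.maximum.accumulate(precisions[::-1])[::-1]
        prev_r = 0.0
        ap = 0.0
        for r, p in zip(recalls, env):
            ap += (r - prev_r) * p
            prev_r = r
        return float(ap)
    if method == "trapezoid":
        rs = np.r_[0.0, recalls]
        ps = np.r_[precisions[:1], precisions]
        return float(np.trapezoid(ps, rs))
    raise InputError(f"method must be 'envelope' or 'trapezoid', got {method!r}")


def map_at(
    scenes: Sequence[tuple[Sequence[Box], Sequence[Box]]],
    classes: Sequence[str] | None = None,
    iou_threshold: float = 0.5,
) -> float:
    """Mean over classes of AP at one IoU threshold, pooled across scenes.

    ``scenes`` is a list of (predictions, ground truths) pairs, one per
    image.  A class with no ground-truth box in any scene has no defined
    recall and is excluded.
    """
    if classes is None:
        classes = sorted({g.label for _, gts in scenes for g in gts})
    aps = []
    for cls in classes:
        total_gt = sum(sum(1 for g in gts if g.label == cls) for _, gts in scenes)
        if total_gt == 0:
            continue
        cls_preds = [
            [p for p in preds if p.label == cls] for preds, _ in scenes
        ]
        cls_gts = [[g for g in gts if g.label == cls] for _, gts in scenes]
        cutoffs = sorted(
            {p.confidence for preds in cls_preds for p in preds}, reverse=True
        )
        if not cutoffs:
            aps.append(0.0)
            continue
        curve = []
        for c in cutoffs:
            tp = fp = 0
            for preds, gts in zip(cls_preds, cls_gts):
                kept = [p for p in preds if p.confidence >= c]
                m = match_detections(kept, gts, iou_threshold)
                tp += m.tp
                fp += m.fp
            prec = tp / (tp + fp) if (tp + fp) else 1.0
            rec = tp / total_gt
            curve.append((c, rec, prec))
        aps.append(average_precision_detection(curve))
    if not aps:
        raise UndefinedMetricError("mAP", "no class has any ground-truth box")
    return float(np.mean(aps))


def map_range(
    scenes: Sequence[tuple[Sequence[Box], Sequence[Box]]],
    thresholds: Sequence[float] | None = None,
    classes: Sequence[str] | None = None,
) -> float:
    """mAP averaged over IoU thresholds (default 0.5 to 0.95, step 0.05)."""
    if thresholds is None:
        thresholds = np.arange(0.5, 0.951, 0.05).round(2).tolist()
    return float(np.mean([map_at(scenes, classes, t) for t in thresholds]))


# ---------------------------------------------------------------------------
# Ranked retrieval
# ---------------------------------------------------------------------------

def precision_at_k(rl: RankedList, k: int) -> float:
    """P@k = (number of relevant results in the top k) / k."""
    if not 1 <= k <= len(rl.relevances):
        raise InputError(f"k must be in [1, {len(rl.relevances)}], got {k}")
    return sum(1.0 for r in rl.relevances[:k] if r > 0) / k


def average_precision_retrieval(rl: RankedList) -> float:
    """AP = sum over ranks k of rel(d_k) * P@k, divided by the total number
    of relevant documents in the collection."""
    total = (
        rl.total_relevant
        if rl.total_relevant is not None
        else sum(1 for r in rl.relevances if r > 0)
    )
    if total == 0:
        if any(r > 0 for r in rl.relevances):
            raise InputError("total_relevant is 0 but relevant results are present")
        return 0.0
    num = sum(
        precision_at_k(rl, k + 1)
        for k, r in enumerate(rl.relevances)
        if r > 0
    )
    return num / total


def dcg(gains: Sequence[float | str], k: int | None = None) -> float:
    """Discounted cumulative gain sum_{i<=k} G(i) / log2(i + 1).

    ``gains`` are numeric, or grade names mapped through the conventional
    values perfect=10, excellent=7, good=3, fair=0.5, bad=0.
    """
    numeric = []
    for g in gains:
        if isinstance(g, str):
            try:
                numeric.append(DEFAULT_GAINS[g.lower()])
            except KeyError:
                raise InputError(
                    f"unknown grade {g!r}; known grades: {sorted(DEFAULT_GAINS)}"
                ) from None
        else:
            numeric.append(float(g))
    if k is None:
        k = len(numeric)
    if not 1 <= k <= len(numeric):
        raise InputError(f"k must be in [1, {len(numeric)}], got {k}")
    ranks = np.arange(1, k + 1)
    return float((np.array(numeric[:k]) / np.log2(ranks + 1)).sum())


def mean_dcg(lists: Sequence[Sequence[float | str]], k: int | None = None) -> float:
    """Mean DCG across queries."""
    if not lists:
        raise InputError("need at least one ranked list")
    return float(np.mean([dcg(g, k) for g in lists]))
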