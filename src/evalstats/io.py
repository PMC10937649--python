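"""Readers and writers for the toolkit's interchange formats.

CSV files are comma-separated UTF-8 with a required header row and ``.``
decimal separator.  Confusion matrices travel as TSV with a one-line
``# orientation=...`` header so the true/predicted axis convention is
explicit in the file itself.  2D masks are PNG (0/255) or delimited text;
3D masks are NIfTI.  Every writer's output is a valid input of the
corresponding reader.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .advisor import FoldPlan
from .confusion import ConfusionMatrixK
from .detection import Box, RankedList
from .errors import InputError
from .regression import PairedRealVectors
from .roc import RocCurve, ScoredPredictions
from .segmentation import Mask
from .stattests import MetricMatrix, PairedSamples

__all__ = [
    "read_confusion_tsv",
    "write_confusion_tsv",
    "read_label_predictions_csv",
    "read_scored_predictions_csv",
    "write_roc_csv",
    "read_regression_csv",
    "read_paired_samples_csv",
    "read_metric_matrix_csv",
    "read_boxes_csv",
    "read_ranked_lists_csv",
    "read_mask",
    "write_mask",
    "write_fold_plan_csv",
]


# ---------------------------------------------------------------------------
# Confusion matrices (TSV with orientation header)
# ---------------------------------------------------------------------------

def write_confusion_tsv(path, K: ConfusionMatrixK, orientation: str = "true_rows") -> None:
    """Write a confusion matrix as TSV with an orientation header line."""
    if orientation not in ("true_rows", "pred_rows"):
        raise InputError(f"unknown orientation {orientation!r}")
    counts = K.counts if orientation == "true_rows" else K.counts.T
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# orientation={orientation}\n")
        if K.class_names:
            fh.write("\t".join(K.class_names) + "\n")
        for row in counts:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def read_confusion_tsv(path) -> ConfusionMatrixK:
    """Read a confusion matrix written by :func:`write_confusion_tsv`."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("# orientation="):
        raise InputError(f"{path}: missing '# orientation=' header on line 1")
    orientation = lines[0].split("=", 1)[1].strip()
    body = [ln for ln in lines[1:] if ln.strip()]
    class_names = None
    first = body[0].split("\t")
    if any(not _is_int(tok) for tok in first):
        class_names = tuple(first)
        body = body[1:]
    try:
        counts = [[int(tok) for tok in ln.split("\t")] for ln in body]
    except ValueError as err:
        raise InputError(f"{path}: non-integer count ({err})") from None
    return ConfusionMatrixK.from_counts(counts, class_names=class_names, orientation=orientation)


def _is_int(tok: str) -> bool:
    try:
        int(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Prediction tables
# ---------------------------------------------------------------------------

def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    return df


def read_label_predictions_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Columns ``id,y_true,y_pred`` -> (true labels, predicted labels)."""
    df = _read_csv(path, ["id", "y_true", "y_pred"])
    return df["y_true"].to_numpy(), df["y_pred"].to_numpy()


def read_scored_predictions_csv(path, role: str = "test") -> dict[str, ScoredPredictions]:
    """Columns ``id,y_true,y_score[,model]`` -> per-model ScoredPredictions.

    Without a ``model`` column the result has the single key ``"model"``.
    """
    df = _read_csv(path, ["id", "y_true", "y_score"])
    if "model" not in df.columns:
        df = df.assign(model="model")
    out = {}
    for name, grp in df.groupby("model", sort=True):
        out[str(name)] = ScoredPredictions(
            scores=grp["y_score"].to_numpy(dtype=float),
            labels=grp["y_true"].to_numpy(),
            role=role,
        )
    return out


def write_roc_csv(path, curve: RocCurve) -> None:
    """ROC curve as CSV ``threshold,fpr,tpr``."""
    pd.DataFrame(
        {"threshold": curve.thresholds, "fpr": curve.fpr, "tpr": curve.tpr}
    ).to_csv(path, index=False)


def read_regression_csv(path) -> PairedRealVectors:
    """Columns ``id,x,y`` -> paired ground truth / prediction vectors."""
    df = _read_csv(path, ["id", "x", "y"])
    return PairedRealVectors(x=df["x"].to_numpy(dtype=float), y=df["y"].to_numpy(dtype=float))


def read_paired_samples_csv(path) -> PairedSamples:
    """Columns ``unit_id,model_a,model_b`` -> paired metric samples."""
    df = _read_csv(path, ["unit_id", "model_a", "model_b"])
    return PairedSamples(
        a=df["model_a"].to_numpy(dtype=float), b=df["model_b"].to_numpy(dtype=float)
    )


def read_metric_matrix_csv(path) -> MetricMatrix:
    """Columns ``dataset_id,<model>,...`` -> J x K metric matrix."""
    df = pd.read_csv(path)
    if "dataset_id" not in df.columns:
        raise InputError(f"{path}: missing required column 'dataset_id'")
    models = [c for c in df.columns if c != "dataset_id"]
    if len(models) < 2:
        raise InputError(f"{path}: need at least two model columns")
    return MetricMatrix(df[models].to_numpy(dtype=float), model_names=tuple(models))


# ---------------------------------------------------------------------------
# Detection and retrieval tables
# ---------------------------------------------------------------------------

def read_boxes_csv(path, with_confidence: bool) -> dict[str, list[Box]]:
    """Detections/ground-truth boxes grouped by image id.

    Detections have columns ``image_id,class,x_min,y_min,x_max,y_max,
    confidence``; ground truth the same minus ``confidence``.
    """
    cols = ["image_id", "class", "x_min", "y_min", "x_max", "y_max"]
    if with_confidence:
        cols.append("confidence")
    df = _read_csv(path, cols)
    out: dict[str, list[Box]] = {}
    for i, row in df.iterrows():
        try:
            box = Box(
                x_min=float(row["x_min"]),
                y_min=float(row["y_min"]),
                x_max=float(row["x_max"]),
                y_max=float(row["y_max"]),
                label=str(row["class"]),
                confidence=float(row["confidence"]) if with_confidence else None,
            )
        except (InputError, ValueError) as err:
            raise InputError(f"{path}: line {i + 2}: {err}") from None
        out.setdefault(str(row["image_id"]), []).append(box)
    return out


def read_ranked_lists_csv(path) -> dict[str, RankedList]:
    """Columns ``query_id,rank,rel_or_grade`` -> per-query ranked lists."""
    df = _read_csv(path, ["query_id", "rank", "rel_or_grade"])
    out = {}
    for qid, grp in df.groupby("query_id", sort=True):
        grp = grp.sort_values("rank")
        out[str(qid)] = RankedList(tuple(grp["rel_or_grade"].astype(float)))
    return out


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

def read_mask(path, threshold: float | None = None, spacing=1.0) -> Mask:
    """Read a mask from PNG (2D, 0/255), delimited text (2D), or NIfTI (3D).

    ``threshold`` binarises probabilistic or 0-255 images at ingest (grid
    value >= threshold becomes foreground); without it, any strictly
    positive value is foreground.
    """
    p = Path(path)
    suffixes = "".join(p.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(p))
        grid = np.asanyarray(img.dataobj)
    elif suffixes.endswith(".png"):
        from PIL import Image

        grid = np.asarray(Image.open(p).convert("L"))
    else:
        grid = np.loadtxt(p)
    if threshold is not None:
        grid = (grid >= threshold).astype(np.int8)
    else:
        grid = (grid > 0).astype(np.int8)
    return Mask(grid, spacing=spacing)


def write_mask(path, m: Mask) -> None:
    """Write a mask as PNG (2D, 0/255), text, or NIfTI per the extension."""
    p = Path(path)
    suffixes = "".join(p.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(m.grid.astype(np.uint8), affine=np.eye(4)), str(p))
    elif suffixes.endswith(".png"):
        from PIL import Image

        if m.ndim != 2:
            raise InputError("PNG masks must be 2-D")
        Image.fromarray((m.grid.astype(np.uint8)) * 255, mode="L").save(p)
    else:
        np.savetxt(p, m.grid.astype(np.uint8), fmt="%d")


def write_fold_plan_csv(path, plan: FoldPlan) -> None:
    """Fold plan as CSV ``round,role,index``."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["round", "role", "index"])
        for rnd, (train, test) in enumerate(plan.rounds):
            for i in train:
                writer.writerow([rnd, "train", i])
            for i in test:
                writer.writerow([rnd, "test", i])
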