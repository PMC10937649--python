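"""Overlap, surface-distance, and structural-similarity metrics for masks.

Binary segmentation masks are compared voxelwise (TP/TN/FP/FN counts,
Dice, IoU and their error complements SVD and VOE) and by the geometry of
their surfaces (surface Dice, average symmetric surface distance, Hausdorff
distance).  Accuracy is a poor metric here: with a sparse foreground the
background dominates and accuracy stays near 1 even when the predicted
object misses the true one entirely, which is why overlap metrics ignore
the true negatives.

A surface voxel is a mask voxel with at least one neighbour outside the
mask, where the neighbourhood is 8-connected in 2D and 18- or 26-connected
in 3D, and the grid boundary counts as outside.  Distances are Euclidean,
scaled by the (possibly anisotropic) voxel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .confusion import BinaryConfusion
from .errors import InputError, UndefinedMetricError

__all__ = [
    "Mask",
    "SurfaceSet",
    "LabelMask",
    "overlap_counts",
    "dice",
    "dice_from_counts",
    "iou",
    "iou_from_counts",
    "surface_extract",
    "surface_dice",
    "asd",
    "hausdorff",
    "svd_error",
    "voe_error",
    "ssim",
    "mean_class_dice",
]

# connectivity code -> scipy binary structure rank (1 = faces, 2 = +edges,
# 3 = +corners); 8 is the full 2D neighbourhood, 18/26 the two 3D ones
_CONNECTIVITY = {
    (2, 4): 1,
    (2, 8): 2,
    (3, 6): 1,
    (3, 18): 2,
    (3, 26): 3,
}


@dataclass(frozen=True)
class Mask:
    """Binary 2D/3D segmentation mask with optional voxel spacing.

    ``spacing`` is a scalar (isotropic) or per-axis sequence used inside
    Euclidean distances; unit spacing by default.
    """

    grid: np.ndarray
    spacing: tuple[float, ...] | float = 1.0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim not in (2, 3) or g.size == 0:
            raise InputError("mask grid must be a non-empty 2-D or 3-D array")
        if not np.isin(g, (0, 1)).all():
            raise InputError("mask entries must be 0 or 1")
        object.__setattr__(self, "grid", g.astype(bool))
        sp = self.spacing
        if np.isscalar(sp):
            sp = (float(sp),) * g.ndim
        else:
            sp = tuple(float(s) for s in sp)
            if len(sp) != g.ndim:
                raise InputError("spacing length must equal mask dimensionality")
        if any(s <= 0 for s in sp):
            raise InputError("spacing must be positive")
        object.__setattr__(self, "spacing", sp)

    @property
    def ndim(self) -> int:
        return self.grid.ndim

    @property
    def volume(self) -> int:
        """Number of foreground voxels |X|."""
        return int(self.grid.sum())


@dataclass(frozen=True)
class SurfaceSet:
    """Coordinates of the surface voxels of a mask and the connectivity used."""

    coords: np.ndarray  # (n_voxels, ndim) integer indices
    connectivity: int
    spacing: tuple[float, ...]

    @property
    def size(self) -> int:
        return self.coords.shape[0]

    def physical(self) -> np.ndarray:
        """Coordinates scaled by the voxel spacing."""
        return self.coords * np.asarray(self.spacing)


@dataclass(frozen=True)
class LabelMask:
    """Integer-labelled grid for semantic (multi-class) segmentation."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim not in (2, 3) or g.size == 0:
            raise InputError("label grid must be a non-empty 2-D or 3-D array")
        if not np.issubdtype(g.dtype, np.integer):
            raise InputError("label grid must be integer-typed")
        object.__setattr__(self, "grid", g)

    def classes(self) -> np.ndarray:
        return np.unique(self.grid)

    def indicator(self, label: int) -> Mask:
        return Mask((self.grid == label).astype(np.int8))


# ---------------------------------------------------------------------------
# Overlap metrics
# ---------------------------------------------------------------------------

def _check_shapes(a: Mask, b: Mask) -> None:
    if a.grid.shape != b.grid.shape:
        raise InputError(f"mask shapes differ: {a.grid.shape} vs {b.grid.shape}")


def overlap_counts(a: Mask, b: Mask) -> BinaryConfusion:
    """Voxelwise TP/TN/FP/FN with ``a`` the ground truth, ``b`` the prediction."""
    _check_shapes(a, b)
    t, p = a.grid, b.grid
    return BinaryConfusion(
        tp=int((t & p).sum()),
        tn=int((~t & ~p).sum()),
        fp=int((~t & p).sum()),
        fn=int((t & ~p).sum()),
    )


def dice_from_counts(cm: BinaryConfusion) -> float:
    """Dice score 2TP / (2TP + FP + FN) from a voxel confusion matrix."""
    den = 2 * cm.tp + cm.fp + cm.fn
    if den == 0:
        raise UndefinedMetricError("dice", "both masks are empty")
    return 2 * cm.tp / den


def dice(a: Mask, b: Mask) -> float:
    """Sorensen–Dice similarity 2|X ∩ Y| / (|X| + |Y|)."""
    _check_shapes(a, b)
    den = a.volume + b.volume
    if den == 0:
        raise UndefinedMetricError("dice", "both masks are empty")
    inter = int((a.grid & b.grid).sum())
    return 2 * inter / den


def iou_from_counts(cm: BinaryConfusion) -> float:
    """Jaccard / IoU: TP / (TP + FP + FN)."""
    den = cm.tp + cm.fp + cm.fn
    if den == 0:
        raise UndefinedMetricError("iou", "both masks are empty")
    return cm.tp / den


def iou(a: Mask, b: Mask) -> float:
    """Jaccard similarity |X ∩ Y| / |X ∪ Y|; equals D / (2 - D)."""
    _check_shapes(a, b)
    union = int((a.grid | b.grid).sum())
    if union == 0:
        raise UndefinedMetricError("iou", "both masks are empty")
    inter = int((a.grid & b.grid).sum())
    return inter / union


def svd_error(a: Mask, b: Mask) -> float:
    """Symmetric volume difference, the Dice-based error 1 - D."""
    return 1.0 - dice(a, b)


def voe_error(a: Mask, b: Mask) -> float:
    """Volumetric overlap error, the IoU-based error 1 - IoU."""
    return 1.0 - iou(a, b)


# ---------------------------------------------------------------------------
# Surface metrics
# ---------------------------------------------------------------------------

def _structure(ndim: int, connectivity: int | None) -> np.ndarray:
    if connectivity is None:
        connectivity = 8 if ndim == 2 else 26
    try:
        rank = _CONNECTIVITY[(ndim, connectivity)]
    except KeyError:
        valid = sorted(c for d, c in _CONNECTIVITY if d == ndim)
        raise InputError(
            f"connectivity {connectivity} invalid for {ndim}-D masks; choose from {valid}"
        ) from None
    return ndimage.generate_binary_structure(ndim, rank)


def surface_extract(m: Mask, connectivity: int | None = None) -> SurfaceSet:
    """Surface voxels of a mask: members with >= 1 neighbour outside it.

    The neighbourhood is given by ``connectivity`` (8 for 2D; 18 or 26 for
    3D; defaults 8/26).  Voxels on the grid boundary are surface voxels,
    since outside the grid counts as outside the mask.
    """
    structure = _structure(m.ndim, connectivity)
    if connectivity is None:
        connectivity = 8 if m.ndim == 2 else 26
    eroded = ndimage.binary_erosion(m.grid, structure=structure, border_value=0)
    surface = m.grid & ~eroded
    coords = np.argwhere(surface)
    return SurfaceSet(coords=coords, connectivity=connectivity, spacing=m.spacing)


def surface_dice(a: Mask, b: Mask, connectivity: int | None = None) -> float:
    """Surface Dice similarity coefficient: Dice of the surface voxel sets."""
    sa = surface_extract(a, connectivity)
    sb = surface_extract(b, connectivity)
    if sa.size == 0 or sb.size == 0:
        raise UndefinedMetricError("surface_dice", "a mask has an empty surface")
    set_a = {tuple(c) for c in sa.coords}
    set_b = {tuple(c) for c in sb.coords}
    return 2 * len(set_a & set_b) / (sa.size + sb.size)


def _directed_distances(src: SurfaceSet, dst: SurfaceSet) -> np.ndarray:
    """d(x, Y) = min over dst surface of Euclidean distance, for each src voxel."""
    tree = cKDTree(dst.physical())
    dists, _ = tree.query(src.physical(), k=1)
    return np.atleast_1d(dists)


def asd(
    a: Mask,
    b: Mask,
    connectivity: int | None = None,
    literal_denominator: bool = False,
) -> float:
    """Average symmetric surface distance between the mask surfaces.

    Sums d(x, ∂Y) over x in ∂X and d(y, ∂X) over y in ∂Y and divides by
    |∂X| + |∂Y|.  ``literal_denominator=True`` divides by the full mask
    volumes |X| + |Y| instead (a reading occasionally seen in print, kept
    for comparability).
    """
    sa = surface_extract(a, connectivity)
    sb = surface_extract(b, connectivity)
    if sa.size == 0 or sb.size == 0:
        raise UndefinedMetricError("asd", "a mask has an empty surface")
    total = _directed_distances(sa, sb).sum() + _directed_distances(sb, sa).sum()
    den = (a.volume + b.volume) if literal_denominator else (sa.size + sb.size)
    return float(total / den)


def hausdorff(
    a: Mask,
    b: Mask,
    connectivity: int | None = None,
    symmetric: bool = True,
) -> float:
    """Hausdorff distance over surface voxels.

    Directed hd(X, Y) = max over x in ∂X of d(x, ∂Y); the symmetric form
    (maximum symmetric surface distance) is max(hd(X,Y), hd(Y,X)).
    """
    sa = surface_extract(a, connectivity)
    sb = surface_extract(b, connectivity)
    if sa.size == 0 or sb.size == 0:
        raise UndefinedMetricError("hausdorff", "a mask has an empty surface")
    forward = float(_directed_distances(sa, sb).max())
    if not symmetric:
        return forward
    backward = float(_directed_distances(sb, sa).max())
    return max(forward, backward)


# ---------------------------------------------------------------------------
# Structural similarity
# ---------------------------------------------------------------------------

def _ssim_window(u: np.ndarray, v: np.ndarray, c1: float, c2: float) -> float:
    mu, mv = u.mean(), v.mean()
    ddof = 1 if u.size > 1 else 0
    su2 = u.var(ddof=ddof)
    sv2 = v.var(ddof=ddof)
    suv = ((u - mu) * (v - mv)).sum() / max(u.size - 1, 1)
    lum = (2 * mu * mv + c1) / (mu**2 + mv**2 + c1)
    struct = (2 * suv + c2) / (su2 + sv2 + c2)
    return float(lum * struct)


def ssim(
    u,
    v,
    c1: float = 0.01,
    c2: float = 0.03,
    window: int | None = None,
) -> float:
    """Structural similarity index of two image matrices, in [-1, 1].

    Per window, SSIM = (2*mu_u*mu_v + c1)/(mu_u^2 + mu_v^2 + c1) *
    (2*s_uv + c2)/(s_u^2 + s_v^2 + c2), where s_u^2, s_v^2 are the sample
    variances and s_uv the sample covariance; 1 means perfect similarity,
    0 no association, -1 perfect opposition.  ``window=None`` evaluates a
    single whole-image window; an integer tiles the image with
    non-overlapping windows of that side length (partial edge tiles
    included) and returns the mean.  ``c1`` and ``c2`` are small positive
    stabilisers conventionally proportional to the squared dynamic range.
    """
    u_arr = np.asarray(u, dtype=np.float64)
    v_arr = np.asarray(v, dtype=np.float64)
    if u_arr.shape != v_arr.shape or u_arr.size == 0:
        raise InputError("images must be non-empty and identically shaped")
    if c1 <= 0 or c2 <= 0:
        raise InputError("c1 and c2 must be positive")
    if window is None:
        return _ssim_window(u_arr, v_arr, c1, c2)
    if window < 1:
        raise InputError("window must be a positive integer")
    vals = []
    shape = u_arr.shape
    for start in np.ndindex(*[max(1, -(-s // window)) for s in shape]):
        sl = tuple(
            slice(i * window, min((i + 1) * window, s)) for i, s in zip(start, shape)
        )
        vals.append(_ssim_window(u_arr[sl], v_arr[sl], c1, c2))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Semantic segmentation
# ---------------------------------------------------------------------------

def mean_class_dice(
    a: LabelMask, b: LabelMask, classes: list[int] | None = None
) -> tuple[dict[int, float], float]:
    """One-vs-rest Dice per class plus their unweighted mean.

    ``classes`` declares the class set (default: union of labels present).
    Classes absent from both masks are undefined and excluded from the
    mean; they appear in the returned dict with value ``nan`` so callers
    can see which classes were skipped.  Background label 0 is treated as
    a class like any other if present.
    """
    if a.grid.shape != b.grid.shape:
        raise InputError("label masks must share a shape")
    labels = (
        np.asarray(classes) if classes is not None else np.union1d(a.classes(), b.classes())
    )
    per_class: dict[int, float] = {}
    defined = []
    for lab in labels.tolist():
        try:
            d = dice(a.indicator(lab), b.indicator(lab))
        except UndefinedMetricError:
            per_class[int(lab)] = float("nan")
            continue
        per_class[int(lab)] = d
        defined.append(d)
    if not defined:
        raise UndefinedMetricError("mean_class_dice", "no class present in either mask")
    return per_class, float(np.mean(defined))
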