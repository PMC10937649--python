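"""Seed-deterministic synthetic data generators.

The generators emulate the study conditions of the embedded worked
examples: two classifiers scoring the same 600-instance balanced test set
(as in the binary chest X-ray experiment), 128x128 tumour masks with a
sparse foreground, and J x K matrices of paired metric values as produced
by repeated five-fold cross-validation (J = 25 rounds).  A shared latent
signal with per-model noise lets the score generator realise both the null
(equal models) and the alternative (one model separates classes better),
which is what the calibration and power checks of the statistical tests
need.

Every generator is a pure function of its config: same seed, same output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InputError
from .roc import ScoredPredictions
from .segmentation import Mask
from .stattests import MetricMatrix

__all__ = ["SynthConfig", "synth_scores", "synth_masks", "synth_paired_metrics"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic generators.

    Score generation: ``n`` instances with ``pos_fraction`` positives; each
    positive's latent signal is shifted by ``separation`` (1.5 gives an
    expected AUC near 0.85, matching the worked examples); each model sees
    the latent signal plus noise of scale ``noise_scale``, correlated
    between models with coefficient ``correlation`` (1 with equal
    separation means identical scores, i.e. an exact null).

    Mask generation: ``image_shape`` grids whose ground truth is a disk
    covering ``foreground_fraction`` of the image (sparse, as tumour masks
    are); the prediction is the same disk displaced by ``jitter`` pixels.

    Metric-matrix generation: ``n_datasets`` x ``n_models`` values, one
    shared per-dataset effect (sd ``dataset_sd``), per-model shifts
    ``model_effects`` (zeros = null), and residual noise ``noise_sd``.
    """

    seed: int = 0
    # scores
    n: int = 600
    pos_fraction: float = 0.5
    separation: float = 1.5
    separation2: float | None = None  # second model; None = same as first
    noise_scale: float = 1.0
    correlation: float = 0.5
    # masks
    image_shape: tuple[int, ...] = (128, 128)
    foreground_fraction: float = 0.013
    jitter: float = 1.0
    # paired metrics
    n_datasets: int = 25
    n_models: int = 2
    model_effects: tuple[float, ...] | None = None
    dataset_sd: float = 0.05
    noise_sd: float = 0.05


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def synth_scores(cfg: SynthConfig) -> tuple[ScoredPredictions, ScoredPredictions]:
    """Two models' scores over one shared set of binary labels.

    Model m's score is sigmoid(separation_m * y + shared + own noise),
    where the shared and own noise parts are mixed so that the noise terms
    of the two models have correlation ``cfg.correlation``.
    """
    if not 0 < cfg.pos_fraction < 1:
        raise InputError("pos_fraction must lie strictly between 0 and 1")
    if not 0.0 <= cfg.correlation <= 1.0:
        raise InputError("correlation must lie in [0, 1]")
    if cfg.n < 4:
        raise InputError("need at least 4 instances")
    rng = np.random.default_rng(cfg.seed)
    n_pos = max(1, min(cfg.n - 1, int(round(cfg.n * cfg.pos_fraction))))
    labels = np.zeros(cfg.n, dtype=np.int64)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    sep2 = cfg.separation if cfg.separation2 is None else cfg.separation2
    shared = rng.standard_normal(cfg.n)
    eps1 = rng.standard_normal(cfg.n)
    eps2 = rng.standard_normal(cfg.n)
    rho = cfg.correlation
    noise1 = cfg.noise_scale * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps1)
    noise2 = cfg.noise_scale * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps2)
    s1 = _sigmoid(cfg.separation * labels + noise1)
    s2 = _sigmoid(sep2 * labels + noise2)
    return (
        ScoredPredictions(scores=s1, labels=labels),
        ScoredPredictions(scores=s2, labels=labels),
    )


def synth_masks(cfg: SynthConfig, offset: tuple[float, ...] | None = None) -> tuple[Mask, Mask]:
    """Ground-truth and predicted masks: a disk and its jittered copy.

    The ground-truth foreground is a disk (sphere in 3D) centred in the
    grid covering ``foreground_fraction`` of it; the prediction is the same
    disk displaced by a random jitter of length ``cfg.jitter`` (an explicit
    ``offset`` overrides the random displacement, e.g. to force disjoint
    masks).  Jitter 0 and no offset reproduce the ground truth exactly.
    """
    if not 0.0 < cfg.foreground_fraction < 1.0:
        raise InputError("foreground_fraction must lie strictly between 0 and 1")
    shape = cfg.image_shape
    ndim = len(shape)
    if ndim not in (2, 3):
        raise InputError("image_shape must be 2-D or 3-D")
    rng = np.random.default_rng(cfg.seed)
    n_voxels = int(np.prod(shape))
    target = cfg.foreground_fraction * n_voxels
    if ndim == 2:
        radius = np.sqrt(target / np.pi)
    else:
        radius = (3.0 * target / (4.0 * np.pi)) ** (1.0 / 3.0)
    centre = np.array([s / 2.0 for s in shape])
    if offset is None:
        direction = rng.standard_normal(ndim)
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else np.zeros(ndim)
        offset_vec = cfg.jitter * direction
    else:
        offset_vec = np.asarray(offset, dtype=np.float64)
        if offset_vec.shape != (ndim,):
            raise InputError("offset length must match image dimensionality")
    grids = np.indices(shape).reshape(ndim, -1).T
    truth = (np.linalg.norm(grids - centre, axis=1) <= radius).reshape(shape)
    pred = (np.linalg.norm(grids - (centre + offset_vec), axis=1) <= radius).reshape(shape)
    return Mask(truth.astype(np.int8)), Mask(pred.astype(np.int8))


def synth_paired_metrics(cfg: SynthConfig) -> MetricMatrix:
    """J x K metric matrix: dataset effect + model effect + noise.

    ``model_effects`` of all zeros (the default) is the global null, under
    which Friedman's and the pairwise tests should reject at their nominal
    rate; a dominant entry creates an alternative whose mean rank tends to
    1 as the noise vanishes.
    """
    J, K = cfg.n_datasets, cfg.n_models
    if J < 2 or K < 2:
        raise InputError("need n_datasets >= 2 and n_models >= 2")
    effects = cfg.model_effects if cfg.model_effects is not None else (0.0,) * K
    if len(effects) != K:
        raise InputError("model_effects length must equal n_models")
    rng = np.random.default_rng(cfg.seed)
    dataset = rng.normal(0.0, cfg.dataset_sd, size=(J, 1))
    noise = rng.normal(0.0, cfg.noise_sd, size=(J, K))
    values = 0.5 + dataset + np.asarray(effects)[None, :] + noise
    return MetricMatrix(values)
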