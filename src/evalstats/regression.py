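"""Correlation and error metrics for real-valued predictions.

Pearson's r measures linear agreement between ground truth ``x`` and
predictions ``y``; Spearman's r_s is Pearson's r on the ranks (midranks
for ties) and is preferred when the values are far from normal.  MAE and
MSE are mean absolute and squared residuals; MSE penalises large
individual errors more heavily.

MAE/MSE are reported as means (divided by n) so values are comparable
across test-set sizes; pass ``mean=False`` for the raw residual sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError, UndefinedMetricError

__all__ = ["PairedRealVectors", "pearson_r", "spearman_r", "mae", "mse"]


@dataclass(frozen=True)
class PairedRealVectors:
    """Ground-truth values ``x`` paired with predictions ``y``."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        if x.shape != y.shape or x.ndim != 1 or x.size == 0:
            raise InputError("x and y must be 1-D, non-empty, equal length")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.size


def _require_nonconstant(v: PairedRealVectors, metric: str) -> None:
    if np.ptp(v.x) == 0 or np.ptp(v.y) == 0:
        raise UndefinedMetricError(metric, "a vector is constant (zero variance)")


def pearson_r(v: PairedRealVectors) -> float:
    """Pearson's correlation coefficient of x and y."""
    _require_nonconstant(v, "pearson_r")
    return float(stats.pearsonr(v.x, v.y).statistic)


def spearman_r(v: PairedRealVectors) -> float:
    """Spearman's rank correlation: Pearson's r of the midrank-transformed
    vectors (average ranks for ties)."""
    _require_nonconstant(v, "spearman_r")
    return float(stats.spearmanr(v.x, v.y).statistic)


def mae(v: PairedRealVectors, mean: bool = True) -> float:
    """Mean (or raw-sum, ``mean=False``) absolute error."""
    total = float(np.abs(v.x - v.y).sum())
    return total / v.n if mean else total


def mse(v: PairedRealVectors, mean: bool = True) -> float:
    """Mean (or raw-sum, ``mean=False``) squared error."""
    total = float(((v.x - v.y) ** 2).sum())
    return total / v.n if mean else total
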