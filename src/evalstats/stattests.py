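"""Paired statistical tests for comparing supervised models.

Values of an evaluation metric for two models are paired — they come from
the same instances or the same test folds — so the tests here are paired
tests: the paired t-test (means), the sign test (counts of wins), the
Wilcoxon signed-rank test (ranked differences; the recommended two-model
test), and Friedman's test with the Iman–Davenport correction for K models
over J data sets.  For binary classifiers on a single test set, McNemar's
test compares sensitivities or specificities from the discordant
misclassification counts, and the DeLong test compares two correlated AUCs
via the U-statistic structural components.  Variance comparisons use the
F-test, or Bartlett's/Levene's tests when normality (testable by
Shapiro–Wilk) is doubtful.

Unless a test is an inherently one-sided omnibus test (Friedman, the
chi-square branch of McNemar), p-values are two-sided in the convention
p = 2 * min(lower tail, upper tail), capped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import InputError, UndefinedMetricError

__all__ = [
    "PairedSamples",
    "MetricMatrix",
    "DiscordantPair",
    "TestResult",
    "paired_t_test",
    "sign_test",
    "wilcoxon_signed_rank",
    "friedman_test",
    "mcnemar_test",
    "delong_auc",
    "delong_test",
    "variance_f_test",
    "bartlett_test",
    "levene_test",
    "shapiro_wilk",
]

WILCOXON_EXACT_MAX_N = 25  # exact T distribution up to here, normal above
SIGN_NORMAL_MIN_N = 20  # normal approximation reported alongside from here
MCNEMAR_CHI2_MIN = 20  # chi-square branch for b + c >= 20, binomial below


@dataclass(frozen=True)
class PairedSamples:
    """Equal-length metric values for two models on the same instances."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=np.float64)
        b = np.asarray(self.b, dtype=np.float64)
        if a.shape != b.shape or a.ndim != 1 or a.size < 2:
            raise InputError("paired samples must be 1-D, equal length >= 2")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b


@dataclass(frozen=True)
class MetricMatrix:
    """J x K matrix of one metric: K models evaluated on J data sets."""

    values: np.ndarray
    model_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise InputError("metric matrix must be J x K with J >= 2, K >= 2")
        if not np.isfinite(v).all():
            raise InputError("metric matrix must have no missing cells")
        object.__setattr__(self, "values", v)
        if self.model_names is not None:
            names = tuple(self.model_names)
            if len(names) != v.shape[1]:
                raise InputError("model_names length must equal K")
            object.__setattr__(self, "model_names", names)

    @property
    def J(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class DiscordantPair:
    """Counts of instances misclassified by exactly one of two classifiers."""

    b: int
    c: int

    def __post_init__(self) -> None:
        if self.b < 0 or self.c < 0:
            raise InputError("discordant counts must be non-negative")
        if self.b + self.c < 1:
            raise InputError("McNemar's test needs b + c >= 1")


@dataclass(frozen=True)
class TestResult:
    """Statistic, reference distribution, and p-value of one test."""

    test: str
    statistic: float
    p_value: float
    distribution: str
    df: tuple[float, ...] = ()
    method: str = "asymptotic"  # "exact" or "asymptotic"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InputError(f"p-value {self.p_value} outside [0, 1]")


def _two_sided(cdf_val: float, sf_val: float) -> float:
    return float(min(1.0, 2.0 * min(cdf_val, sf_val)))


# ---------------------------------------------------------------------------
# Paired location tests
# ---------------------------------------------------------------------------

def paired_t_test(ps: PairedSamples) -> TestResult:
    """Paired t-test of zero mean difference; df = n - 1.

    Not valid on resampled (cross-validation) test sets, where fold
    overlap makes the variance estimate too small; see the advisor.
    """
    d = ps.differences
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        raise UndefinedMetricError("paired_t", "differences have zero variance")
    t = d.mean() / (sd / math.sqrt(n))
    p = _two_sided(stats.t.cdf(t, n - 1), stats.t.sf(t, n - 1))
    return TestResult("paired_t", float(t), p, "t", (n - 1,))


def sign_test(ps: PairedSamples) -> TestResult:
    """Exact sign test: under no difference each model wins N/2 times.

    Ties (zero differences) are dropped and N reduced.  The statistic is
    the number of positive differences, Binomial(N, 1/2) under the null;
    the exact two-sided p is always computed, and the normal approximation
    (mean N/2, sd sqrt(N)/2) is reported in ``extras`` for N >= 20.
    """
    d = ps.differences
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise UndefinedMetricError("sign_test", "all differences are ties")
    wins = int((d > 0).sum())
    dist = stats.binom(n, 0.5)
    p = _two_sided(dist.cdf(wins), dist.sf(wins - 1))
    extras: dict = {"n_after_ties": n, "wins": wins}
    if n >= SIGN_NORMAL_MIN_N:
        z = (wins - n / 2) / (math.sqrt(n) / 2)
        extras["z"] = float(z)
        extras["p_normal"] = _two_sided(stats.norm.cdf(z), stats.norm.sf(z))
    return TestResult(
        "sign", float(wins), p, "binomial", (n, 0.5), method="exact", extras=extras
    )


@lru_cache(maxsize=64)
def _signed_rank_null_counts(n: int) -> np.ndarray:
    """Counts of sign assignments giving each value of R+ for ranks 1..n."""
    max_sum = n * (n + 1) // 2
    counts = np.zeros(max_sum + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(ps: PairedSamples) -> TestResult:
    """Wilcoxon signed-rank test of zero median difference.

    Zero differences are discarded; absolute differences are ranked with
    midranks for ties; T = min(R+, R-).  For n <= 25 with untied ranks the
    exact null distribution of R+ (enumerated by dynamic programming) gives
    the p-value; otherwise the normal statistic
    z = (T - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24) is used.  ``extras`` always
    carries R+, R-, and z.
    """
    d = ps.differences
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise UndefinedMetricError("wilcoxon", "all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    r_plus = float(ranks[d > 0].sum())
    r_minus = float(ranks[d < 0].sum())
    t_stat = min(r_plus, r_minus)
    mean_t = n * (n + 1) / 4.0
    sd_t = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (t_stat - mean_t) / sd_t
    extras = {"r_plus": r_plus, "r_minus": r_minus, "z": float(z), "n_after_zeros": n}
    untied = np.unique(ranks).size == n
    if n <= WILCOXON_EXACT_MAX_N and untied:
        counts = _signed_rank_null_counts(n)
        total = counts.sum()
        rp = int(round(r_plus))
        p = _two_sided(counts[: rp + 1].sum() / total, counts[rp:].sum() / total)
        return TestResult(
            "wilcoxon", t_stat, p, "exact signed-rank", (n,), method="exact", extras=extras
        )
    p = _two_sided(stats.norm.cdf(z), stats.norm.sf(z))
    return TestResult("wilcoxon", t_stat, p, "normal", (), method="asymptotic", extras=extras)


def friedman_test(
    mm: MetricMatrix, statistic: Literal["iman_davenport", "chi2"] = "iman_davenport"
) -> TestResult:
    """Friedman's rank test for K models over J data sets.

    Within each data set (row) the models are ranked, rank 1 for the best
    (highest) metric value, midranks for ties.  The chi-square form is
    chi2_F = 12J/(K(K+1)) * (sum_k Rbar_k^2 - K(K+1)^2/4) with K-1 df; the
    Iman–Davenport form F_ID = (J-1) chi2_F / (J(K-1) - chi2_F) with
    (K-1, (K-1)(J-1)) df is the default, as the chi-square form is overly
    conservative.  One-sided upper-tail p (omnibus test).
    """
    J, K = mm.J, mm.K
    # rank 1 = best (highest) value within each row
    ranks = np.apply_along_axis(lambda r: stats.rankdata(-r), 1, mm.values)
    mean_ranks = ranks.mean(axis=0)
    chi2_f = 12.0 * J / (K * (K + 1)) * ((mean_ranks**2).sum() - K * (K + 1) ** 2 / 4.0)
    extras = {"mean_ranks": mean_ranks.tolist(), "chi2_f": float(chi2_f)}
    if statistic == "chi2":
        p = float(stats.chi2.sf(chi2_f, K - 1))
        return TestResult(
            "friedman", float(chi2_f), p, "chi2", (K - 1,), extras=extras
        )
    if statistic != "iman_davenport":
        raise InputError(f"statistic must be 'iman_davenport' or 'chi2', got {statistic!r}")
    den = J * (K - 1) - chi2_f
    if den <= 0:
        raise UndefinedMetricError(
            "friedman_f_id", "chi2_F equals J(K-1): all rows rank the models identically"
        )
    f_id = (J - 1) * chi2_f / den
    p = float(stats.f.sf(f_id, K - 1, (K - 1) * (J - 1)))
    extras["f_id"] = float(f_id)
    return TestResult(
        "friedman", float(f_id), p, "F", (K - 1, (K - 1) * (J - 1)), extras=extras
    )


# ---------------------------------------------------------------------------
# Single-test-set classifier tests
# ---------------------------------------------------------------------------

def mcnemar_test(dp: DiscordantPair) -> TestResult:
    """McNemar's test on discordant counts b and c.

    The continuity-corrected statistic (|b - c| - 1)^2 / (b + c) follows
    chi-square with 1 df for b + c >= 20; below that the exact two-sided
    binomial p = 2 P(X <= min(b, c)) with X ~ Binomial(b + c, 1/2) is used.
    The statistic is reported on both branches.
    """
    b, c = dp.b, dp.c
    n = b + c
    statistic = (abs(b - c) - 1) ** 2 / n
    extras = {"b": b, "c": c}
    if n >= MCNEMAR_CHI2_MIN:
        p = float(stats.chi2.sf(statistic, 1))
        return TestResult("mcnemar", float(statistic), p, "chi2", (1,), extras=extras)
    p = float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5)))
    return TestResult(
        "mcnemar", float(statistic), p, "binomial", (n, 0.5), method="exact", extras=extras
    )


def _psi_matrix(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Mann–Whitney kernel over all positive-negative pairs (m x n)."""
    diff = pos[:, None] - neg[None, :]
    return np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))


def delong_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC estimate and its structural components.

    Returns (theta_hat, V10, V01): theta is the Mann–Whitney estimate; for
    each positive instance i, V10[i] is the mean kernel value over all
    negatives, and for each negative j, V01[j] the mean over all positives.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise InputError("scores and labels must be 1-D and equal length")
    if not np.isin(y, (0, 1)).all():
        raise InputError("labels must be 0 or 1")
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedMetricError("delong_auc", "both classes must be present")
    psi = _psi_matrix(pos, neg)
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def delong_test(scores1, scores2, labels) -> TestResult:
    """DeLong test for a difference between two correlated AUCs.

    Both classifiers score the same instances, so their AUC estimates are
    correlated; variances and the covariance come from the empirical
    covariance of the structural components (S10 over positives, S01 over
    negatives): Var = S10/m + S01/n.  Z_D = (theta1 - theta2) / sqrt(Var1 +
    Var2 - 2 Cov) is standard normal under the null of equal AUCs.
    """
    s1 = np.asarray(scores1, dtype=np.float64)
    s2 = np.asarray(scores2, dtype=np.float64)
    if np.array_equal(s1, s2):
        raise UndefinedMetricError(
            "delong_z", "the two score vectors are identical: covariance equals "
            "variance and the pooled variance of the difference is zero"
        )
    theta1, v10_1, v01_1 = delong_auc(s1, labels)
    theta2, v10_2, v01_2 = delong_auc(s2, labels)
    m = v10_1.size
    n = v01_1.size
    if m < 2 or n < 2:
        raise InputError("DeLong test needs at least two instances per class")
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    var1 = s10[0, 0] / m + s01[0, 0] / n
    var2 = s10[1, 1] / m + s01[1, 1] / n
    cov = s10[0, 1] / m + s01[0, 1] / n
    denom = var1 + var2 - 2 * cov
    extras = {"theta1": theta1, "theta2": theta2, "var1": var1, "var2": var2, "cov": cov}
    if denom <= 0:
        if theta1 == theta2:
            # equal AUC estimates whose difference shows no spread at all:
            # no evidence of a difference, Z pinned to 0
            return TestResult("delong", 0.0, 1.0, "normal", (), extras=extras)
        raise UndefinedMetricError(
            "delong_z", "pooled variance of the AUC difference is not positive"
        )
    z = (theta1 - theta2) / math.sqrt(denom)
    p = _two_sided(stats.norm.cdf(z), stats.norm.sf(z))
    return TestResult("delong", float(z), p, "normal", (), extras=extras)


# ---------------------------------------------------------------------------
# Variance and normality tests
# ---------------------------------------------------------------------------

def variance_f_test(x, y) -> TestResult:
    """F-test of equal variances: F = S1^2 / S2^2, F(n1-1, n2-1) reference.

    Two-sided p = 2 min(lower tail, upper tail).  Sensitive to
    non-normality; prefer Bartlett's or Levene's test for skewed metrics.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise InputError("each sample needs at least two values")
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    if v1 == 0 or v2 == 0:
        raise UndefinedMetricError("f_test", "a sample has zero variance")
    f = v1 / v2
    d1, d2 = x.size - 1, y.size - 1
    p = _two_sided(stats.f.cdf(f, d1, d2), stats.f.sf(f, d1, d2))
    return TestResult("variance_f", float(f), p, "F", (d1, d2))


def bartlett_test(groups: Sequence) -> TestResult:
    """Bartlett's test of equal variances across >= 2 groups (delegated)."""
    if len(groups) < 2:
        raise InputError("need at least two groups")
    stat, p = stats.bartlett(*[np.asarray(g, dtype=np.float64) for g in groups])
    return TestResult("bartlett", float(stat), float(p), "chi2", (len(groups) - 1,))


def levene_test(groups: Sequence, center: str = "mean") -> TestResult:
    """Levene's test of equal variances, group-mean centering by default
    (``center`` may also be "median" or "trimmed"); robust to
    non-normality (delegated)."""
    if len(groups) < 2:
        raise InputError("need at least two groups")
    stat, p = stats.levene(*[np.asarray(g, dtype=np.float64) for g in groups], center=center)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return TestResult("levene", float(stat), float(p), "F", (k - 1, n - k))


def shapiro_wilk(x) -> TestResult:
    """Shapiro–Wilk normality test (delegated); gate for the variance tests."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise InputError("Shapiro-Wilk needs n >= 3")
    stat, p = stats.shapiro(x)
    return TestResult("shapiro_wilk", float(stat), float(p), "shapiro_w", ())
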