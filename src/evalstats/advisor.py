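"""Test-selection advisor and resampling plans.

Which statistical test fits a model comparison depends on the task, the
metric, how many models are compared, and whether the evidence is the raw
predictions of a single test set or metric values collected over several
test sets.  The advisor encodes that decision flow as an ordered *rule
table* — data, not code branches — so the full rule set can be printed,
audited, and tested exhaustively.  Each rule carries a rationale and
caveats (e.g. that resampled test sets are not independent, or that the
paired t-test is invalid on them).

The fold-plan helpers generate the resampling schemes that produce paired
metric values: k-fold cross-validation, repeated k-fold, and group-wise
splits that never let one group (e.g. one patient's images) span train and
test.  One plan is shared by all models on the same round.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InputError

__all__ = [
    "Scenario",
    "Recommendation",
    "FoldPlan",
    "RULES",
    "advise",
    "rule_table",
    "kfold_plan",
    "repeated_kfold_plan",
    "group_split_plan",
]

TASKS = (
    "binary_classification",
    "multiclass_classification",
    "multilabel_classification",
    "regression",
    "segmentation",
    "detection",
    "retrieval",
)
EVIDENCE = ("single_test_set", "metric_values")
QUESTIONS = ("performance", "variance")
NORMALITY = ("normal", "non_normal", "unknown")

RESAMPLING_CAVEAT = (
    "resampled test sets are not independent; the variance of the test "
    "statistic is underestimated, so interpret borderline p-values cautiously"
)
T_TEST_CAVEAT = (
    "the paired t-test is sensitive to outliers and not valid on resampled "
    "test sets; it is never the primary recommendation here"
)


@dataclass(frozen=True)
class Scenario:
    """One model-comparison situation, with every field a closed enumeration."""

    task: str
    metric: str
    n_models: int
    evidence: str  # "single_test_set" predictions or "metric_values" over test sets
    question: str = "performance"
    normality: str = "unknown"
    n_test_sets: int = 1

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise InputError(f"unknown task {self.task!r}; choose from {TASKS}")
        if self.evidence not in EVIDENCE:
            raise InputError(f"evidence must be one of {EVIDENCE}")
        if self.question not in QUESTIONS:
            raise InputError(f"question must be one of {QUESTIONS}")
        if self.normality not in NORMALITY:
            raise InputError(f"normality must be one of {NORMALITY}")
        if self.n_models < 2:
            raise InputError("comparison needs at least two models")
        if self.evidence == "metric_values" and self.n_test_sets < 2:
            raise InputError("metric-values evidence needs n_test_sets >= 2")
        if self.metric == "auc" and self.evidence == "single_test_set" and self.task != "binary_classification":
            raise InputError("single-test-set AUC comparison applies to binary classification")


@dataclass(frozen=True)
class Recommendation:
    """A recommended test with its rationale and caveats."""

    test: str
    rationale: str
    caveats: tuple[str, ...] = ()
    source: str = "body"  # "body" for rules stated in prose, "inferred" for flowchart placement


@dataclass(frozen=True)
class Rule:
    """One row of the advisor's rule table.

    ``matches`` maps Scenario field names to an allowed value or tuple of
    values; a missing field matches anything.  ``n_models`` matches "2" or
    ">2"; ``n_test_sets`` matches "small" (< 5) or "large" (>= 5).
    """

    name: str
    matches: dict
    test: str
    rationale: str
    caveats: tuple[str, ...] = ()
    source: str = "body"
    refuse: str | None = None  # if set, the rule rejects with this explanation

    def applies(self, s: Scenario) -> bool:
        for key, allowed in self.matches.items():
            if key == "n_models":
                value = "2" if s.n_models == 2 else ">2"
            elif key == "n_test_sets":
                value = "small" if s.n_test_sets < 5 else "large"
            else:
                value = getattr(s, key)
            allowed_t = allowed if isinstance(allowed, tuple) else (allowed,)
            if value not in allowed_t:
                return False
        return True


RULES: tuple[Rule, ...] = (
    # --- variance question -------------------------------------------------
    Rule(
        name="variance_normal",
        matches={"question": "variance", "normality": "normal"},
        test="variance_f",
        rationale="for normally distributed metric values, the F-test compares variances directly",
        caveats=(RESAMPLING_CAVEAT,),
    ),
    Rule(
        name="variance_non_normal",
        matches={"question": "variance", "normality": "non_normal"},
        test="levene",
        rationale=(
            "the F-test is unreliable for non-normal values; Levene's test "
            "(or Bartlett's) is the robust alternative"
        ),
        caveats=("Bartlett's test is the other named alternative", RESAMPLING_CAVEAT),
    ),
    Rule(
        name="variance_gate",
        matches={"question": "variance", "normality": "unknown"},
        test="shapiro_wilk",
        rationale=(
            "test normality first with Shapiro-Wilk, then use the F-test if "
            "normal and Levene's/Bartlett's test otherwise"
        ),
        source="inferred",
    ),
    # --- performance, single test set, binary classification ---------------
    Rule(
        name="binary_auc_single",
        matches={
            "question": "performance",
            "evidence": "single_test_set",
            "task": "binary_classification",
            "metric": "auc",
            "n_models": "2",
        },
        test="delong",
        rationale="the DeLong test compares two correlated AUCs from the same instances",
    ),
    Rule(
        name="binary_sen_spe_single",
        matches={
            "question": "performance",
            "evidence": "single_test_set",
            "task": "binary_classification",
            "metric": ("sensitivity", "specificity"),
            "n_models": "2",
        },
        test="mcnemar",
        rationale=(
            "McNemar's test compares sensitivity or specificity of two "
            "classifiers from the discordant misclassifications of one test set"
        ),
    ),
    Rule(
        name="binary_accuracy_single_refused",
        matches={
            "question": "performance",
            "evidence": "single_test_set",
            "task": "binary_classification",
            "metric": "accuracy",
            "n_models": "2",
        },
        test="mcnemar",
        rationale="",
        refuse=(
            "comparing accuracy by counting errors pooled over positive and "
            "negative instances is not recommended; test sensitivity and "
            "specificity separately with McNemar's test"
        ),
    ),
    # --- performance, single test set, per-instance metric values ----------
    Rule(
        name="segmentation_single",
        matches={
            "question": "performance",
            "evidence": "single_test_set",
            "task": "segmentation",
            "n_models": "2",
        },
        test="wilcoxon",
        rationale=(
            "segmentation yields one Dice/IoU value per image, so a single "
            "test set already gives paired values for the Wilcoxon signed-rank test"
        ),
    ),
    Rule(
        name="regression_single",
        matches={
            "question": "performance",
            "evidence": "single_test_set",
            "task": "regression",
            "n_models": "2",
        },
        test="wilcoxon",
        rationale=(
            "per-instance squared (or absolute) errors can be tested instead "
            "of their mean, giving paired values within one test set"
        ),
        source="inferred",
    ),
    # --- performance, metric values over several test sets -----------------
    Rule(
        name="two_models_metric_values",
        matches={
            "question": "performance",
            "evidence": "metric_values",
            "n_models": "2",
        },
        test="wilcoxon",
        rationale=(
            "the Wilcoxon signed-rank test is the best paired two-model test: "
            "non-parametric and robust to outliers, unlike the paired t-test"
        ),
        caveats=(T_TEST_CAVEAT, RESAMPLING_CAVEAT),
    ),
    Rule(
        name="many_models_many_sets",
        matches={
            "question": "performance",
            "evidence": "metric_values",
            "n_models": ">2",
            "n_test_sets": "large",
        },
        test="friedman",
        rationale=(
            "for K models over J data sets, Friedman's test (Iman-Davenport "
            "form) avoids the inflated type-I error of repeated pairwise tests"
        ),
        caveats=("use the F_ID statistic; chi2_F is overly conservative", RESAMPLING_CAVEAT),
    ),
    Rule(
        name="many_models_few_sets",
        matches={
            "question": "performance",
            "evidence": "metric_values",
            "n_models": ">2",
            "n_test_sets": "small",
        },
        test="wilcoxon",
        rationale=(
            "with few test sets Friedman's test is unreliable; use a few "
            "separate pairwise Wilcoxon signed-rank tests instead"
        ),
        caveats=("multiple comparisons inflate type-I error", RESAMPLING_CAVEAT),
    ),
    # --- fallbacks: single test set, one-value-per-set metrics -------------
    Rule(
        name="single_set_needs_resampling",
        matches={"question": "performance", "evidence": "single_test_set"},
        test="wilcoxon",
        rationale=(
            "this metric yields one value per test set; create several test "
            "sets by (repeated) cross-validation, then compare the paired "
            "values with the Wilcoxon signed-rank test (or Friedman's test "
            "for more than two models)"
        ),
        caveats=(RESAMPLING_CAVEAT, T_TEST_CAVEAT),
        source="inferred",
    ),
)


def advise(s: Scenario) -> Recommendation:
    """First matching rule of the table wins; refusal rules raise.

    The table is ordered from specific to general and ends in a resampling
    fallback, so every valid scenario receives a recommendation.
    """
    for rule in RULES:
        if rule.applies(s):
            if rule.refuse is not None:
                raise InputError(rule.refuse)
            return Recommendation(
                test=rule.test,
                rationale=rule.rationale,
                caveats=rule.caveats,
                source=rule.source,
            )
    raise InputError(f"no rule covers scenario {s!r}")  # unreachable by construction


def rule_table() -> list[dict]:
    """The full rule table as printable records (for audit)."""
    return [
        {
            "name": r.name,
            "matches": r.matches,
            "test": r.test,
            "refuses": r.refuse is not None,
            "source": r.source,
        }
        for r in RULES
    ]


# ---------------------------------------------------------------------------
# Resampling plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """Train/test index pairs per round, with the scheme and seed that made them."""

    rounds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    scheme: str
    seed: int

    def __len__(self) -> int:
        return len(self.rounds)


def kfold_plan(n: int, k: int, seed: int) -> FoldPlan:
    """k-fold cross-validation: folds sized within one of each other, each
    index in the test set exactly once.  Same seed, same plan."""
    if not 2 <= k <= n:
        raise InputError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    rounds = []
    for i, fold in enumerate(folds):
        test = tuple(int(x) for x in np.sort(fold))
        train = tuple(
            int(x) for x in np.sort(np.concatenate([f for j, f in enumerate(folds) if j != i]))
        )
        rounds.append((train, test))
    return FoldPlan(rounds=tuple(rounds), scheme=f"{k}-fold", seed=seed)


def repeated_kfold_plan(n: int, k: int, repeats: int, seed: int) -> FoldPlan:
    """Repeated k-fold: ``repeats`` independent k-fold shuffles, k * repeats
    rounds in total (each index tested once per repetition)."""
    if repeats < 1:
        raise InputError("repeats must be >= 1")
    rounds: list = []
    for rep in range(repeats):
        sub = kfold_plan(n, k, seed + rep)  # derived per-repeat seed
        rounds.extend(sub.rounds)
    return FoldPlan(rounds=tuple(rounds), scheme=f"{repeats}x{k}-fold", seed=seed)


def group_split_plan(group_ids: Sequence, test_fraction: float, seed: int) -> FoldPlan:
    """Single group-wise train/test split: no group spans both sides.

    Picks the subset of groups whose total size gives the realized test
    fraction closest to the request (exhaustively for up to 16 groups,
    greedily in shuffled order beyond that).  Ties break toward fewer test
    groups, then lexicographically, so the plan is seed-deterministic.
    """
    ids = np.asarray(group_ids)
    if ids.ndim != 1 or ids.size == 0:
        raise InputError("group_ids must be a non-empty 1-D sequence")
    if not 0.0 < test_fraction < 1.0:
        raise InputError("test_fraction must lie strictly between 0 and 1")
    uniq, inverse = np.unique(ids, return_inverse=True)
    g = uniq.size
    if g < 2:
        raise InputError("need at least two groups to split group-wise")
    sizes = np.bincount(inverse)
    n = ids.size
    if g <= 16:
        best = None
        for r in range(1, g):
            for combo in itertools.combinations(range(g), r):
                frac = sizes[list(combo)].sum() / n
                key = (abs(frac - test_fraction), r, combo)
                if best is None or key < best[0]:
                    best = (key, combo)
        test_groups = set(best[1])
    else:
        rng = np.random.default_rng(seed)
        order = rng.permutation(g)
        test_groups = set()
        total = 0
        for gi in order:
            cand = total + sizes[gi]
            if abs(cand / n - test_fraction) <= abs(total / n - test_fraction):
                test_groups.add(int(gi))
                total = cand
        if not test_groups:
            test_groups = {int(order[0])}
        if len(test_groups) == g:
            test_groups.discard(int(order[-1]))
    test_mask = np.isin(inverse, list(test_groups))
    test = tuple(int(i) for i in np.flatnonzero(test_mask))
    train = tuple(int(i) for i in np.flatnonzero(~test_mask))
    return FoldPlan(rounds=((train, test),), scheme="group-split", seed=seed)
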