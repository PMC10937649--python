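# Methods

`evalstats` implements the catalogue of evaluation metrics used for the
common supervised learning tasks — classification (binary, multi-class,
multi-label), regression, image segmentation, object detection, and ranked
retrieval — together with the paired statistical tests used to decide
whether two or more models genuinely differ on such a metric. This note
records the models and conventions the package commits to, the parameters
that matter, what the synthetic-data generators do and do not emulate, and
the numerical choices made where the underlying definitions are ambiguous.

## Metric definitions and conventions

**Confusion-matrix orientation.** All k×k confusion matrices are stored
with rows = true class and columns = predicted class. Printed matrices in
the other orientation are transposed at ingest via an explicit
`orientation` flag (and the TSV format records the orientation in its
header), so the convention can never silently flip.

**Undefined metrics.** A ratio with a zero denominator (no positives in
the test set, an empty class, zero variance) raises a typed
`UndefinedMetricError` naming the metric and, inside micro/macro
aggregation, the class that failed. Returning 0 or 1 would silently encode
a convention that differs across libraries.

**Binary metrics.** Accuracy, sensitivity (= recall), specificity,
precision, Youden's index (sen + spe − 1), and F1 (harmonic mean of
precision and recall) are computed exactly from the counts. Cohen's κ uses
the marginal-product chance agreement
p_e = ((TP+FN)(TP+FP) + (TN+FP)(TN+FN)) / n²; MCC is
(TN·TP − FN·FP) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

**Micro vs macro averaging.** Each class i of a k×k matrix yields a
one-vs-rest 2×2 matrix (TP_i = n_ii, FN_i = rest of row, FP_i = rest of
column, TN_i = remainder). Macro-averaging means the k per-class metric
values; micro-averaging evaluates the metric once on the summed counts.
Because ΣFP = ΣFN for any square confusion matrix, micro-precision,
micro-recall and micro-F1 always coincide; with equal class sizes micro and
macro also coincide for accuracy, sensitivity, specificity and Youden's
index. Multi-label data are evaluated by flattening the k label columns to
per-label binary confusions and reusing the binary machinery; the Hamming
loss is the mean elementwise disagreement.

**Known κ discrepancy.** The embedded four-class worked example's source
reports κ = 0.598, but the multi-class κ formula applied to the printed
matrix gives p₀ = 389/560 and p_e = 1/4 exactly (all row sums are 140),
hence κ ≈ 0.593. The formula value is what the package computes; the
rounded published figure is not asserted anywhere.

**Scores and ROC.** The decision rule is score ≥ threshold → positive.
The empirical ROC curve has one point per distinct score (ties merged into
a single point, producing a diagonal segment) plus the (0,0) and (1,1)
sentinels; with that convention the trapezoidal area equals the
Mann–Whitney estimator θ̂ = mean over positive–negative pairs of
Ψ (1 if the positive scores higher, ½ if tied, 0 otherwise) exactly, ties
or not. Threshold selection evaluates Youden's index or accuracy at
midpoints between consecutive distinct *training* scores (plus sentinels
outside the score range), breaking criterion ties toward the smallest
threshold; test-role inputs are refused because tuning the cut-point on
test predictions biases every threshold-level metric upward.

**Cross-entropy.** `cross_entropy` is the positive-label-only sum
−Σ p_i ln q_i, exactly as commonly printed for binary labels; the full
two-term binary cross-entropy is available separately as
`binary_cross_entropy`. Natural logarithm throughout.

**Regression.** Pearson's r and Spearman's r_s (midranks for ties) are
delegated to scipy behind the module surface. MAE/MSE are divided by n —
"mean" semantics, comparable across test-set sizes — with `mean=False`
giving the raw residual sums for strict formula fidelity.

**Segmentation.** Overlap metrics treat the first mask as ground truth.
Dice and IoU are computed in both the set form and the count form (tested
to be identical); SVD = 1 − Dice and VOE = 1 − IoU. A surface voxel is a
mask voxel with at least one neighbour outside the mask under the chosen
connectivity (2D: 8, default; 3D: 18 or 26, default 26); the grid boundary
counts as outside. Surface Dice is literal voxel-set Dice of the two
surfaces (not a distance-tolerance overlap). ASD sums the directed
nearest-surface Euclidean distances both ways and divides by |∂X| + |∂Y|,
the internally consistent denominator; the variant dividing by the mask
volumes |X| + |Y|, occasionally seen in print, is available behind
`literal_denominator=True`. The Hausdorff distance is the directed (or
symmetric maximum) of nearest-surface distances over surface voxels.
Spacing is isotropic 1 by default; an anisotropic spacing vector scales
each axis inside the Euclidean distance.

**SSIM.** Computed per window as
[(2·ū·v̄ + c₁)/(ū² + v̄² + c₁)] · [(2·s_uv + c₂)/(s_u² + s_v² + c₂)]
with sample variances/covariance (ddof = 1); this is the standard two-factor
form in which the structure factor uses the *covariance*, which is what
makes −1 attainable for opposed zero-mean images. The default is a single
whole-image window; an integer `window` tiles the image with
non-overlapping windows (partial edge tiles included) and returns the mean.
c₁ = 0.01 and c₂ = 0.03 by default, the usual small stabilisers for
unit-dynamic-range images; both are configurable and must be positive.

**Detection.** Boxes are closed real-coordinate rectangles with area
(x_max−x_min)(y_max−y_min) — no pixel "+1" convention. Matching is
class-partitioned and greedy in decreasing confidence; each prediction may
claim the unmatched same-class ground truth with the highest IoU at or
above the threshold, exact IoU ties breaking toward the earlier-listed
ground truth. AP integrates the precision envelope (every-point
interpolation: p(r) = max precision at recall ≥ r), removing the sawtooth
ambiguity of the raw curve; the raw trapezoid is available behind
`method="trapezoid"`. mAP averages per-class APs (classes with no ground
truth anywhere are excluded), and mAP@[0.5:0.95] averages over IoU
thresholds 0.5, 0.55, …, 0.95.

**Retrieval.** P@k and AP follow the printed formulas, with
`total_relevant` allowing relevant documents the list never retrieved.
DCG discounts gain G(i) by log₂(i+1); the conventional grade gains
perfect/excellent/good/fair/bad → 10 / 7 / 3 / 0.5 / 0 are the default
mapping for named grades.

## Statistical tests

All tests return a `TestResult` with the statistic, reference distribution
and degrees of freedom, a two-sided p-value in the convention
p = 2·min(lower tail, upper tail) capped at 1, and a method tag (exact vs
asymptotic). The omnibus tests (Friedman, the χ² branch of McNemar) use
the upper tail, as their statistics are one-sided by construction.

- **Paired t**: t = d̄/(s_d/√n), df n−1. Valid only for roughly normal,
  non-resampled differences; the advisor never recommends it as primary.
- **Sign test**: ties dropped, exact Binomial(N, ½) p always computed, the
  normal approximation (mean N/2, sd √N/2) reported alongside for N ≥ 20.
- **Wilcoxon signed-rank**: zero differences discarded, midranks for tied
  |d|, T = min(R⁺, R⁻). For n ≤ 25 with untied ranks the p-value comes
  from the exact null distribution of R⁺ (dynamic-programming enumeration
  of all 2ⁿ sign assignments); otherwise from
  z = (T − n(n+1)/4)/√(n(n+1)(2n+1)/24). The cutoff 25 keeps the exact
  branch cheap while the normal approximation is already accurate.
- **Friedman**: within-row ranks, rank 1 for the *best* (highest) value,
  midranks for ties. χ²_F = 12J/(K(K+1))·(ΣR̄_k² − K(K+1)²/4) with K−1 df;
  the Iman–Davenport F_ID = (J−1)χ²_F/(J(K−1) − χ²_F) with
  (K−1, (K−1)(J−1)) df is the default and recommended form, since χ²_F is
  overly conservative. Identical rankings in every row make F_ID's
  denominator vanish; that degenerate case is signalled.
- **McNemar**: continuity-corrected statistic (|b−c|−1)²/(b+c), χ²₁
  reference for b+c ≥ 20, exact two-sided binomial p = 2·P(X ≤ min(b,c))
  below; the statistic is reported on both branches.
- **DeLong**: AUCs via the Mann–Whitney kernel; variances and the
  covariance of the two correlated AUCs from the empirical covariance of
  the structural components (per-positive means V10 over negatives,
  per-negative means V01 over positives): Var(θ̂) = S10/m + S01/n.
  Z_D = (θ̂₁−θ̂₂)/√(Var₁+Var₂−2Cov) is standard normal under the null;
  the construction is validated by Monte-Carlo calibration (2000 null
  replicates: Z mean ≈ 0, sd ≈ 1, 5% rejection) and a hand-enumerated
  example. Identical score vectors are refused; equal AUC estimates whose
  difference has zero estimated spread return Z = 0, p = 1.
- **Variance tests**: the F-test (two-sided via 2·min of the tails) is
  exact under normality but fragile otherwise; Bartlett's and Levene's
  tests (group-mean centering by default) and the Shapiro–Wilk normality
  gate are delegated to scipy's vetted routines behind the module surface.

## Advisor and resampling

The decision flow from comparison scenario to test is a *rule table* —
ordered data, not code branches — so it can be printed, audited, and tested
exhaustively; each rule carries a rationale, caveats, and a source tag
(`body` for rules stated in prose in the methodological literature the
toolkit follows, `inferred` for placements the table needs to be total).
Notable rules: McNemar for single-test-set sensitivity/specificity of two
classifiers, DeLong for single-test-set AUC, refusal (with explanation) of
pooled-error accuracy comparison on a single test set, Wilcoxon for any
two-model comparison on paired metric values, Friedman (F_ID) for K > 2
models over J ≥ 5 test sets with a pairwise-Wilcoxon fallback for smaller
J, and the Shapiro–Wilk → F-test / Levene chain for variance questions.
The paired t-test and F-test remain invokable but are never the primary
recommendation for non-normal or resampled settings; every
metric-values-regime recommendation carries the caveat that resampled test
sets are not independent and bias the variance downward.

Fold plans: k-fold (fold sizes within one, each index tested exactly once),
repeated k-fold (per-repeat derived seeds), and group-wise splits that
never let a group span train and test, choosing the group subset whose
realized test fraction is closest to the request (exhaustive for ≤ 16
groups, greedy beyond). One plan is meant to be shared by all models on a
round. All plans are pure functions of (sizes, seed).

## Synthetic data: what it emulates and what it does not

`synth_scores` emulates two classifiers scoring one shared balanced test
set of n = 600 (the size of the embedded binary worked example): a latent
class signal with separation 1.5 (expected AUC ≈ 0.85, near the worked
examples' AUCs) plus per-model Gaussian noise correlated at 0.5 between
models, squashed through a sigmoid. Correlation 1 with equal separations
gives an exact null of identical scores. `synth_masks` emulates sparse
tumour masks: a centred disk covering 1.3% of a 128×128 grid (the
foreground fraction of the embedded mask example) whose prediction is the
same disk displaced by a jitter of 1 pixel. `synth_paired_metrics`
emulates the 25 paired metric values produced by repeated five-fold
cross-validation: dataset effect (sd 0.05) + model effects (zeros = null)
+ noise (sd 0.05).

What these generators do **not** emulate: real score distributions are not
sigmoid-Gaussian and real per-fold metric values are *not independent*
(fold overlap correlates them — exactly the caveat the advisor attaches),
masks are not disks, and class balance in the wild is rarely 50/50.
Passing calibration tests on this synthetic null therefore shows the tests
are implemented correctly and attain their nominal level under their own
assumptions; it does not show those assumptions hold for any particular
real evaluation.

## Problem sizes and runtime choices

The worked-example checks are desk-scale (600- and 560-instance confusion
matrices, one 128×128 mask pair) and run in milliseconds. Property checks
use 1000 random confusion matrices / mask pairs and 500 random score sets.
Type-I calibration uses 2000 null replicates per test with J = 25 paired
values (the repeated five-fold CV condition) and, for McNemar, 600-instance
score pairs; DeLong calibration uses 2000 replicates of 60 instances.
The exact Wilcoxon null distribution is cached per n, so the calibration
loop stays inexpensive.

## Limitations

- Surface metrics assume voxelised surfaces; no sub-voxel surface meshes,
  no 95th-percentile Hausdorff, no distance-tolerance surface Dice.
- No probability-calibration metrics (Brier, ECE), no weighted class
  averaging, no partial AUC or ROC confidence bands, no post-hoc
  Nemenyi/Holm procedures after Friedman, and no corrected resampled
  t-test variants.
- Detection ingestion is CSV only (no COCO JSON), boxes are axis-aligned,
  and non-maximum suppression is assumed to have happened upstream.
- The fixtures' mask geometry is synthetic (only the pixel counts of the
  published example are known); every metric asserted on it depends only
  on those counts.
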