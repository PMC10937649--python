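# evalstats

Evaluation metrics and paired statistical tests for supervised machine
learning, written for researchers — particularly in medical imaging — who
need to go beyond "model A's number is bigger than model B's" and say
whether a difference in accuracy, AUC, Dice, or mAP is statistically real.

The package provides, as plain Python functions over numpy arrays:

- **Classification metrics** from confusion matrices: accuracy,
  sensitivity/recall, specificity, precision, Youden's index J = Sen + Spe − 1,
  F1, Cohen's κ = (p₀ − p_e)/(1 − p_e), and Matthews' correlation, in
  binary, multi-class (micro/macro averaged) and multi-label (Hamming loss)
  form.
- **Score-based evaluation**: ROC curves, AUC both as trapezoidal area and
  as the Mann–Whitney statistic θ̂ = (mn)⁻¹ ΣΣ Ψ(Y_i1, Y_j0), training-set
  threshold selection, and cross-entropy loss.
- **Regression metrics**: Pearson's r, Spearman's r_s, MAE, MSE.
- **Segmentation metrics** for 2D/3D masks: Dice D = 2|X∩Y|/(|X|+|Y|),
  IoU = D/(2−D), surface Dice, average symmetric surface distance,
  Hausdorff distance, SVD/VOE error complements, SSIM, per-class mean Dice.
- **Detection and retrieval**: IoU box matching, precision–recall curves,
  AP/mAP@τ/mAP@[0.5:0.95], P@k, average precision, DCG.
- **Paired statistical tests**, each returning statistic, reference
  distribution, and p-value: paired t, sign, Wilcoxon signed-rank
  (T = min(R⁺, R⁻), exact or normal z), Friedman's χ²_F with the
  Iman–Davenport F_ID correction, McNemar's (|b−c|−1)²/(b+c), the DeLong
  test for two correlated AUCs, and F/Bartlett/Levene variance tests with a
  Shapiro–Wilk normality gate.
- An **advisor** that maps a comparison scenario (task, metric, number of
  models, evidence regime) to the appropriate test via an auditable rule
  table, plus k-fold / repeated k-fold / group-wise resampling plans.

Embedded fixtures reproduce published worked examples (chest X-ray
classification and PET tumour segmentation), so everything is runnable and
checkable without any dataset or trained model.

## Worked example

Evaluate a binary classifier's confusion matrix (261 TP, 193 TN, 107 FP,
39 FN — a COVID-19 X-ray classifier on 300 positive and 300 negative
images) and compare two classifiers' sensitivity with McNemar's test:

```python
>>> from evalstats import BinaryConfusion, binary_metrics, cohen_kappa_binary
>>> from evalstats import DiscordantPair, mcnemar_test
>>> cm = BinaryConfusion(tp=261, tn=193, fp=107, fn=39)
>>> r = binary_metrics(cm)
>>> round(r.accuracy, 3), round(r.sensitivity, 3), round(r.f1, 3)
(0.757, 0.87, 0.781)
>>> round(cohen_kappa_binary(cm), 3)
0.513
>>> t = mcnemar_test(DiscordantPair(b=54, c=19))  # discordant positives
>>> round(t.statistic, 3), t.distribution, round(t.p_value, 6)
(15.836, 'chi2', 6.9e-05)
```

The classifier gets 75.7% of images right and finds 87% of the positives;
κ = 0.513 says agreement is well above chance but far from perfect. The
McNemar statistic 15.836 on 1 df (p ≈ 7·10⁻⁵) means the first classifier's
sensitivity advantage over the second is very unlikely to be luck.

The same catalogue is available from the shell:

```sh
$ evalstats reproduce-examples        # all embedded worked-example values
$ evalstats advise --task binary_classification --metric sensitivity \
      --evidence single_test_set
{
  "test": "mcnemar",
  ...
}
$ evalstats metrics --task segmentation --input pred.png --truth gt.png
$ evalstats compare --test wilcoxon --input paired_dice.csv
```

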