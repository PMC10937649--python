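"""Count-based classification metrics: binary, multi-class, multi-label."""

import numpy as np
import pytest

from evalstats import (
    BinaryConfusion,
    ConfusionMatrixK,
    Metric,
    MultiLabelSet,
    UndefinedMetricError,
    binary_metrics,
    cohen_kappa_binary,
    cohen_kappa_multiclass,
    confusion_from_labels,
    hamming_loss,
    macro_average,
    mcc_binary,
    mcc_multiclass,
    micro_average,
    multilabel_average,
    per_class_confusion,
)
from evalstats.errors import InputError

from conftest import random_confusion_2x2


class TestConfusionFromLabels:
    def test_one_of_each_designation(self):
        cm = confusion_from_labels([1, 1, 0, 0], [1, 0, 1, 0])
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)

    def test_identity_prediction(self):
        cm = confusion_from_labels([1, 0], [1, 0])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (1, 1, 0, 0)

    def test_matches_brute_force_tally(self, rng):
        truth = rng.integers(0, 2, size=20)
        pred = rng.integers(0, 2, size=20)
        cm = confusion_from_labels(truth, pred)
        # direct per-instance enumeration oracle
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for t, p in zip(truth, pred):
            key = ("t" if t == p else "f") + ("p" if p == 1 else "n")
            tally[key] += 1
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (
            tally["tp"], tally["tn"], tally["fp"], tally["fn"],
        )

    @pytest.mark.parametrize(
        "truth,pred",
        [([1, 0], [1]), ([1, 2], [1, 0]), ([], [])],
    )
    def test_rejects_bad_input(self, truth, pred):
        with pytest.raises(InputError):
            confusion_from_labels(truth, pred)


class TestBinaryMetrics:
    def test_perfect_classifier_scores_one_everywhere(self):
        r = binary_metrics(BinaryConfusion(tp=50, tn=50, fp=0, fn=0))
        assert all(v == 1.0 for v in r.as_dict().values())

    def test_agrees_with_label_list_recomputation(self, rng):
        # realize random counts as a label list and recompute per instance
        for _ in range(20):
            cm = random_confusion_2x2(rng)
            truth = [1] * (cm.tp + cm.fn) + [0] * (cm.fp + cm.tn)
            pred = [1] * cm.tp + [0] * cm.fn + [1] * cm.fp + [0] * cm.tn
            cm2 = confusion_from_labels(truth, pred)
            assert binary_metrics(cm) == binary_metrics(cm2)

    def test_all_fields_in_unit_interval(self, rng):
        for _ in range(200):
            cm = random_confusion_2x2(rng)
            r = binary_metrics(cm)
            for name, v in r.as_dict().items():
                if name == "youden":
                    assert -1.0 <= v <= 1.0
                else:
                    assert 0.0 <= v <= 1.0

    def test_zero_denominator_is_an_error_not_zero(self):
        cm = BinaryConfusion(tp=0, tn=10, fp=0, fn=0)  # no true positives
        with pytest.raises(UndefinedMetricError, match="sensitivity"):
            binary_metrics(cm)

    def test_negative_count_rejected(self):
        with pytest.raises(InputError):
            BinaryConfusion(tp=-1, tn=1, fp=1, fn=1)


class TestKappaAndMcc:
    def test_perfect_diagonal_gives_kappa_one(self):
        assert cohen_kappa_binary(BinaryConfusion(tp=50, tn=50, fp=0, fn=0)) == 1.0

    def test_chance_agreement_of_balanced_marginals_is_half(self, table1):
        # marginals 300*368 + 300*232 over 600^2 = 1/2 exactly
        n = table1.total
        pe = (
            (table1.tp + table1.fn) * (table1.tp + table1.fp)
            + (table1.tn + table1.fp) * (table1.tn + table1.fn)
        ) / n**2
        assert pe == 0.5
        acc = (table1.tp + table1.tn) / n
        assert cohen_kappa_binary(table1) == pytest.approx((acc - 0.5) / 0.5)

    def test_antiperfect_mcc_is_minus_one(self):
        assert mcc_binary(BinaryConfusion(tp=0, tn=0, fp=50, fn=50)) == -1.0

    def test_mcc_undefined_for_zero_marginal(self):
        with pytest.raises(UndefinedMetricError):
            mcc_binary(BinaryConfusion(tp=10, tn=0, fp=0, fn=5))

    def test_k2_reductions_match_binary_formulas(self, rng):
        """Multi-class kappa and MCC reduce exactly to the binary forms at k=2."""
        for _ in range(1000):
            cm = random_confusion_2x2(rng)
            K = ConfusionMatrixK(cm.as_matrix())
            assert cohen_kappa_multiclass(K) == pytest.approx(
                cohen_kappa_binary(cm), abs=1e-12
            )
            assert mcc_multiclass(K) == pytest.approx(mcc_binary(cm), abs=1e-12)

    def test_mcc_multiclass_equals_onehot_correlation(self, rng):
        """The k-class MCC is the correlation of the one-hot codings of true
        and predicted labels, with covariances summed over the k indicator
        columns (the R_K construction), recomputed here from a label list."""
        counts = rng.integers(1, 30, size=(3, 3))
        K = ConfusionMatrixK(counts)
        truth, pred = [], []
        for i in range(3):
            for j in range(3):
                truth += [i] * counts[i, j]
                pred += [j] * counts[i, j]
        t = np.eye(3)[truth]  # n x k indicators
        p = np.eye(3)[pred]
        cov_tp = sum(np.cov(t[:, k], p[:, k], ddof=0)[0, 1] for k in range(3))
        var_t = sum(t[:, k].var() for k in range(3))
        var_p = sum(p[:, k].var() for k in range(3))
        r = cov_tp / np.sqrt(var_t * var_p)
        assert mcc_multiclass(K) == pytest.approx(r, abs=1e-10)

    def test_identity_permutation_matrix_kappa_one(self):
        K = ConfusionMatrixK(np.diag([10, 20, 30]))
        assert cohen_kappa_multiclass(K) == 1.0


class TestPerClassAndAveraging:
    def test_class4_counts_from_printed_matrix(self, table2):
        cm = per_class_confusion(table2, 3)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (38, 102, 10, 410)

    def test_class1_fp_is_column_sum_minus_diagonal(self, table2):
        cm = per_class_confusion(table2, 0)
        assert cm.tp == 120
        assert cm.fp == 149 - 120

    def test_per_class_counts_sum_to_n(self, table2):
        for i in range(table2.k):
            assert per_class_confusion(table2, i).total == table2.n

    def test_diagonal_matrix_has_no_errors(self):
        K = ConfusionMatrixK(np.diag([5, 5, 5]))
        for i in range(3):
            cm = per_class_confusion(K, i)
            assert cm.fp == cm.fn == 0

    def test_index_out_of_range(self, table2):
        with pytest.raises(InputError):
            per_class_confusion(table2, 4)

    def test_micro_precision_equals_recall_equals_f1(self, rng):
        # for any square matrix sum FP = sum FN, so the three coincide
        for _ in range(50):
            k = int(rng.integers(2, 6))
            K = ConfusionMatrixK(rng.integers(1, 40, size=(k, k)))
            p = micro_average(K, "precision")
            assert micro_average(K, "sensitivity") == pytest.approx(p, abs=1e-12)
            assert micro_average(K, "f1") == pytest.approx(p, abs=1e-12)

    def test_balanced_classes_micro_equals_macro(self, table2):
        """All row sums equal => micro and macro coincide for acc/sen/spe/youden."""
        assert np.unique(table2.row_sums()).size == 1
        for m in ("accuracy", "sensitivity", "specificity", "youden"):
            assert macro_average(table2, m) == pytest.approx(
                micro_average(table2, m), abs=1e-12
            )

    def test_permuting_classes_leaves_aggregates_unchanged(self, rng, table2):
        perm = rng.permutation(table2.k)
        Kp = ConfusionMatrixK(table2.counts[np.ix_(perm, perm)])
        assert cohen_kappa_multiclass(Kp) == pytest.approx(cohen_kappa_multiclass(table2))
        assert mcc_multiclass(Kp) == pytest.approx(mcc_multiclass(table2))
        for m in Metric:
            assert macro_average(Kp, m) == pytest.approx(macro_average(table2, m))
            assert micro_average(Kp, m) == pytest.approx(micro_average(table2, m))

    def test_undefined_class_metric_names_the_class(self):
        K = ConfusionMatrixK(
            [[5, 0, 0], [0, 5, 0], [0, 0, 0]], class_names=("a", "b", "c")
        )
        with pytest.raises(UndefinedMetricError, match="class c"):
            macro_average(K, "sensitivity")


class TestMultiLabel:
    def test_hamming_loss_zero_for_identical(self, rng):
        m = rng.integers(0, 2, size=(6, 4))
        assert hamming_loss(MultiLabelSet(truth=m, predicted=m)) == 0.0

    def test_hamming_loss_one_for_complement(self, rng):
        m = rng.integers(0, 2, size=(6, 4))
        assert hamming_loss(MultiLabelSet(truth=m, predicted=1 - m)) == 1.0

    def test_hamming_loss_counts_disagreements(self):
        ml = MultiLabelSet(truth=[[1, 0], [0, 1]], predicted=[[1, 1], [0, 1]])
        assert hamming_loss(ml) == 0.25

    def test_micro_accuracy_complements_hamming_loss(self, rng):
        ml = MultiLabelSet(
            truth=rng.integers(0, 2, size=(10, 5)),
            predicted=rng.integers(0, 2, size=(10, 5)),
        )
        assert multilabel_average(ml, "accuracy", "micro") == pytest.approx(
            1.0 - hamming_loss(ml)
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            MultiLabelSet(truth=[[1, 0]], predicted=[[1], [0]])


class TestOrientation:
    def test_pred_rows_ingest_transposes(self, table2):
        K2 = ConfusionMatrixK.from_counts(table2.counts.T, orientation="pred_rows")
        assert np.array_equal(K2.counts, table2.counts)


class TestLibraryOracles:
    """Independent cross-checks against scikit-learn's implementations."""

    def test_kappa_and_mcc_match_sklearn_from_labels(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            truth = rng.integers(0, 2, size=60)
            pred = rng.integers(0, 2, size=60)
            if truth.sum() in (0, 60) or pred.sum() in (0, 60):
                continue
            cm = confusion_from_labels(truth, pred)
            assert cohen_kappa_binary(cm) == pytest.approx(
                sk.cohen_kappa_score(truth, pred), abs=1e-12
            )
            assert mcc_binary(cm) == pytest.approx(
                sk.matthews_corrcoef(truth, pred), abs=1e-12
            )

    def test_multiclass_kappa_mcc_and_averages_match_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        truth = rng.integers(0, 4, size=200)
        pred = rng.integers(0, 4, size=200)
        counts = np.zeros((4, 4), dtype=int)
        for t, p in zip(truth, pred):
            counts[t, p] += 1
        K = ConfusionMatrixK(counts)
        assert cohen_kappa_multiclass(K) == pytest.approx(
            sk.cohen_kappa_score(truth, pred), abs=1e-12
        )
        assert mcc_multiclass(K) == pytest.approx(
            sk.matthews_corrcoef(truth, pred), abs=1e-12
        )
        assert macro_average(K, "f1") == pytest.approx(
            sk.f1_score(truth, pred, average="macro"), abs=1e-12
        )
        assert micro_average(K, "precision") == pytest.approx(
            sk.precision_score(truth, pred, average="micro"), abs=1e-12
        )
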