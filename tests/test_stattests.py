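"""Paired model-comparison tests, variance tests, and their exact branches."""

import itertools

import numpy as np
import pytest
from scipy import stats

from evalstats import (
    DiscordantPair,
    InputError,
    MetricMatrix,
    PairedSamples,
    UndefinedMetricError,
    bartlett_test,
    delong_auc,
    delong_test,
    friedman_test,
    levene_test,
    mcnemar_test,
    paired_t_test,
    shapiro_wilk,
    sign_test,
    variance_f_test,
    wilcoxon_signed_rank,
)
from evalstats.synth import SynthConfig, synth_scores


def ps_from_diff(d):
    d = np.asarray(d, dtype=float)
    return PairedSamples(a=d, b=np.zeros_like(d))


class TestPairedT:
    def test_textbook_example(self):
        r = paired_t_test(ps_from_diff([1, 2, 3]))
        assert r.statistic == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-6)  # 3.464
        assert r.df == (2,)

    def test_matches_scipy(self, rng):
        a = rng.standard_normal(15)
        b = rng.standard_normal(15)
        r = paired_t_test(PairedSamples(a=a, b=b))
        ref = stats.ttest_rel(a, b)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue)

    def test_constant_difference_is_degenerate(self):
        with pytest.raises(UndefinedMetricError):
            paired_t_test(ps_from_diff([2, 2, 2]))


class TestSignTest:
    def test_clean_sweep_of_ten(self):
        r = sign_test(ps_from_diff([1] * 10))
        assert r.p_value == pytest.approx(2 * 0.5**10)

    def test_even_split_p_one(self):
        r = sign_test(ps_from_diff([1] * 5 + [-1] * 5))
        assert r.p_value == 1.0

    def test_ties_dropped_before_counting(self):
        r = sign_test(ps_from_diff([1, 1, 0, 0, -1]))
        assert r.extras["n_after_ties"] == 3
        assert r.extras["wins"] == 2

    def test_exact_p_matches_sign_pattern_enumeration(self, rng):
        """Brute-force oracle: all 2^n equally likely win patterns."""
        for n in (4, 7, 10):
            d = rng.standard_normal(n)
            wins = int((d > 0).sum())
            counts = np.bincount(
                [sum(pat) for pat in itertools.product((0, 1), repeat=n)],
                minlength=n + 1,
            )
            total = counts.sum()
            expected = min(
                1.0,
                2 * min(counts[: wins + 1].sum() / total, counts[wins:].sum() / total),
            )
            assert sign_test(ps_from_diff(d)).p_value == pytest.approx(expected)

    def test_normal_approximation_reported_for_large_n(self, rng):
        d = rng.standard_normal(30)
        r = sign_test(ps_from_diff(d))
        assert "z" in r.extras and 0 <= r.extras["p_normal"] <= 1

    def test_all_ties_rejected(self):
        with pytest.raises(UndefinedMetricError):
            sign_test(ps_from_diff([0.0, 0.0]))


class TestWilcoxon:
    def test_one_sided_extreme_ranks(self):
        r = wilcoxon_signed_rank(ps_from_diff([1, 2, 3]))
        assert r.extras["r_plus"] == 6.0
        assert r.extras["r_minus"] == 0.0
        assert r.statistic == 0.0

    def test_hand_ranked_example_with_z(self):
        r = wilcoxon_signed_rank(ps_from_diff([1, -2, 3, -4, 5]))
        assert r.extras["r_plus"] == 9.0
        assert r.extras["r_minus"] == 6.0
        assert r.statistic == 6.0
        assert r.extras["z"] == pytest.approx((6 - 7.5) / np.sqrt(13.75), abs=1e-6)

    def test_swapping_sides_preserves_t_and_abs_z(self, rng):
        a = rng.standard_normal(12)
        b = rng.standard_normal(12)
        r1 = wilcoxon_signed_rank(PairedSamples(a=a, b=b))
        r2 = wilcoxon_signed_rank(PairedSamples(a=b, b=a))
        assert r1.extras["r_plus"] == r2.extras["r_minus"]
        assert r1.statistic == r2.statistic
        assert abs(r1.extras["z"]) == pytest.approx(abs(r2.extras["z"]))

    def test_exact_p_matches_sign_flip_enumeration(self, rng):
        """Brute-force null: all 2^n sign assignments of the ranked |d|."""
        for n in (5, 8, 10):
            d = rng.standard_normal(n)
            ranks = stats.rankdata(np.abs(d))
            r_plus_obs = ranks[d > 0].sum()
            r_plus_all = [
                sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product((False, True), repeat=n)
            ]
            r_plus_all = np.array(r_plus_all)
            total = r_plus_all.size
            expected = min(
                1.0,
                2
                * min(
                    (r_plus_all <= r_plus_obs).sum() / total,
                    (r_plus_all >= r_plus_obs).sum() / total,
                ),
            )
            r = wilcoxon_signed_rank(ps_from_diff(d))
            assert r.method == "exact"
            assert r.p_value == pytest.approx(expected)

    def test_exact_p_matches_scipy_exact_mode(self, rng):
        d = rng.standard_normal(14)
        r = wilcoxon_signed_rank(ps_from_diff(d))
        ref = stats.wilcoxon(d, mode="exact")
        assert r.p_value == pytest.approx(ref.pvalue)

    def test_normal_branch_above_cutoff(self, rng):
        d = rng.standard_normal(40)
        r = wilcoxon_signed_rank(ps_from_diff(d))
        assert r.method == "asymptotic"
        z = r.extras["z"]
        assert r.p_value == pytest.approx(2 * stats.norm.cdf(-abs(z)))

    def test_zeros_discarded(self):
        r = wilcoxon_signed_rank(ps_from_diff([0, 0, 1, -2, 3]))
        assert r.extras["n_after_zeros"] == 3

    def test_all_zero_differences_rejected(self):
        with pytest.raises(UndefinedMetricError):
            wilcoxon_signed_rank(ps_from_diff([0.0, 0.0, 0.0]))


class TestFriedman:
    def test_hand_computed_statistics(self):
        # rows rank the three models (1,2,3), (1,2,3), (1,3,2)
        mm = MetricMatrix(np.array([[3, 2, 1], [3, 2, 1], [3, 1, 2]], dtype=float))
        r_chi = friedman_test(mm, "chi2")
        assert r_chi.statistic == pytest.approx(14 / 3, abs=1e-9)
        r_f = friedman_test(mm)
        assert r_f.statistic == pytest.approx(7.0, abs=1e-9)
        assert r_f.df == (2, 4)

    def test_chi2_matches_scipy(self, rng):
        values = rng.standard_normal((12, 4))
        mm = MetricMatrix(values)
        ref = stats.friedmanchisquare(*values.T)
        r = friedman_test(mm, "chi2")
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue)

    def test_identical_rankings_maximal_chi2(self, rng):
        J, K = 20, 3
        base = rng.standard_normal(J)[:, None]
        values = base + np.array([3.0, 2.0, 1.0])[None, :]
        mm = MetricMatrix(values)
        r = friedman_test(mm, "chi2")
        assert r.statistic == pytest.approx(2 * J)  # max separation at K=3
        with pytest.raises(UndefinedMetricError):
            friedman_test(mm, "iman_davenport")  # F_ID denominator vanishes

    def test_column_permutation_invariance(self, rng):
        values = rng.standard_normal((10, 4))
        mm = MetricMatrix(values)
        perm = rng.permutation(4)
        mm_p = MetricMatrix(values[:, perm])
        assert friedman_test(mm, "chi2").statistic == pytest.approx(
            friedman_test(mm_p, "chi2").statistic
        )
        assert friedman_test(mm).statistic == pytest.approx(
            friedman_test(mm_p).statistic
        )

    def test_k2_ranks_agree_with_sign_test_direction(self, rng):
        a = rng.standard_normal(15)
        b = a + 0.2 + 0.6 * rng.standard_normal(15)  # b better on average
        mm = MetricMatrix(np.column_stack([a, b]))
        r = friedman_test(mm)
        # model with more wins has the better (smaller) mean rank
        wins_b = (b > a).sum()
        ranks = r.extras["mean_ranks"]
        assert (wins_b > 15 / 2) == (ranks[1] < ranks[0])


class TestMcNemar:
    def test_continuity_corrected_statistic_from_counts(self):
        r = mcnemar_test(DiscordantPair(b=54, c=19))
        assert r.statistic == pytest.approx((35 - 1) ** 2 / 73, abs=1e-9)
        assert r.distribution == "chi2"

    def test_balanced_counts_small_statistic(self):
        assert mcnemar_test(DiscordantPair(b=10, c=10)).statistic == pytest.approx(0.05)

    def test_binomial_branch_below_twenty(self):
        r = mcnemar_test(DiscordantPair(b=15, c=4))
        assert r.distribution == "binomial"
        assert r.method == "exact"
        assert r.p_value == pytest.approx(min(1.0, 2 * stats.binom.cdf(4, 19, 0.5)))

    def test_exact_p_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for b, c in [(15, 4), (3, 9), (1, 10)]:
            table = [[0, b], [c, 0]]
            ref = sm.mcnemar(table, exact=True)
            assert mcnemar_test(DiscordantPair(b=b, c=c)).p_value == pytest.approx(
                ref.pvalue
            )

    def test_chi2_branch_matches_statsmodels_corrected(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        ref = sm.mcnemar([[0, 54], [19, 0]], exact=False, correction=True)
        r = mcnemar_test(DiscordantPair(b=54, c=19))
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue)

    def test_empty_pair_rejected(self):
        with pytest.raises(InputError):
            DiscordantPair(b=0, c=0)


class TestDeLong:
    def test_structural_components_of_worked_example(self):
        theta, v10, v01 = delong_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        assert theta == pytest.approx(0.75)
        assert v10.tolist() == [1.0, 0.5]
        assert v01.tolist() == [0.5, 1.0]

    def test_equal_auc_curves_give_z_zero(self):
        r = delong_test([0.9, 0.8, 0.4, 0.3], [0.7, 0.6, 0.5, 0.2], [1, 0, 1, 0])
        assert r.statistic == 0.0
        assert r.p_value == 1.0
        assert r.extras["theta1"] == r.extras["theta2"] == 0.75

    def test_identical_scores_rejected(self):
        s = [0.9, 0.8, 0.4, 0.3]
        with pytest.raises(UndefinedMetricError):
            delong_test(s, s, [1, 0, 1, 0])

    def test_clearly_better_classifier_detected(self, rng):
        cfg = SynthConfig(seed=5, n=400, separation=1.5, separation2=0.2, correlation=0.3)
        sp1, sp2 = synth_scores(cfg)
        r = delong_test(sp1.scores, sp2.scores, sp1.labels)
        assert r.statistic > 3
        assert r.p_value < 0.01

    def test_null_z_approximately_standard_normal(self):
        """Monte-Carlo calibration: two noisy copies of one latent score."""
        zs = []
        for rep in range(2000):
            cfg = SynthConfig(seed=rep, n=60, separation=1.0, correlation=0.5)
            sp1, sp2 = synth_scores(cfg)
            zs.append(delong_test(sp1.scores, sp2.scores, sp1.labels).statistic)
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 3 / np.sqrt(2000)  # 3 MC SEs of 0
        assert zs.std() == pytest.approx(1.0, abs=0.08)
        rej = (np.abs(zs) > stats.norm.ppf(0.975)).mean()
        assert abs(rej - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / 2000)


class TestVarianceAndNormality:
    def test_identical_samples_f_one(self, rng):
        x = rng.standard_normal(20)
        r = variance_f_test(x, x.copy())
        assert r.statistic == 1.0
        assert r.p_value == pytest.approx(1.0)

    def test_scaling_moves_f_by_square(self, rng):
        x = rng.standard_normal(25)
        r = variance_f_test(2 * x, x)
        assert r.statistic == pytest.approx(4.0)

    def test_f_null_rejection_near_alpha(self, rng):
        rejections = 0
        reps = 1000
        for _ in range(reps):
            x = rng.standard_normal(30)
            y = rng.standard_normal(30)
            if variance_f_test(x, y).p_value < 0.05:
                rejections += 1
        assert abs(rejections / reps - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedMetricError):
            variance_f_test([1.0, 1.0, 1.0], [1, 2, 3])

    def test_identical_groups_bartlett_zero(self, rng):
        g = rng.standard_normal(15)
        r = bartlett_test([g, g.copy(), g.copy()])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_levene_more_robust_than_f_on_skewed_data(self, rng):
        """Equal-variance lognormal groups: F rejects more than Levene."""
        f_rej = lev_rej = 0
        reps = 400
        for _ in range(reps):
            x = rng.lognormal(0, 1, size=25)
            y = rng.lognormal(0, 1, size=25)
            if variance_f_test(x, y).p_value < 0.05:
                f_rej += 1
            if levene_test([x, y]).p_value < 0.05:
                lev_rej += 1
        assert lev_rej < f_rej

    def test_shapiro_rejects_uniform_samples(self, rng):
        rejections = sum(
            shapiro_wilk(rng.uniform(size=200)).p_value < 0.05 for _ in range(50)
        )
        assert rejections >= 45

    def test_shapiro_needs_three(self):
        with pytest.raises(InputError):
            shapiro_wilk([1.0, 2.0])


def test_every_result_p_in_unit_interval(rng):
    results = [
        paired_t_test(ps_from_diff(rng.standard_normal(10))),
        sign_test(ps_from_diff(rng.standard_normal(10))),
        wilcoxon_signed_rank(ps_from_diff(rng.standard_normal(10))),
        friedman_test(MetricMatrix(rng.standard_normal((8, 3)))),
        mcnemar_test(DiscordantPair(b=5, c=9)),
        variance_f_test(rng.standard_normal(10), rng.standard_normal(10)),
    ]
    assert all(0.0 <= r.p_value <= 1.0 for r in results)
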