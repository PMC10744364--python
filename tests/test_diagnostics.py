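import numpy as np
import pytest
from scipy import stats

from specratio.diagnostics import (
    BootstrapConfig,
    auc_sample_size,
    bootstrap_cutoff_ci,
    delong_paired_test,
    exact_binomial_ci,
    ppv_npv,
    pr_auc_logit_ci,
    pr_curve,
    roc_auc_delong,
    youden_cutoff,
)
from specratio.stats import mann_whitney_u


def brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestRocAucDelong:
    def test_perfect_separation(self):
        res = roc_auc_delong([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0 and res.se == 0.0

    def test_small_examples_match_pair_counting(self):
        scores = np.array([1.0, 2, 3, 4])
        assert roc_auc_delong(scores, np.array([0, 0, 1, 1])).auc == 1.0
        res = roc_auc_delong(scores, np.array([0, 1, 0, 1]), orient=False)
        assert res.auc == pytest.approx(0.75)

    def test_auc_matches_brute_force_on_random_data(self, rng):
        for _ in range(25):
            n = rng.integers(6, 30)
            scores = rng.integers(0, 8, n).astype(float)  # ties likely
            labels = np.r_[np.ones(3), np.zeros(n - 3)]
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            res = roc_auc_delong(scores, labels, orient=False)
            assert res.auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_orientation_flips_low_auc(self, rng):
        scores = np.r_[rng.normal(1, 1, 30), rng.normal(0, 1, 30)]
        labels = np.r_[np.zeros(30), np.ones(30)]  # positives score LOWER
        res = roc_auc_delong(scores, labels)
        assert res.auc >= 0.5
        assert res.orientation == "less-is-positive"

    def test_null_auc_within_three_se(self, rng):
        scores = rng.standard_normal(400)
        labels = np.r_[np.ones(200), np.zeros(200)]
        res = roc_auc_delong(scores, labels, orient=False)
        assert abs(res.auc - 0.5) <= 3 * res.se

    def test_curve_is_monotone(self, rng):
        scores = rng.standard_normal(50)
        labels = (rng.random(50) < 0.4).astype(int)
        res = roc_auc_delong(scores, labels)
        curve = res.curve
        assert tuple(curve[0]) == (0.0, 0.0) and tuple(curve[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve[:, 0]) >= 0)
        assert np.all(np.diff(curve[:, 1]) >= 0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_delong([1.0, 2.0], [1, 1])

    def test_auc_equals_mwu_u_identity(self, rng):
        """Empirical AUC must equal U/(n1*n2) exactly."""
        for _ in range(20):
            x = rng.standard_normal(13) + 0.3
            y = rng.standard_normal(17)
            u, _ = mann_whitney_u(x, y)
            scores = np.r_[x, y]
            labels = np.r_[np.ones(13), np.zeros(17)]
            res = roc_auc_delong(scores, labels, orient=False)
            assert res.auc == pytest.approx(u / (13 * 17), abs=1e-12)

    def test_invariance_under_monotone_transform(self, rng):
        scores = rng.standard_normal(40)
        labels = (rng.random(40) < 0.5).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a = roc_auc_delong(scores, labels, orient=False)
        b = roc_auc_delong(np.exp(2 * scores), labels, orient=False)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)


def test_delong_se_agrees_with_bootstrap_variance():
    """DeLong's analytic variance should track the stratified-bootstrap
    variance of the AUC within 20% relative error at n >= 50 per group."""
    rng = np.random.default_rng(17)
    pos = rng.normal(1.0, 1, 60)
    neg = rng.normal(0.0, 1, 60)
    res = roc_auc_delong(np.r_[pos, neg], np.r_[np.ones(60), np.zeros(60)],
                         orient=False)
    aucs = []
    for _ in range(2000):
        p = rng.choice(pos, 60)
        n = rng.choice(neg, 60)
        aucs.append(brute_force_auc(np.r_[p, n],
                                    np.r_[np.ones(60), np.zeros(60)]))
    boot_var = np.var(aucs, ddof=1)
    assert res.se**2 == pytest.approx(boot_var, rel=0.2)


class TestDelongPaired:
    def test_identical_markers(self, rng):
        scores = rng.standard_normal(30)
        labels = np.r_[np.ones(15), np.zeros(15)]
        z, p = delong_paired_test(scores, scores, labels)
        assert (z, p) == (0.0, 1.0)

    def test_monotone_transform_equivalent(self, rng):
        scores = rng.standard_normal(30)
        labels = np.r_[np.ones(15), np.zeros(15)]
        z, p = delong_paired_test(scores, scores**3 + 5, labels)
        assert z == 0.0 and p == 1.0

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(2024)
        ps = []
        for _ in range(300):
            a = rng.standard_normal(80)
            b = rng.standard_normal(80)
            labels = np.r_[np.ones(40), np.zeros(40)]
            ps.append(delong_paired_test(a, b, labels)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            delong_paired_test(
                rng.standard_normal(10), rng.standard_normal(9),
                np.r_[np.ones(5), np.zeros(5)],
            )


def numeric_pr_area(scores, labels, n_grid=200001):
    """Oracle: dense numeric integration of precision d(recall) along the
    linear-in-(TP,FP) path between achievable points."""
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    s = scores[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.r_[0.0, np.cumsum(y)[distinct]]
    fp = np.r_[0.0, np.cumsum(1 - y)[distinct]]
    n_pos = labels.sum()
    area = 0.0
    for i in range(len(tp) - 1):
        dtp = tp[i + 1] - tp[i]
        if dtp <= 0:
            continue
        u = np.linspace(tp[i], tp[i + 1], n_grid)
        f = fp[i] + (fp[i + 1] - fp[i]) * (u - tp[i]) / dtp
        prec = np.where(u + f > 0, u / np.maximum(u + f, 1e-300), 1.0)
        area += np.trapezoid(prec, u / n_pos)
    return area


class TestPRCurve:
    def test_perfect_marker(self):
        res = pr_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == pytest.approx(1.0)

    def test_constant_marker_gives_prevalence(self):
        labels = np.r_[np.ones(4), np.zeros(8)]
        res = pr_curve(np.zeros(12), labels)
        assert res.auc == pytest.approx(4 / 12)

    @pytest.mark.parametrize(
        "scores, labels",
        [
            ([0.9, 0.8, 0.7, 0.6, 0.5, 0.4], [1, 0, 1, 1, 0, 0]),
            ([3.0, 2.5, 2.5, 1.0, 0.5, 0.1, 0.1, 0.0], [1, 1, 0, 1, 0, 1, 0, 0]),
        ],
    )
    def test_area_matches_numeric_path_integration(self, scores, labels):
        scores = np.asarray(scores, float)
        labels = np.asarray(labels)
        res = pr_curve(scores, labels)
        assert res.auc == pytest.approx(numeric_pr_area(scores, labels), abs=1e-9)

    def test_random_markers_match_oracle(self, rng):
        for _ in range(10):
            scores = rng.standard_normal(25)
            labels = (rng.random(25) < 0.4).astype(int)
            if labels.sum() == 0:
                labels[0] = 1
            res = pr_curve(scores, labels)
            assert res.auc == pytest.approx(
                numeric_pr_area(scores, labels), abs=1e-7
            )

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_curve([1.0, 2.0], [0, 0])


class TestPrAucLogitCi:
    def test_symmetric_about_half_on_logit_scale(self):
        (lo, hi), flag = pr_auc_logit_ci(0.5, 20, 20)
        assert not flag
        assert lo == pytest.approx(1 - hi, abs=1e-12)

    def test_interval_narrows_with_n(self):
        (lo1, hi1), _ = pr_auc_logit_ci(0.7, 20, 20)
        (lo2, hi2), _ = pr_auc_logit_ci(0.7, 200, 200)
        assert (hi2 - lo2) < (hi1 - lo1)

    def test_degenerate_flag(self):
        interval, flag = pr_auc_logit_ci(1.0, 20, 20)
        assert flag and interval == (1.0, 1.0)

    def test_coverage_at_study_sample_sizes(self):
        """~95% CIs should cover the population PR AUC in 92-98% of
        binormal-marker replicates at the study's 23/29 split."""
        rng = np.random.default_rng(11)
        mu, n_pos, n_neg = 1.19, 23, 29
        pi = n_pos / (n_pos + n_neg)
        th = np.linspace(-10, 12, 40001)
        tpr = stats.norm.sf(th - mu)
        fpr = stats.norm.sf(th)
        prec = pi * tpr / (pi * tpr + (1 - pi) * fpr)
        pop_auc = np.trapezoid(prec[::-1], tpr[::-1])
        cover = 0
        n_rep = 500
        for _ in range(n_rep):
            scores = np.r_[rng.normal(mu, 1, n_pos), rng.normal(0, 1, n_neg)]
            labels = np.r_[np.ones(n_pos), np.zeros(n_neg)]
            res = pr_curve(scores, labels)
            cover += res.ci95[0] <= pop_auc <= res.ci95[1]
        assert 0.92 <= cover / n_rep <= 0.98


class TestYoudenCutoff:
    @pytest.mark.parametrize(
        "sens, spec, expect_ppv, expect_npv",
        [(0.696, 0.793, 77.1, 72.3), (0.696, 0.862, 83.5, 73.9)],
    )
    def test_predictive_value_arithmetic(self, sens, spec, expect_ppv, expect_npv):
        ppv, npv = ppv_npv(sens, spec, 0.5)
        assert round(100 * ppv, 1) == expect_ppv
        assert round(100 * npv, 1) == expect_npv

    def test_perfect_test(self):
        report = youden_cutoff([0, 0, 0, 5, 5, 5], [0, 0, 0, 1, 1, 1])
        assert report.sensitivity == 100.0 and report.specificity == 100.0
        assert report.youden_j == pytest.approx(1.0)
        assert report.ppv == 100.0 and report.npv == 100.0

    def test_report_arithmetic_identities(self, rng):
        """J = se + sp - 1 and the prevalence formulas hold for every
        emitted report."""
        for _ in range(10):
            scores = rng.standard_normal(40)
            labels = (rng.random(40) < 0.45).astype(int)
            if labels.min() == labels.max():
                continue
            rep = youden_cutoff(scores, labels)
            se, sp = rep.sensitivity / 100, rep.specificity / 100
            assert rep.youden_j == pytest.approx(se + sp - 1, abs=1e-12)
            ppv, npv = ppv_npv(se, sp, rep.prevalence)
            assert rep.ppv == pytest.approx(100 * ppv, abs=1e-9)
            assert rep.npv == pytest.approx(100 * npv, abs=1e-9)

    def test_tie_break_prefers_specificity(self):
        # two cutoffs reach J = 0.5; the more specific one must win
        scores = np.array([1.0, 2.0, 3.0, 4.0], float)
        labels = np.array([0, 1, 0, 1])
        rep = youden_cutoff(scores, labels)
        assert rep.direction == ">"
        assert rep.cutoff == pytest.approx(3.5)
        assert rep.specificity == 100.0

    def test_cutoff_rule_invariant_under_monotone_transform(self, rng):
        scores = rng.standard_normal(30)
        labels = (rng.random(30) < 0.5).astype(int)
        labels[:2] = [0, 1]
        rep1 = youden_cutoff(scores, labels)
        rep2 = youden_cutoff(np.exp(scores), labels)
        cls1 = scores > rep1.cutoff if rep1.direction == ">" else scores <= rep1.cutoff
        s2 = np.exp(scores)
        cls2 = s2 > rep2.cutoff if rep2.direction == ">" else s2 <= rep2.cutoff
        assert np.array_equal(cls1, cls2)

    def test_less_is_positive_direction(self, rng):
        scores = np.r_[rng.normal(0, 1, 20), rng.normal(2, 1, 20)]
        labels = np.r_[np.ones(20), np.zeros(20)]  # positives score lower
        rep = youden_cutoff(scores, labels)
        assert rep.direction == "<="
        assert rep.youden_j > 0


class TestBootstrapCutoffCi:
    def _marker(self, rng, n=40):
        scores = np.r_[rng.normal(1.2, 1, n), rng.normal(0, 1, n)]
        labels = np.r_[np.ones(n), np.zeros(n)]
        return scores, labels

    def test_deterministic_under_seed(self, rng):
        scores, labels = self._marker(rng)
        cfg = BootstrapConfig(iterations=500, seed=978)
        assert bootstrap_cutoff_ci(scores, labels, cfg) == bootstrap_cutoff_ci(
            scores, labels, cfg
        )

    def test_duplicated_data_narrows_j_interval(self, rng):
        scores, labels = self._marker(rng, n=25)
        cfg = BootstrapConfig(iterations=800, seed=978)
        _, j_small = bootstrap_cutoff_ci(scores, labels, cfg)
        _, j_big = bootstrap_cutoff_ci(
            np.tile(scores, 10), np.tile(labels, 10), cfg
        )
        assert (j_big[1] - j_big[0]) < (j_small[1] - j_small[0])

    def test_matches_naive_bootstrap_distribution(self, rng):
        """The vectorized multinomial resampler must agree with a naive
        per-draw resampling loop (same statistic, independent code)."""
        from specratio.diagnostics import _best_youden

        scores, labels = self._marker(rng, n=20)
        cfg = BootstrapConfig(iterations=2000, seed=4)
        _, j_ci = bootstrap_cutoff_ci(scores, labels, cfg, direction=">")
        r = np.random.default_rng(5)
        pos, neg = scores[labels == 1], scores[labels == 0]
        js = []
        for _ in range(2000):
            p = r.choice(pos, pos.size)
            n_ = r.choice(neg, neg.size)
            js.append(_best_youden(p, n_, ">")[3])
        naive = np.percentile(js, [2.5, 97.5])
        assert j_ci[0] == pytest.approx(naive[0], abs=0.08)
        assert j_ci[1] == pytest.approx(naive[1], abs=0.08)

    def test_low_iteration_warning_flag(self):
        cfg = BootstrapConfig(iterations=50, seed=1)
        assert cfg.unstable


class TestExactBinomialCi:
    def test_boundaries(self):
        assert exact_binomial_ci(10, 10)[1] == 1.0
        assert exact_binomial_ci(0, 10)[0] == 0.0

    def test_study_sensitivity_row(self):
        lo, hi = exact_binomial_ci(16, 23)
        assert round(100 * lo, 1) == 47.1
        assert round(100 * hi, 1) == 86.8

    def test_matches_beta_quantile_oracle(self):
        k, n = 7, 31
        lo, hi = exact_binomial_ci(k, n)
        assert lo == pytest.approx(stats.beta.ppf(0.025, k, n - k + 1), abs=1e-12)
        assert hi == pytest.approx(stats.beta.ppf(0.975, k + 1, n - k), abs=1e-12)


class TestAucSampleSize:
    def test_study_calculation(self):
        assert auc_sample_size(alpha=0.01, power=0.8, auc_alt=0.8,
                               auc_null=0.5) == 20

    def test_monotone_in_effect(self):
        sizes = [
            auc_sample_size(alpha=0.01, power=0.8, auc_alt=a, auc_null=0.5)
            for a in (0.7, 0.8, 0.9, 0.95)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_monotone_in_alpha(self):
        n_strict = auc_sample_size(alpha=0.01, power=0.8, auc_alt=0.8)
        n_loose = auc_sample_size(alpha=0.05, power=0.8, auc_alt=0.8)
        assert n_loose < n_strict

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            auc_sample_size(auc_alt=0.5, auc_null=0.8)
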