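import math

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
import statsmodels.api as sm

from tendoqus import (
    CalibrationError,
    FitError,
    StatsError,
    auroc,
    binormal_auc,
    binormal_youden_cutoff,
    chi_square_proportions,
    hanley_mcneil_se,
    logistic_fit_univariate,
    or_from_beta,
    roc_curve,
    sens_spec_at,
    ttest_independent,
    youden_from_rates,
)


def random_instance(rng, n_max=50, tie_prone=False):
    n_pos = rng.integers(2, n_max // 2)
    n_neg = rng.integers(2, n_max // 2)
    if tie_prone:
        scores = rng.integers(0, 6, n_pos + n_neg).astype(float)
    else:
        scores = np.concatenate([rng.normal(1, 1, n_pos), rng.normal(0, 1, n_neg)])
    labels = np.array(["pos"] * n_pos + ["neg"] * n_neg)
    return scores, labels


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 4], ["neg", "neg", "pos", "pos"]) == 1.0

    def test_all_ties_is_chance(self):
        assert auroc([5, 5, 5, 5], ["neg", "pos", "neg", "pos"]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(CalibrationError):
            auroc([1, 2], ["pos", "pos"])

    @pytest.mark.parametrize("tie_prone", [False, True])
    def test_matches_reference_implementation(self, rng, tie_prone):
        for _ in range(50):
            scores, labels = random_instance(rng, tie_prone=tie_prone)
            expected = roc_auc_score((labels == "pos").astype(int), scores)
            assert auroc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_antisymmetry_under_score_negation(self, rng):
        for _ in range(30):
            scores, labels = random_instance(rng, tie_prone=True)
            assert auroc(scores, labels) + auroc(-scores, labels) == pytest.approx(1.0)

    def test_invariance_under_monotone_transform(self, rng):
        for transform in (np.exp, np.cbrt, lambda s: 3 * s - 7):
            scores, labels = random_instance(rng)
            assert auroc(transform(scores), labels) == pytest.approx(auroc(scores, labels))

    def test_binormal_closed_form_at_large_n(self):
        # Transverse StdDev group distributions, 200k draws per group.
        rng = np.random.default_rng(7)
        pos = rng.normal(30.1, 6.8, 200_000)
        neg = rng.normal(21.9, 4.1, 200_000)
        labels = np.array(["pos"] * len(pos) + ["neg"] * len(neg))
        expected = binormal_auc(30.1, 6.8, 21.9, 4.1)
        assert expected == pytest.approx(sps.norm.cdf(8.2 / math.hypot(6.8, 4.1)))
        assert auroc(np.concatenate([pos, neg]), labels) == pytest.approx(expected, abs=0.005)


class TestRocCurve:
    def test_perfect_toy(self):
        roc = roc_curve([1, 2, 3, 4], ["neg", "neg", "pos", "pos"])
        assert roc.best_cutoff == 2.5
        assert roc.youden_j == 1.0
        assert roc.sens_at_best == 1.0 and roc.spec_at_best == 1.0
        assert roc.auc == 1.0

    def test_points_monotone_and_trapezoid_equals_auc(self, rng):
        for _ in range(20):
            scores, labels = random_instance(rng, tie_prone=True)
            roc = roc_curve(scores, labels)
            fpr = np.array([p[0] for p in roc.points])
            tpr = np.array([p[1] for p in roc.points])
            assert (np.diff(fpr) >= -1e-12).all() and (np.diff(tpr) >= -1e-12).all()
            assert np.trapezoid(tpr, fpr) == pytest.approx(roc.auc, abs=1e-12)

    def test_best_j_equals_exhaustive_scan(self, rng):
        for _ in range(60):
            scores, labels = random_instance(rng, tie_prone=bool(rng.integers(2)))
            roc = roc_curve(scores, labels)
            pos = scores[labels == "pos"]
            neg = scores[labels == "neg"]
            brute = max(
                np.mean(pos > t) + np.mean(neg <= t) - 1.0
                for t in np.unique(np.concatenate([scores, scores - 1e-6, scores + 1e-6]))
            )
            assert roc.youden_j == pytest.approx(brute, abs=1e-12)

    def test_ci_is_clipped_normal_interval(self, rng):
        scores, labels = random_instance(rng)
        roc = roc_curve(scores, labels)
        assert roc.ci95[0] == pytest.approx(max(0.0, roc.auc - 1.96 * roc.auc_se))
        assert roc.ci95[1] == pytest.approx(min(1.0, roc.auc + 1.96 * roc.auc_se))

    def test_hanley_mcneil_se_shrinks_with_n(self):
        ses = [hanley_mcneil_se(0.85, n, n) for n in (50, 500, 5000)]
        assert ses[0] > ses[1] > ses[2]
        assert ses[2] < 0.01


class TestRates:
    def test_youden_identities(self):
        assert youden_from_rates(0.68, 0.90) == pytest.approx(0.58, abs=1e-12)
        assert youden_from_rates(1.0, 1.0) == 1.0
        assert youden_from_rates(0.5, 0.5) == 0.0
        with pytest.raises(CalibrationError):
            youden_from_rates(1.2, 0.5)

    def test_sens_spec_toy(self):
        assert sens_spec_at([1, 2, 3, 4], np.array(["neg", "neg", "pos", "pos"]), 2.5) == (1.0, 1.0)

    def test_sens_spec_binormal_oracle(self):
        rng = np.random.default_rng(11)
        n = 200_000
        for (mu, sd), cutoff in [((30.1, 6.8), 26.85), ((26.5, 6.0), 21.25)]:
            pos = rng.normal(mu, sd, n)
            neg = rng.normal(mu - 10, sd, n)
            scores = np.concatenate([pos, neg])
            labels = np.array(["pos"] * n + ["neg"] * n)
            sens, _ = sens_spec_at(scores, labels, cutoff)
            assert sens == pytest.approx(sps.norm.sf(cutoff, mu, sd), abs=0.005)


class TestLogistic:
    def test_matches_statsmodels(self, rng):
        for _ in range(10):
            n = int(rng.integers(40, 120))
            x = rng.normal(0, 2, n)
            p = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
            y = (rng.random(n) < p).astype(int)
            if y.min() == y.max():
                continue
            fit = logistic_fit_univariate(x, y)
            if not fit.converged:
                continue
            ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
            assert fit.beta == pytest.approx(ref.params[1], abs=1e-6)
            assert fit.se == pytest.approx(ref.bse[1], rel=1e-4)

    def test_optimum_beats_grid_search(self):
        x = np.array([-2.0, -1.5, -0.7, -0.2, 0.3, 0.9, 1.4, 2.2])
        y = np.array([0, 0, 1, 0, 1, 0, 1, 1])
        fit = logistic_fit_univariate(x, y)
        assert fit.converged

        def loglik(b0, b1):
            eta = b0 + b1 * x
            return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

        best_grid = max(
            loglik(b0, b1)
            for b0 in np.linspace(fit.intercept - 3, fit.intercept + 3, 200)
            for b1 in np.linspace(fit.beta - 3, fit.beta + 3, 200)
        )
        assert loglik(fit.intercept, fit.beta) >= best_grid

    def test_score_equation_identity(self, rng):
        n = 200
        x = rng.normal(25, 6, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(x - 25) / 4))).astype(int)
        fit = logistic_fit_univariate(x, y)
        p = 1 / (1 + np.exp(-(fit.intercept + fit.beta * x)))
        assert p.mean() == pytest.approx(y.mean(), abs=1e-8)

    def test_complete_separation_flagged(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        fit = logistic_fit_univariate(x, y)
        assert not fit.converged

    def test_degenerate_inputs_raise(self):
        with pytest.raises(FitError):
            logistic_fit_univariate([1.0, 1.0, 1.0], [0, 1, 0])
        with pytest.raises(FitError):
            logistic_fit_univariate([1.0, 2.0, 3.0], [1, 1, 1])

    def test_odds_ratio_is_exp_beta(self):
        assert round(or_from_beta(0.335), 3) == 1.398
        assert round(or_from_beta(0.342), 3) == 1.408
        assert round(or_from_beta(-0.044), 3) == 0.957
        assert or_from_beta(0.0) == 1.0


class TestGroupComparisons:
    def test_identical_groups(self):
        res = ttest_independent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_stat == 0.0 and res.t_p == pytest.approx(1.0)

    def test_shifted_groups_match_pooled_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([11.0, 12.0, 13.0])
        res = ttest_independent(a, b)
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert res.t_stat == pytest.approx(t_hand, abs=1e-12)

    def test_simulated_group_contrast_is_significant(self):
        rng = np.random.default_rng(5)
        res = ttest_independent(rng.normal(30.1, 6.8, 136), rng.normal(21.9, 4.1, 200))
        assert res.t_p < 0.001

    def test_too_small_group_raises(self):
        with pytest.raises(StatsError):
            ttest_independent([1.0], [1.0, 2.0])

    def test_chi_square_equal_proportions(self):
        res = chi_square_proportions(20, 100, 20, 100)
        assert res.chi2_stat == 0.0 and res.chi2_p == pytest.approx(1.0)

    def test_chi_square_sex_balance_not_significant(self):
        # 39.7% vs 41.0% male in groups of 136 and 200.
        res = chi_square_proportions(54, 136, 82, 200)
        assert res.chi2_p > 0.05

    def test_chi_square_matches_direct_formula(self, rng):
        for _ in range(30):
            n1, n2 = int(rng.integers(5, 200)), int(rng.integers(5, 200))
            k1, k2 = int(rng.integers(1, n1)), int(rng.integers(1, n2))
            res = chi_square_proportions(k1, n1, k2, n2)
            obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
            exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            assert res.chi2_stat == pytest.approx(((obs - exp) ** 2 / exp).sum(), abs=1e-10)
            ref = sps.chi2_contingency(obs, correction=False)
            assert res.chi2_stat == pytest.approx(ref.statistic, abs=1e-10)
            assert res.chi2_p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_margin_raises(self):
        with pytest.raises(StatsError):
            chi_square_proportions(0, 10, 0, 10)


class TestBinormalTheory:
    def test_equal_variance_optimum_is_midpoint(self):
        assert binormal_youden_cutoff(10, 2, 4, 2) == pytest.approx(7.0)

    def test_optimum_is_stationary_maximum(self):
        for mu_p, sd_p, mu_n, sd_n in [(30.1, 6.8, 21.9, 4.1), (26.5, 6.0, 18.7, 4.7)]:
            t = binormal_youden_cutoff(mu_p, sd_p, mu_n, sd_n)

            def j(x):
                return sps.norm.sf(x, mu_p, sd_p) + sps.norm.cdf(x, mu_n, sd_n) - 1

            grid = np.linspace(mu_n - 3 * sd_n, mu_p + 3 * sd_p, 4001)
            assert j(t) >= max(j(g) for g in grid) - 1e-6
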