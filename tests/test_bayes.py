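import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import mannwhitneyu

from osteoproba import bayes
from osteoproba.bayes import ModelInput, PriorSpec, SamplerSettings

FAST = SamplerSettings(n_walkers=16, n_draws=600, n_warmup=600, seed=0)


def separable_input(n=30, seed=0):
    rng = np.random.default_rng(seed)
    ratios = np.concatenate(
        [rng.uniform(0.75, 0.95, n // 2), rng.uniform(0.1, 0.45, n - n // 2)]
    )
    labels = (ratios > 0.7).astype(int)
    return ModelInput([f"S{i}" for i in range(n)], ratios, labels, "species")


def simulate_input(alpha, beta, n=56, seed=0):
    rng = np.random.default_rng(seed)
    ratios = np.clip(rng.beta(4, 1.5, n), 0, 1)
    p = expit(alpha + beta * ratios)
    labels = rng.binomial(1, p)
    return ModelInput([f"S{i}" for i in range(n)], ratios, labels, "species")


class TestModelInput:
    def test_validation(self):
        with pytest.raises(ValueError):
            ModelInput(["a"], np.array([1.5]), np.array([1]))
        with pytest.raises(ValueError):
            ModelInput(["a", "b"], np.array([0.5, 0.5]), np.array([0, 2]))

    def test_drop(self):
        mi = separable_input(5)
        sub = mi.drop(2)
        assert len(sub) == 4 and "S2" not in sub.sample_ids


class TestFit:
    def test_separable_input_gives_positive_slope(self):
        fit = bayes.fit(separable_input(seed=1), settings=FAST)
        assert np.mean(fit.beta_flat > 0) > 0.95

    def test_null_input_slope_covers_zero(self):
        rng = np.random.default_rng(2)
        mi = ModelInput(
            [f"S{i}" for i in range(60)],
            rng.uniform(0, 1, 60),
            rng.binomial(1, 0.5, 60),
        )
        fit = bayes.fit(mi, settings=FAST)
        lo, hi = np.percentile(fit.beta_flat, [2.5, 97.5])
        assert lo < 0 < hi

    def test_reproducible_given_seed(self):
        a = bayes.fit(separable_input(), settings=FAST)
        b = bayes.fit(separable_input(), settings=FAST)
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.beta, b.beta)

    def test_degenerate_all_one_label_warns_not_crashes(self):
        mi = ModelInput(["a", "b", "c"], np.array([0.2, 0.5, 0.9]), np.array([1, 1, 1]))
        with pytest.warns(UserWarning, match="all labels identical"):
            fit = bayes.fit(mi, settings=FAST)
        assert np.all(np.isfinite(fit.alpha_flat))

    def test_minimal_two_samples(self):
        mi = ModelInput(["a", "b"], np.array([0.2, 0.9]), np.array([0, 1]))
        fit = bayes.fit(mi, settings=FAST)
        assert fit.beta_flat.std() > 1.0  # wide posterior at n=2

    def test_diagnostics_recorded(self):
        fit = bayes.fit(separable_input(), settings=FAST)
        assert {"rhat_alpha", "rhat_beta", "ess_alpha", "ess_beta"} <= set(fit.diagnostics)


class TestPredictProb:
    @staticmethod
    def fixed_fit(alpha, beta):
        mi = separable_input(6)
        a = np.full((2, 5), float(alpha))
        b = np.full((2, 5), float(beta))
        return bayes.LogisticFit(a, b, mi, PriorSpec(), SamplerSettings())

    def test_zero_draws_give_half(self):
        assert bayes.predict_prob(self.fixed_fit(0, 0), 0.3)["mean"] == pytest.approx(0.5)

    def test_closed_form(self):
        out = bayes.predict_prob(self.fixed_fit(-4, 8), 0.75)
        assert out["mean"] == pytest.approx(expit(2.0))  # ~0.881

    def test_matches_direct_evaluation_on_random_draws(self):
        rng = np.random.default_rng(5)
        fit = self.fixed_fit(0, 0)
        fit.alpha = rng.normal(size=(2, 50))
        fit.beta = rng.normal(size=(2, 50))
        r = 0.42
        expected = expit(fit.alpha_flat + fit.beta_flat * r)
        out = bayes.predict_prob(fit, r)
        np.testing.assert_allclose(out["draws"], expected, rtol=0, atol=0)
        assert out["mean"] == pytest.approx(expected.mean())

    def test_ratio_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bayes.predict_prob(self.fixed_fit(0, 1), 1.2)

    def test_curve_monotone_when_all_beta_positive(self):
        curve = bayes.probability_curve(self.fixed_fit(-2, 5), grid_size=51)
        assert len(curve) == 51
        assert (np.diff(curve["mean_p"]) >= 0).all()
        eps = 1e-12  # constant draws: interval collapses onto the mean
        assert ((curve["lower"] <= curve["mean_p"] + eps)
                & (curve["mean_p"] <= curve["upper"] + eps)).all()


class TestRocAuc:
    def test_perfect_and_inverted(self):
        labels = [0, 0, 1, 1]
        assert bayes.roc_auc([0.1, 0.2, 0.8, 0.9], labels)["auc"] == 1.0
        assert bayes.roc_auc([0.9, 0.8, 0.2, 0.1], labels)["auc"] == 0.0

    def test_random_predictions_near_half(self):
        rng = np.random.default_rng(8)
        preds = rng.uniform(size=2000)
        labels = rng.binomial(1, 0.5, 2000)
        assert bayes.roc_auc(preds, labels)["auc"] == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            bayes.roc_auc([0.1, 0.9], [1, 1])

    def test_equals_mann_whitney_u(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            preds = rng.normal(size=40) + np.repeat([0, 0.8], 20)
            preds[rng.integers(0, 40, 5)] = 0.5  # inject ties
            labels = np.repeat([0, 1], 20)
            auc = bayes.roc_auc(preds, labels)["auc"]
            u = mannwhitneyu(preds[labels == 1], preds[labels == 0]).statistic
            assert auc == pytest.approx(u / (20 * 20))


class TestExactLoo:
    def test_refit_count_and_reproducibility(self):
        mi = separable_input(6, seed=3)
        a = bayes.exact_loo(mi, settings=FAST)
        b = bayes.exact_loo(mi, settings=FAST)
        assert len(a) == 6
        pd.testing.assert_frame_equal(a, b)

    def test_refit_equivalence_with_manual_drop(self):
        mi = separable_input(6, seed=4)
        loo = bayes.exact_loo(mi, settings=FAST)
        from dataclasses import replace

        manual_fit = bayes.fit(mi.drop(0), settings=replace(FAST, seed=FAST.seed + 0))
        pred = bayes.predict_prob(manual_fit, float(mi.ratios[0]))
        assert loo.iloc[0]["mean_p"] == pytest.approx(pred["mean"])

    def test_separable_cohort_held_out_means(self):
        mi = separable_input(24, seed=5)
        loo = bayes.exact_loo(mi, settings=FAST)
        ones = loo[loo["label"] == 1]["mean_p"]
        zeros = loo[loo["label"] == 0]["mean_p"]
        assert ones.mean() > 0.8 and zeros.mean() < 0.3
        assert bayes.roc_auc(loo["mean_p"], loo["label"])["auc"] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            bayes.exact_loo(separable_input(2), settings=FAST)


class TestPsisLooCompare:
    def test_self_comparison_zero_difference(self):
        fit = bayes.fit(separable_input(seed=6), settings=FAST)
        comp = bayes.psis_loo_compare({"a": fit, "b": fit})
        dcol = "elpd_diff" if "elpd_diff" in comp.columns else "d_loo"
        assert comp[dcol].abs().max() == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_samples_rejected(self):
        f1 = bayes.fit(separable_input(10, seed=1), settings=FAST)
        f2 = bayes.fit(separable_input(12, seed=1), settings=FAST)
        with pytest.raises(ValueError):
            bayes.psis_loo_compare({"a": f1, "b": f2})

    def test_cleaner_covariate_ranks_best(self):
        # same labels; the "spectra" covariate separates them, the "peptide"
        # covariate is the same signal with heavy noise
        rng = np.random.default_rng(12)
        n = 40
        labels = np.repeat([1, 0], [30, 10])
        clean = np.clip(np.where(labels, rng.normal(0.8, 0.05, n), rng.normal(0.35, 0.05, n)), 0, 1)
        noisy = np.clip(clean + rng.normal(0, 0.25, n), 0, 1)
        ids = [f"S{i}" for i in range(n)]
        f_clean = bayes.fit(ModelInput(ids, clean, labels), settings=FAST)
        f_noisy = bayes.fit(ModelInput(ids, noisy, labels), settings=FAST)
        comp = bayes.psis_loo_compare({"spectra": f_clean, "peptide": f_noisy})
        assert comp.index[0] == "spectra"

    def test_psis_agrees_with_exact_loo_within_se(self):
        mi = simulate_input(-3.0, 6.0, n=30, seed=13)
        fit = bayes.fit(mi, settings=FAST)
        idata = fit.to_inference_data()
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            psis = az.loo(idata, pointwise=True, scale="deviance")
        loo = bayes.exact_loo(mi, settings=FAST)
        # exact elpd: log of held-out predictive density at the observed label
        p = loo["mean_p"].to_numpy()
        y = loo["label"].to_numpy()
        exact_dev = -2 * np.sum(np.log(np.where(y == 1, p, 1 - p)))
        assert abs(float(psis.elpd_loo) - exact_dev) < float(psis.se)


def test_parameter_recovery_interval_coverage():
    """95% credible intervals cover the generating (alpha, beta) in >= 18/20
    replicates at n = 56."""
    alpha_true, beta_true = -2.0, 5.0
    covered = 0
    for rep in range(20):
        mi = simulate_input(alpha_true, beta_true, n=56, seed=100 + rep)
        fit = bayes.fit(mi, settings=SamplerSettings(n_walkers=16, n_draws=700, n_warmup=700, seed=rep))
        a_lo, a_hi = np.percentile(fit.alpha_flat, [2.5, 97.5])
        b_lo, b_hi = np.percentile(fit.beta_flat, [2.5, 97.5])
        covered += int(a_lo <= alpha_true <= a_hi and b_lo <= beta_true <= b_hi)
    assert covered >= 18
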