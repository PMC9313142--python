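import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from psma_percist import phantom, stats

from oracles import brute_force_roc, cox_partial_loglik, logistic_loglik


class TestRocCutoffs:
    def test_perfectly_separable(self):
        roc = stats.roc_cutoffs([5, 10, 1, 2], [True, True, False, False])
        assert roc.auc == 1.0
        assert 2 < roc.cutoff_youden <= 5
        assert roc.sens_youden == 1.0 and roc.spec_youden == 1.0

    def test_uninformative_scores(self):
        roc = stats.roc_cutoffs([3.0] * 10, [True] * 5 + [False] * 5)
        assert roc.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stats.roc_cutoffs([1, 2, 3], [True, True, True])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_thresholds_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        scores = np.round(rng.normal(labels * 1.0, 1.0), 2)  # rounding forces ties
        roc = stats.roc_cutoffs(scores, labels)
        auc, cut_y, sens_y, spec_y, cut_m, sens_m = brute_force_roc(scores, labels)
        assert roc.auc == pytest.approx(auc)
        assert roc.cutoff_youden == pytest.approx(cut_y)
        assert roc.sens_youden == pytest.approx(sens_y)
        assert roc.spec_youden == pytest.approx(spec_y)
        assert roc.cutoff_minspec == pytest.approx(cut_m)
        assert roc.sens_minspec == pytest.approx(sens_m)

    def test_youden_index_is_maximal_at_reported_cutoff(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        labels[:3] = True
        labels[-3:] = False
        roc = stats.roc_cutoffs(scores, labels)
        j_best = roc.sens_youden + roc.spec_youden - 1
        assert j_best == pytest.approx((roc.sensitivities + roc.specificities - 1).max())


class TestBootstrapCorrectedAuc:
    def test_separable_data_keeps_auc_one(self):
        scores = np.r_[np.linspace(5, 8, 40), np.linspace(0, 3, 40)]
        labels = np.r_[np.ones(40, bool), np.zeros(40, bool)]
        corrected, apparent = stats.bootstrap_corrected_auc(scores, labels, B=50, seed=0)
        assert apparent == 1.0
        assert corrected == pytest.approx(1.0, abs=0.01)

    def test_correction_removes_optimism_on_noise(self):
        """On pure-noise data the corrected AUC should drop toward 0.5 and
        never exceed the apparent AUC by more than Monte-Carlo jitter."""
        rng = np.random.default_rng(1)
        worse = 0
        for rep in range(20):
            scores = rng.normal(size=40)
            labels = rng.random(40) < 0.5
            if labels.all() or not labels.any():
                labels[0] = ~labels[0]
            corrected, apparent = stats.bootstrap_corrected_auc(
                scores, labels, B=60, seed=rep
            )
            if corrected > apparent + 0.02:
                worse += 1
        assert worse <= 1

    def test_seeded_reproducibility(self):
        scores = np.arange(20.0)
        labels = np.r_[np.zeros(10, bool), np.ones(10, bool)]
        a = stats.bootstrap_corrected_auc(scores, labels, B=1, seed=7)
        b = stats.bootstrap_corrected_auc(scores, labels, B=1, seed=7)
        assert a == b


def _cohort(n_patients=60, seed=0, **kw):
    spec = phantom.CohortSpec(n_patients=n_patients, seed=seed, **kw)
    lesions, patients = phantom.simulate_cohort(spec)
    lesions = lesions.assign(psma_tv_l=lesions.psma_tv / 1000.0)
    return lesions, patients


class TestFitLmm:
    def test_exp_coefficients_consistent_with_formatter(self):
        lesions, _ = _cohort()
        res = stats.fit_lmm(lesions, response="responder", covariates=("psma_tv_l", "site"))
        tbl = res.coefficients
        assert np.allclose(tbl["exp_coef"], np.exp(tbl["coef"]))
        assert (tbl["ci_low"] <= tbl["ci_high"]).all()
        # log-scale 0.59 formats as ratio 1.80 under the report formatter
        assert stats.format_value(math.exp(0.59), 2) == "1.80"

    def test_tau_zero_matches_ols(self):
        """With no between-patient variance the mixed model collapses to the
        fixed-effects regression (boundary estimate of tau^2 near zero)."""
        lesions, _ = _cohort(n_patients=100, tau=0.0, sigma=0.2, seed=5)
        res = stats.fit_lmm(lesions, response="responder", covariates=("psma_tv_l", "site"))
        import statsmodels.formula.api as smf

        ols = smf.ols(
            "log_suv_peak ~ C(responder) + psma_tv_l + C(site)", lesions
        ).fit()
        assert res.tau2 == pytest.approx(0.0, abs=5e-3)
        got = res.coefficients.loc["C(responder)[T.True]", "coef"]
        assert got == pytest.approx(ols.params["C(responder)[T.True]"], abs=5e-3)

    def test_categorical_response_uses_ipd_reference(self):
        lesions, _ = _cohort(seed=2)
        res = stats.fit_lmm(lesions, response="response", covariates=("psma_tv_l", "site"))
        terms = res.coefficients.index
        assert any("iPR" in t for t in terms)
        assert not any("[T.iPD]" in t for t in terms)  # iPD is the reference

    def test_lrt_against_null_model(self):
        lesions, _ = _cohort(seed=3)
        res = stats.fit_lmm(lesions, response="responder", covariates=("psma_tv_l", "site"))
        assert res.lrt_df == 1
        assert 0 <= res.lrt_p < 0.05  # strong true effect
        null_like, _ = _cohort(responder_log_ratio=0.0, seed=4)
        res0 = stats.fit_lmm(null_like, response="responder", covariates=("psma_tv_l", "site"))
        assert res0.lrt_p > 1e-4

    def test_interaction_and_singularity_error(self):
        lesions, _ = _cohort(seed=6)
        res = stats.fit_lmm(
            lesions, response="responder", covariates=("psma_tv_l", "site"),
            interaction=True,
        )
        assert any(":" in t for t in res.coefficients.index)
        dup = lesions.assign(psma_tv_twice=lesions.psma_tv_l * 2.0)
        with pytest.raises(ValueError, match="collinear|singular"):
            stats.fit_lmm(
                dup, response="responder",
                covariates=("psma_tv_l", "psma_tv_twice", "site"),
            )


class TestGeometricMeans:
    def test_log_symmetry(self):
        gm = stats.geometric_means([1.0, 10.0, 100.0], ["a"] * 3)
        assert gm.loc["a", "geometric_mean"] == pytest.approx(10.0)

    def test_single_value_degenerate(self):
        gm = stats.geometric_means([7.0], ["a"])
        assert gm.loc["a", "geometric_mean"] == pytest.approx(7.0)
        assert gm.loc["a", "degenerate"]
        assert math.isnan(gm.loc["a", "ci_low"])

    def test_matches_independent_rederivation(self, rng):
        values = rng.lognormal(1.0, 0.5, size=50)
        gm = stats.geometric_means(values, ["g"] * 50)
        logs = np.log(values)
        assert gm.loc["g", "geometric_mean"] == pytest.approx(math.exp(logs.mean()))
        from scipy import stats as sps

        half = sps.t.ppf(0.975, 49) * logs.std(ddof=1) / math.sqrt(50)
        assert gm.loc["g", "ci_low"] == pytest.approx(math.exp(logs.mean() - half))
        assert gm.loc["g", "ci_high"] == pytest.approx(math.exp(logs.mean() + half))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            stats.geometric_means([1.0, 0.0], ["a", "a"])


class TestLogisticLrt:
    def _toy(self):
        # 12-row table with a real but imperfect signal
        return pd.DataFrame(
            {
                "y": [0, 0, 0, 0, 0, 1, 0, 0, 1, 1, 1, 1],
                "x": [0.1, 0.5, 0.9, 1.3, 2.0, 1.8, 2.2, 2.6, 3.0, 3.3, 3.9, 4.1],
                "psma_tv": [0.2, 0.9, 0.4, 1.1, 0.7, 0.9, 1.4, 0.8, 0.5, 1.2, 0.6, 1.0],
            }
        )

    def test_lrt_statistic_matches_direct_likelihood_evaluation(self):
        """2*(l1 - l0) recomputed by maximizing the hand-written Bernoulli
        likelihood must agree with the reported statistic."""
        from scipy.optimize import minimize

        df = self._toy()
        res = stats.logistic_lrt(df, "x", "y", covariate="psma_tv")
        y = df.y.to_numpy(float)
        X1 = np.column_stack([np.ones(12), df.x, df.psma_tv])
        X0 = np.column_stack([np.ones(12), df.psma_tv])
        l1 = -minimize(lambda b: -logistic_loglik(b, X1, y), np.zeros(3), method="BFGS").fun
        l0 = -minimize(lambda b: -logistic_loglik(b, X0, y), np.zeros(2), method="BFGS").fun
        assert res.lrt_statistic == pytest.approx(2 * (l1 - l0), abs=1e-4)
        assert not res.separation

    def test_null_variable_large_sample(self):
        rng = np.random.default_rng(8)
        n = 4000
        df = pd.DataFrame(
            {
                "y": rng.random(n) < 0.5,
                "x": rng.normal(size=n),
                "psma_tv": rng.lognormal(0, 0.5, n),
            }
        )
        res = stats.logistic_lrt(df, "x", "y")
        assert res.odds_ratio == pytest.approx(1.0, abs=0.1)
        assert res.lrt_p > 0.001

    def test_perfect_predictor_flags_separation(self):
        rng = np.random.default_rng(9)
        y = np.r_[np.zeros(15), np.ones(15)].astype(int)
        df = pd.DataFrame({"y": y, "x": y.astype(float), "psma_tv": rng.lognormal(0, 0.5, 30)})
        res = stats.logistic_lrt(df, "x", "y")
        assert res.separation
        assert res.odds_ratio > 100  # mirrors the extreme-odds-ratio behavior
        assert res.lrt_p < 0.001  # LRT is still reported at the boundary

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"y": [1, 1, 1], "x": [1.0, 2.0, 3.0], "psma_tv": [1.0] * 3})
        with pytest.raises(ValueError):
            stats.logistic_lrt(df, "x", "y")


class TestKmLogrank:
    def test_hand_product_limit_no_censoring(self):
        res = stats.km_logrank(
            [1, 2, 3, 4, 1, 2, 3, 4], [True] * 8, ["a"] * 4 + ["b"] * 4
        )
        curve = res.km_curves["a"]
        assert curve.survival.to_numpy() == pytest.approx([1.0, 0.75, 0.5, 0.25, 0.0])
        assert res.medians["a"] == 2.0
        assert res.logrank_p == 1.0  # identical groups: statistic 0

    def test_km_equals_one_minus_ecdf_without_censoring(self, rng):
        times = rng.exponential(10, size=30).round(1)
        res = stats.km_logrank(
            np.r_[times, [1.0]], [True] * 31, ["a"] * 30 + ["b"]
        )
        curve = res.km_curves["a"].set_index("time").survival
        for t in times:
            assert curve.loc[t] == pytest.approx(1.0 - (times <= t).mean())

    def test_hand_computed_censored_product_limit(self):
        """10-subject set checked against the manual product-limit table.

        Risk sets/events: t=2 (10, 1), t=4 (8, 1), t=6 (5, 2), t=9 (2, 1);
        censoring at 3, 5, 5, 8 and 10.
        """
        times = [2, 3, 4, 5, 5, 6, 6, 8, 9, 10]
        events = [1, 0, 1, 0, 0, 1, 1, 0, 1, 0]
        res = stats.km_logrank(
            times + [1], [bool(e) for e in events] + [True], ["a"] * 10 + ["b"]
        )
        curve = res.km_curves["a"].set_index("time").survival
        assert curve.loc[2] == pytest.approx(9 / 10)
        assert curve.loc[4] == pytest.approx(9 / 10 * 7 / 8)
        assert curve.loc[6] == pytest.approx(9 / 10 * 7 / 8 * 3 / 5)
        assert curve.loc[9] == pytest.approx(9 / 10 * 7 / 8 * 3 / 5 * 1 / 2)

    def test_all_censored_group_median_not_reached(self):
        res = stats.km_logrank(
            [5, 6, 7, 1, 2, 3], [False] * 3 + [True] * 3, ["a"] * 3 + ["b"] * 3
        )
        assert math.isinf(res.medians["a"])


class TestCoxUnivariate:
    def test_null_covariate_large_sample(self, rng):
        n = 500
        x = rng.normal(size=n)
        times = rng.exponential(10, size=n)
        res = stats.cox_univariate(times, np.ones(n, bool), x)
        assert res.table["hr"].iloc[0] == pytest.approx(1.0, abs=0.15)
        assert not res.monotone_likelihood

    def test_recovers_true_hazard_ratio(self, rng):
        n = 500
        x = rng.random(n) < 0.5
        lam = 0.1 * np.where(x, 2.0, 1.0)  # true HR 2 for x=1
        times = rng.exponential(1.0 / lam)
        cens = rng.uniform(0, 30, n)
        obs = np.minimum(times, cens)
        events = times <= cens
        res = stats.cox_univariate(obs, events, x.astype(bool), name="arm")
        coef = res.table["coef"].iloc[0]
        se = (np.log(res.table["ci_high"].iloc[0]) - coef) / 1.959964
        assert abs(coef - math.log(2.0)) < 3 * se

    def test_maximizes_hand_written_partial_likelihood(self):
        """Four subjects, no ties: the fitted coefficient must maximize the
        independently coded partial likelihood."""
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([True, True, True, False])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        res = stats.cox_univariate(times, events, x)
        beta_hat = res.table["coef"].iloc[0]
        opt = minimize_scalar(
            lambda b: -cox_partial_loglik(b, times, events, x), bounds=(-5, 5),
            method="bounded",
        )
        assert beta_hat == pytest.approx(opt.x, abs=1e-3)

    def test_monotone_likelihood_flagged(self):
        # two subjects, both events, perfectly ranked by the covariate
        res = stats.cox_univariate([1.0, 2.0], [True, True], [1.0, 0.0])
        assert res.monotone_likelihood

    def test_categorical_reference_coding(self, rng):
        n = 90
        level = pd.Categorical(
            rng.choice(["low", "mid", "high"], n), categories=["low", "mid", "high"]
        )
        times = rng.exponential(10, n)
        res = stats.cox_univariate(times, np.ones(n, bool), level, name="grade")
        assert set(res.table.index) == {"grade_mid", "grade_high"}  # "low" is ref
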