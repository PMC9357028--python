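"""Factor-model library, (FI)ML estimation, fit indices, nested tests, scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from triarchy import cfa
from conftest import simulate_cs_scores

EXPECTED_DF = {
    "I+U+S": 24, "S/I+U": 26, "U/I+S": 26, "S/U+I": 26, "G": 27,
    "C+I+U+S": 18, "C+I+S": 21, "C+I+U": 21, "C+U+S": 21,
    "C+I": 24, "C+S": 24, "C+U": 24,
}


class TestModelLibrary:
    def test_twelve_models(self):
        assert len(cfa.model_library()) == 12

    def test_one_factor_model_loads_all_indicators(self):
        g = cfa.model_library()["G"]
        assert g.n_factors == 1 and g.factors["G"] == cfa.INDICATORS

    def test_bifactor_structure(self):
        cs = cfa.model_library()["C+S"]
        assert cs.orthogonal
        assert cs.factors["C"] == cfa.INDICATORS
        assert cs.factors["S"] == cfa.SHIFTING

    @pytest.mark.parametrize("name,df", EXPECTED_DF.items())
    def test_degrees_of_freedom(self, name, df):
        assert cfa.model_degrees_of_freedom(cfa.model_library()[name]) == df

    def test_df_plus_params_is_45(self):
        for spec in cfa.model_library().values():
            q = spec.n_free_loadings + 9 + spec.n_free_correlations
            assert cfa.model_degrees_of_freedom(spec) + q == 45


class TestFitCFA:
    def test_parameter_recovery_large_n(self, cs_truth):
        spec, L, theta = cs_truth
        rng = np.random.default_rng(0)
        scores, _ = simulate_cs_scores(L, theta, 50_000, rng)
        fit = cfa.fit_cfa(scores, spec, compute_se=False)
        pat = spec.loading_pattern()
        assert fit.converged
        assert np.max(np.abs(fit.loadings.to_numpy()[pat] - L[pat])) < 0.02

    def test_fiml_equals_complete_ml_on_complete_data(self, cs_sample):
        spec, L, theta, scores, _ = cs_sample
        fit_c = cfa.fit_cfa(scores, spec, missing="listwise", compute_se=False)
        fit_f = cfa.fit_cfa(scores, spec, missing="fiml", compute_se=False)
        assert fit_f.loglik == pytest.approx(fit_c.loglik, abs=1e-6)

    def test_fiml_handles_missing_rows(self, cs_truth):
        spec, L, theta = cs_truth
        rng = np.random.default_rng(5)
        scores, _ = simulate_cs_scores(L, theta, 1500, rng, missing_rate=0.1)
        fit = cfa.fit_cfa(scores, spec, missing="fiml", compute_se=False)
        assert fit.converged and fit.n_used == 1500
        pat = spec.loading_pattern()
        assert np.max(np.abs(fit.loadings.to_numpy()[pat] - L[pat])) < 0.15

    def test_direct_numerical_maximization_oracle(self, cs_truth):
        """Independent multi-start optimization reaches the same maximum logL."""
        spec, L, theta = cs_truth
        rng = np.random.default_rng(9)
        scores, _ = simulate_cs_scores(L, theta, 400, rng)
        fit = cfa.fit_cfa(scores, spec, compute_se=False)
        X = scores.to_numpy()
        n, p = X.shape
        S = np.cov(X, rowvar=False, ddof=0)
        pat = spec.loading_pattern()
        nl = int(pat.sum())

        def negll(thetav):
            Lm = np.zeros(pat.shape)
            Lm[pat] = thetav[:nl]
            sigma = Lm @ Lm.T + np.diag(np.exp(thetav[nl:]))
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                return np.inf
            return 0.5 * n * (p * np.log(2 * np.pi) + logdet
                              + np.trace(S @ np.linalg.inv(sigma)))

        best = np.inf
        for r in range(10):
            x0 = np.concatenate([rng.uniform(0.2, 0.8, nl), np.log(rng.uniform(0.3, 0.9, p))])
            res = optimize.minimize(negll, x0, method="L-BFGS-B",
                                    options={"maxiter": 2000, "ftol": 1e-13})
            best = min(best, res.fun)
        assert fit.loglik == pytest.approx(-best, abs=1e-5)

    def test_monotone_loglik_under_nesting(self, cs_sample):
        spec, L, theta, scores, _ = cs_sample
        lib = cfa.model_library()
        ll_restricted = cfa.fit_cfa(scores, lib["C+S"], compute_se=False).loglik
        ll_full = cfa.fit_cfa(scores, lib["C+U+S"], compute_se=False).loglik
        assert ll_full >= ll_restricted - 1e-6

    def test_loading_se_and_p_reported(self, cs_sample):
        spec, L, theta, scores, _ = cs_sample
        fit = cfa.fit_cfa(scores, spec, compute_se=True)
        pat = spec.loading_pattern()
        assert np.isfinite(fit.loading_se.to_numpy()[pat]).all()
        assert (fit.loading_p.to_numpy()[pat] < 0.05).all()  # strong true loadings


class TestFitIndices:
    def test_perfect_fit_limits(self, cs_sample):
        spec, L, theta, scores, _ = cs_sample
        fit = cfa.fit_cfa(scores, spec, compute_se=False)
        fit_forced = fit
        fit_forced.chisq = float(fit.df)  # chi^2 = df
        fi = cfa.fit_indices(fit_forced, scores)
        assert fi.rmsea == pytest.approx(0.0)
        assert fi.cfi == pytest.approx(1.0)

    def test_good_fit_for_generating_model(self, cs_sample):
        spec, L, theta, scores, _ = cs_sample
        fit = cfa.fit_cfa(scores, spec, compute_se=False)
        fi = cfa.fit_indices(fit, scores)
        assert fi.cfi > 0.95 and fi.rmsea < 0.05 and fi.srmr < 0.05

    def test_misfit_detected_for_wrong_model(self, cs_sample):
        spec, L, theta, scores, _ = cs_sample
        g = cfa.model_library()["G"]
        fit = cfa.fit_cfa(scores, g, compute_se=False)
        fi = cfa.fit_indices(fit, scores)
        assert fi.cfi < 0.95

    def test_aic_bic_ordering_prefers_true_model(self, cs_sample):
        spec, L, theta, scores, _ = cs_sample
        lib = cfa.model_library()
        fi_cs = cfa.fit_indices(cfa.fit_cfa(scores, lib["C+S"], compute_se=False), scores)
        fi_g = cfa.fit_indices(cfa.fit_cfa(scores, lib["G"], compute_se=False), scores)
        assert fi_cs.bic < fi_g.bic


class TestChisqDiff:
    def test_identical_models(self, cs_sample):
        spec, L, theta, scores, _ = cs_sample
        fit = cfa.fit_cfa(scores, spec, compute_se=False)
        d_chi, d_df, p, warn = cfa.chisq_diff_test(fit, fit)
        assert d_chi == 0.0 and p == 1.0

    def test_printed_tail_value(self):
        # a chi^2 difference of 33.24 on 2 df has an upper tail near 6.07e-8
        assert stats.chi2.sf(33.24, 2) == pytest.approx(6.07e-8, rel=0.01)

    def test_type_one_error_calibrated(self, cs_truth):
        spec, L, theta = cs_truth
        lib = cfa.model_library()
        rng = np.random.default_rng(17)
        rejections = 0
        n_sims = 120
        for _ in range(n_sims):
            scores, _ = simulate_cs_scores(L, theta, 600, rng)
            fit_r = cfa.fit_cfa(scores, lib["C+S"], compute_se=False)
            fit_f = cfa.fit_cfa(scores, lib["C+U+S"], compute_se=False)
            _, _, p, _ = cfa.chisq_diff_test(fit_r, fit_f)
            rejections += p < 0.05
        assert 0.01 <= rejections / n_sims <= 0.12

    def test_reversed_nesting_rejected(self, cs_sample):
        spec, L, theta, scores, _ = cs_sample
        lib = cfa.model_library()
        fit_r = cfa.fit_cfa(scores, lib["C+S"], compute_se=False)
        fit_f = cfa.fit_cfa(scores, lib["C+U+S"], compute_se=False)
        with pytest.raises(ValueError):
            cfa.chisq_diff_test(fit_f, fit_r)


class TestFactorScores:
    def test_single_indicator_identity(self):
        """lambda=1, Theta~0 one-factor model: the score is the indicator itself."""
        spec = cfa.ModelSpec(name="one", factors={"F": ["antisaccade"]},
                             orthogonal=True, indicators=["antisaccade"])
        fit = cfa.CFAFit(
            spec=spec,
            loadings=pd.DataFrame([[1.0]], index=["antisaccade"], columns=["F"]),
            factor_corr=pd.DataFrame([[1.0]], index=["F"], columns=["F"]),
            residual_var=pd.Series([1e-12], index=["antisaccade"]),
            mu=np.zeros(1), loglik=0, loglik_saturated=0, chisq=0, df=0,
            n_used=3, n_params=2, converged=True, missing="fiml",
        )
        x = pd.DataFrame({"antisaccade": [-1.0, 0.0, 2.0]})
        out = cfa.factor_scores(fit, x)
        assert np.allclose(out["F"], x["antisaccade"], atol=1e-6)

    def test_determinacy_of_common_factor(self, cs_sample):
        spec, L, theta, scores, f = cs_sample
        fit = cfa.fit_cfa(scores, spec, compute_se=False)
        out = cfa.factor_scores(fit, scores)
        assert np.corrcoef(out["C"], f[:, 0])[0, 1] > 0.8

    def test_deterministic_across_refits(self, cs_sample):
        spec, L, theta, scores, _ = cs_sample
        s1 = cfa.factor_scores(cfa.fit_cfa(scores, spec, compute_se=False), scores)
        s2 = cfa.factor_scores(cfa.fit_cfa(scores, spec, compute_se=False), scores)
        assert np.allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-8)

    def test_all_missing_row_gets_nan(self, cs_truth):
        spec, L, theta = cs_truth
        rng = np.random.default_rng(2)
        scores, _ = simulate_cs_scores(L, theta, 300, rng, missing_rate=0.05)
        scores.iloc[0] = np.nan
        fit = cfa.fit_cfa(scores, spec, compute_se=False)
        out = cfa.factor_scores(fit, scores)
        assert out.iloc[0].isna().all()
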