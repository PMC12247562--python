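"""Latent growth curve specs, FIML likelihood, fitting, selection."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from netgrowth.lgc import (BaselineFit, FitIndices, LGCFit, LGCSpec,
                           build_lgc_spec, ci_overlap, compute_fit_indices,
                           detect_heywood, fiml_loglik, fit_all_variants,
                           fit_baselines, fit_lgc, model_moments,
                           panel_to_arrays, params_from_dict, select_model)
from netgrowth.synthetic import PanelTruth, simulate_panel

#: independent hand count of free parameters per variant:
#: factor means + 3 covariate paths per regressed factor + free variances
#: + free covariances + one residual variance
HAND_PARAM_COUNTS = {1: 3, 2: 7, 3: 12, 4: 8, 5: 19}

V3_PARAMS = dict(mean_intercept=50.0, mean_linear=0.4,
                 age0_on_intercept=-0.28, sex_on_intercept=1.0,
                 education_on_intercept=1.5, age0_on_linear=-0.01,
                 sex_on_linear=0.0, education_on_linear=0.0,
                 var_intercept=25.0, var_linear=1.0,
                 cov_intercept_linear=0.0, resid_var=4.0)


class TestSpec:
    def test_variant1_structure(self):
        spec = build_lgc_spec(1)
        lam = spec.loadings()
        assert np.array_equal(lam[:, 0], np.ones(5))
        assert np.array_equal(lam[:, 1], [0, 1, 2, 4, 7])
        assert spec.free_variances == ()
        assert spec.covariate_factors == ()

    def test_variant5_structure(self):
        spec = build_lgc_spec(5)
        lam = spec.loadings()
        assert np.array_equal(lam[:, 2], [0, 1, 4, 16, 49])
        assert spec.free_variances == (0, 1, 2)
        assert len(spec.free_covariances) == 3
        assert spec.covariate_factors == (0, 1, 2)

    @pytest.mark.parametrize("variant", [1, 2, 3, 4, 5])
    def test_param_count_matches_hand_enumeration(self, variant):
        assert build_lgc_spec(variant).n_free_params \
            == HAND_PARAM_COUNTS[variant]

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            build_lgc_spec(6)

    def test_covariance_requires_variances(self):
        with pytest.raises(ValueError):
            LGCSpec(variant_id=0, occasions=(0, 1, 2, 4, 7), n_factors=2,
                    free_variances=(0,), free_covariances=((0, 1),),
                    covariate_factors=())


class TestModelMoments:
    def test_zero_psi_theta(self):
        spec = build_lgc_spec(1)
        params = params_from_dict(spec, dict(mean_intercept=50.0,
                                             mean_linear=1.0, resid_var=0.0))
        mean, cov = model_moments(spec, params)
        assert np.allclose(cov, 0.0)
        assert np.allclose(mean, [50, 51, 52, 54, 57])

    def test_implied_cov_psd(self):
        spec = build_lgc_spec(3)
        params = params_from_dict(spec, V3_PARAMS)
        _, cov = model_moments(spec, params)
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() >= -1e-10


def _complete_panel(n=40, seed=1):
    truth = PanelTruth.default()
    panel = simulate_panel(n, truth, 0.0, seed=seed)
    return panel_to_arrays(panel)[:2]


class TestFimlLoglik:
    def test_complete_data_equals_joint_mvn(self):
        y, X = _complete_panel()
        spec = build_lgc_spec(3)
        params = params_from_dict(spec, V3_PARAMS)
        ll = fiml_loglik(spec, params, (y, X))
        ref = sum(
            multivariate_normal.logpdf(y[i],
                                       *model_moments(spec, params, X[i]))
            for i in range(y.shape[0]))
        assert ll == pytest.approx(ref, abs=1e-8)

    def test_single_occasion_subject_marginal(self):
        spec = build_lgc_spec(3)
        params = params_from_dict(spec, V3_PARAMS)
        y = np.array([[48.0, np.nan, np.nan, np.nan, np.nan]])
        X = np.array([[2.0, 1.0, 0.0]])
        ll = fiml_loglik(spec, params, (y, X))
        mean, cov = model_moments(spec, params, X[0])
        ref = norm.logpdf(48.0, mean[0], np.sqrt(cov[0, 0]))
        assert ll == pytest.approx(ref, abs=1e-10)

    def test_subject_order_invariant(self):
        y, X = _complete_panel()
        y[3, 2] = np.nan
        spec = build_lgc_spec(2)
        params = params_from_dict(spec, dict(
            mean_intercept=50.0, mean_linear=0.3, age0_on_intercept=-0.2,
            sex_on_intercept=0.5, education_on_intercept=1.0,
            var_intercept=20.0, resid_var=5.0))
        ll = fiml_loglik(spec, params, (y, X))
        perm = np.random.default_rng(0).permutation(y.shape[0])
        ll_perm = fiml_loglik(spec, params, (y[perm], X[perm]))
        assert ll == pytest.approx(ll_perm, abs=1e-9)

    def test_singular_implied_covariance_gives_minus_inf(self):
        y, X = _complete_panel(5)
        spec = build_lgc_spec(1)
        with pytest.warns(UserWarning, match="positive definite"):
            ll = fiml_loglik(spec, np.array([50.0, 0.0, 0.0]), (y, X))
        assert ll == -np.inf

    def test_all_missing_subject_rejected(self):
        y, X = _complete_panel(5)
        y[0] = np.nan
        spec = build_lgc_spec(1)
        with pytest.raises(ValueError):
            fiml_loglik(spec, np.array([50.0, 0.0, 4.0]), (y, X))


class TestFitLgc:
    def test_fiml_equals_complete_ml_when_no_missing(self):
        y, X = _complete_panel(200, seed=3)
        fit = fit_lgc(build_lgc_spec(3), (y, X))
        assert fit.converged
        # the same maximum from a panel DataFrame path
        panel = simulate_panel(200, PanelTruth.default(), 0.0, seed=3)
        fit2 = fit_lgc(build_lgc_spec(3), panel)
        for k in fit.estimates:
            assert fit.estimates[k] == pytest.approx(fit2.estimates[k],
                                                     abs=1e-6)

    def test_deterministic_and_order_invariant(self):
        truth = PanelTruth.default()
        panel = simulate_panel(150, truth, 0.2, seed=4)
        y, X, _ = panel_to_arrays(panel)
        fit1 = fit_lgc(build_lgc_spec(2), (y, X))
        perm = np.random.default_rng(1).permutation(y.shape[0])
        fit2 = fit_lgc(build_lgc_spec(2), (y[perm], X[perm]))
        for k in fit1.estimates:
            assert fit1.estimates[k] == pytest.approx(fit2.estimates[k],
                                                      abs=1e-6)

    def test_covariate_affine_recoding(self):
        """Doubling a covariate halves its regression coefficient and leaves
        the loglik unchanged."""
        panel = simulate_panel(150, PanelTruth.default(), 0.1, seed=5)
        y, X, _ = panel_to_arrays(panel)
        fit1 = fit_lgc(build_lgc_spec(2), (y, X))
        X2 = X.copy()
        X2[:, 0] *= 2.0
        fit2 = fit_lgc(build_lgc_spec(2), (y, X2))
        assert fit2.estimates["age0_on_intercept"] == pytest.approx(
            fit1.estimates["age0_on_intercept"] / 2.0, abs=1e-5)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-6)

    def test_saturated_dominates_all_variants(self):
        panel = simulate_panel(120, PanelTruth.default(), 0.2, seed=6)
        y, X, _ = panel_to_arrays(panel)
        sat_cov, _ = fit_baselines((y, X), with_covariates=True)
        sat_nocov, _ = fit_baselines((y, X), with_covariates=False)
        for v in (1, 2, 3, 4, 5):
            fit = fit_lgc(build_lgc_spec(v), (y, X))
            sat = sat_cov if fit.has_covariates else sat_nocov
            assert sat.loglik >= fit.loglik - 1e-6


class TestBaselines:
    def test_complete_data_saturated_closed_form(self):
        y, X = _complete_panel(100, seed=7)
        sat, _ = fit_baselines((y, X), with_covariates=False)
        mu_hat = np.array([sat.estimates[f"mu_{t}"] for t in range(5)])
        assert np.allclose(mu_hat, y.mean(axis=0), atol=1e-5)
        # ML covariance (divisor n)
        resid = y - y.mean(axis=0)
        cov_ml = resid.T @ resid / y.shape[0]
        for i in range(5):
            assert sat.estimates[f"var_y{i}"] == pytest.approx(
                cov_ml[i, i], abs=1e-4)
            for j in range(i + 1, 5):
                assert sat.estimates[f"cov_y{i}_y{j}"] == pytest.approx(
                    cov_ml[i, j], abs=1e-4)

    def test_independence_below_saturated(self):
        panel = simulate_panel(100, PanelTruth.default(), 0.2, seed=8)
        sat, ind = fit_baselines(panel, with_covariates=False)
        assert ind.loglik <= sat.loglik
        assert sat.n_params == 20
        assert ind.n_params == 10

    def test_model_df_counting(self):
        """For a no-covariate model, df = 20 - k (moment counting)."""
        panel = simulate_panel(80, PanelTruth.default(), 0.0, seed=9)
        fits = fit_all_variants(panel, variants=(1,))
        assert fits[0].fit.df == 20 - HAND_PARAM_COUNTS[1]


def _fake_fit(variant=1, loglik=-100.0, heywood=False, converged=True,
              estimates=None, ses=None, indices=None):
    spec = build_lgc_spec(variant)
    est = estimates or {k: 0.0 for k in spec.param_names()}
    se = ses or {k: 1.0 for k in est}
    ci = {k: (est[k] - 1.96 * se[k], est[k] + 1.96 * se[k]) for k in est}
    fit = LGCFit(spec=spec, estimates=est, standard_errors=se, ci95=ci,
                 loglik=loglik, n_subjects=50, converged=converged,
                 heywood=heywood, fit=indices)
    return fit


def _indices(n_good, bic):
    return FitIndices(chi2=1.0, df=1, p_chi2=0.5, chi2_over_df=1.0, cfi=1.0,
                      rmsea=0.0, bic=bic, n_good_indicators=n_good)


class TestFitIndices:
    def test_model_equals_saturated(self):
        sat = BaselineFit("saturated", -100.0, 20, True)
        ind = BaselineFit("independence", -150.0, 10, True)
        fit = _fake_fit(variant=1, loglik=-100.0)
        fi = compute_fit_indices(fit, sat, ind, n_subjects=50)
        assert fi.chi2 == 0.0
        assert fi.cfi == 1.0
        assert fi.rmsea == 0.0

    def test_bic_hand_formula(self):
        sat = BaselineFit("saturated", -90.0, 20, True)
        ind = BaselineFit("independence", -150.0, 10, True)
        fit = _fake_fit(variant=1, loglik=-100.0)
        fi = compute_fit_indices(fit, sat, ind, n_subjects=50)
        assert fi.bic == pytest.approx(200.0 + 3 * np.log(50))

    def test_cfi_bounds(self, rng):
        for _ in range(30):
            ll_s = -rng.uniform(50, 150)
            ll_m = ll_s - rng.uniform(0, 60)
            ll_i = ll_m - rng.uniform(0, 60)
            sat = BaselineFit("saturated", ll_s, 20, True)
            ind = BaselineFit("independence", ll_i, 10, True)
            fi = compute_fit_indices(_fake_fit(1, ll_m), sat, ind, 40)
            assert 0.0 <= fi.cfi <= 1.0
            assert fi.chi2 >= 0.0
            assert fi.rmsea >= 0.0


class TestHeywood:
    def test_negative_variance(self):
        est = {k: 1.0 for k in build_lgc_spec(3).param_names()}
        est["var_linear"] = -0.3
        assert detect_heywood(_fake_fit(3, estimates=est))

    def test_out_of_range_correlation(self):
        est = {k: 0.0 for k in build_lgc_spec(3).param_names()}
        est.update(var_intercept=1.0, var_linear=1.0,
                   cov_intercept_linear=1.04, resid_var=1.0)
        assert detect_heywood(_fake_fit(3, estimates=est))

    def test_admissible_solution(self):
        est = {k: 0.0 for k in build_lgc_spec(3).param_names()}
        est.update(var_intercept=4.0, var_linear=1.0,
                   cov_intercept_linear=1.5, resid_var=2.0)
        assert not detect_heywood(_fake_fit(3, estimates=est))


class TestSelectModel:
    def test_most_good_indicators_wins(self):
        fits = [_fake_fit(1, indices=_indices(5, 1000.0)),
                _fake_fit(2, indices=_indices(0, 900.0)),
                _fake_fit(3, indices=_indices(1, 800.0))]
        assert select_model(fits).selected_variant == 1

    def test_bic_breaks_ties(self):
        fits = [_fake_fit(1, indices=_indices(4, 1000.0)),
                _fake_fit(2, indices=_indices(4, 990.0))]
        assert select_model(fits).selected_variant == 2

    def test_heywood_disqualifies_best_bic(self):
        fits = [_fake_fit(1, indices=_indices(4, 990.0), heywood=True),
                _fake_fit(2, indices=_indices(4, 1000.0))]
        assert select_model(fits).selected_variant == 2

    def test_nonconverged_disqualified(self):
        fits = [_fake_fit(1, indices=_indices(5, 990.0), converged=False),
                _fake_fit(2, indices=_indices(1, 1000.0))]
        assert select_model(fits).selected_variant == 2

    def test_all_disqualified_raises(self):
        fits = [_fake_fit(1, heywood=True, indices=_indices(5, 1.0))]
        with pytest.raises(ValueError):
            select_model(fits)


class TestCiOverlap:
    def test_identical_intervals(self):
        a = _fake_fit(3)
        assert ci_overlap(a, a, "mean_linear") is True

    def test_disjoint(self):
        a = _fake_fit(3, estimates={k: 0.0 for k in
                                    build_lgc_spec(3).param_names()},
                      ses={k: 0.1 for k in build_lgc_spec(3).param_names()})
        b = _fake_fit(3, estimates={k: 10.0 for k in
                                    build_lgc_spec(3).param_names()},
                      ses={k: 0.1 for k in build_lgc_spec(3).param_names()})
        assert ci_overlap(a, b, "mean_linear") is False

    def test_shared_endpoint_counts_as_overlap(self):
        names = build_lgc_spec(3).param_names()
        a = _fake_fit(3, estimates={k: 0.5 for k in names},
                      ses={k: 0.5 / 1.96 for k in names})   # CI (0, 1)
        b = _fake_fit(3, estimates={k: 1.5 for k in names},
                      ses={k: 0.5 / 1.96 for k in names})   # CI (1, 2)
        assert ci_overlap(a, b, "mean_linear") is True

    def test_absent_parameter_not_comparable(self):
        a = _fake_fit(5)  # quadratic model
        b = _fake_fit(3)  # linear model
        assert ci_overlap(a, b, "mean_quadratic") == "not comparable"


class TestRecovery:
    def test_variant3_estimates_near_truth_large_n(self):
        truth = PanelTruth([50.0, 0.4], [[25.0, 0.0], [0.0, 1.0]], 4.0,
                           [[-0.28, 1.0, 1.5], [-0.01, 0.0, 0.0]])
        panel = simulate_panel(2000, truth, 0.15, seed=10)
        fit = fit_lgc(build_lgc_spec(3), panel)
        assert fit.converged and not fit.heywood
        assert fit.estimates["mean_intercept"] == pytest.approx(50.0,
                                                                abs=0.5)
        assert fit.estimates["mean_linear"] == pytest.approx(0.4, abs=0.12)
        assert fit.estimates["var_intercept"] == pytest.approx(25.0, rel=0.15)
        assert fit.estimates["var_linear"] == pytest.approx(1.0, rel=0.2)
        assert fit.estimates["resid_var"] == pytest.approx(4.0, rel=0.15)
        assert fit.estimates["age0_on_intercept"] == pytest.approx(-0.28,
                                                                   abs=0.08)
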