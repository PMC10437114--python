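"""Design construction and the prewhitened robust GLM."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import lfilter

from fnirsglm.first_level import (
    ArIwlsGlm,
    ContrastResult,
    DesignError,
    FirstLevelFit,
    build_design,
    contrast,
    fit_ar_iwls,
    t_from_beta_se,
)
from fnirsglm.paradigm import CONDITIONS, condition_boxcars


@pytest.fixture(scope="module")
def design(short_schedule):
    return build_design(short_schedule, fs=5.0)


class TestDesign:
    def test_column_layout(self, design):
        assert design.matrix.shape[1] == 4 + 4  # conditions + drift order 3 + intercept
        assert design.labels[:4] == CONDITIONS
        assert design.labels[4:] == ("drift_0", "drift_1", "drift_2", "drift_3")

    def test_boxcar_sums_before_convolution(self, default_schedule):
        box = condition_boxcars(default_schedule, fs=10.0)
        assert all(box[c].sum() == 1200 for c in CONDITIONS)

    def test_unit_impulse_kernel_reproduces_raw_boxcars(self, short_schedule):
        d = build_design(short_schedule, fs=5.0, hrf_kernel=np.array([1.0]))
        box = condition_boxcars(short_schedule, fs=5.0)
        for j, cond in enumerate(CONDITIONS):
            np.testing.assert_array_equal(d.matrix[:, j], box[cond].to_numpy())

    def test_collinear_design_rejected_with_column_names(self, short_schedule):
        from fnirsglm.paradigm import schedule_to_events

        ev = schedule_to_events(short_schedule)
        dup = ev.copy()
        dup["trial_type"] = dup["trial_type"] + "_copy"
        both = pd.concat([ev, dup], ignore_index=True)
        with pytest.raises(DesignError, match="rank deficient"):
            build_design(both, fs=5.0, n_samples=1700)

    def test_contrast_vector_helper(self, design):
        c = design.contrast_vector("NMES+AE", "NMES+LO")
        assert c[design.labels.index("NMES+AE")] == 1
        assert c[design.labels.index("NMES+LO")] == -1
        assert c.sum() == 0


class TestArIwls:
    def test_reduces_to_closed_form_ols(self, design):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, design.n_samples)
        fit = fit_ar_iwls(y, design, max_ar_order=0, robust=False)
        x = design.matrix
        beta_ols = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-8)
        resid = y - x @ fit.beta
        sigma2 = resid @ resid / (len(y) - x.shape[1])
        cov_ols = sigma2 * np.linalg.inv(x.T @ x)
        np.testing.assert_allclose(fit.beta_cov, cov_ols, rtol=1e-6)

    def test_zero_series_gives_zero_coefficients(self, design):
        fit = fit_ar_iwls(np.zeros(design.n_samples), design)
        np.testing.assert_allclose(fit.beta, 0.0, atol=1e-12)

    def test_recovers_injected_amplitude_within_three_se(self, design):
        rng = np.random.default_rng(42)
        truth = np.zeros(8)
        truth[1] = 2.0  # 2 uM on the second condition
        y = design.matrix @ truth + rng.normal(0, 1, design.n_samples)
        fit = fit_ar_iwls(y, design)
        res = contrast(fit, design.contrast_vector(CONDITIONS[1]))
        assert abs(res.estimate - 2.0) < 3 * res.se

    def test_scale_equivariance(self, design):
        rng = np.random.default_rng(3)
        y = lfilter([1.0], [1.0, -0.6], rng.normal(0, 1, design.n_samples))
        k = 7.5
        a = fit_ar_iwls(y, design)
        b = fit_ar_iwls(k * y, design)
        np.testing.assert_allclose(b.beta, k * a.beta, rtol=1e-6)
        ca = contrast(a, design.contrast_vector(CONDITIONS[2]))
        cb = contrast(b, design.contrast_vector(CONDITIONS[2]))
        assert cb.se == pytest.approx(k * ca.se, rel=1e-6)
        assert cb.t == pytest.approx(ca.t, rel=1e-6)

    def test_detects_and_whitens_ar1_noise(self, design):
        rng = np.random.default_rng(11)
        y = lfilter([1.0], [1.0, -0.8], rng.normal(0, 0.5, design.n_samples + 200))[200:]
        fit = fit_ar_iwls(y, design)
        assert fit.ar_order >= 1
        assert fit.ar_coeffs[0] == pytest.approx(0.8, abs=0.1)

    def test_robust_weights_downweight_spikes(self, design):
        rng = np.random.default_rng(21)
        truth = np.zeros(8)
        truth[0] = 1.5
        y = design.matrix @ truth + rng.normal(0, 0.5, design.n_samples)
        spikes = rng.choice(design.n_samples, size=15, replace=False)
        y[spikes] += 25.0
        robust = fit_ar_iwls(y, design, max_ar_order=0, robust=True)
        plain = fit_ar_iwls(y, design, max_ar_order=0, robust=False)
        assert robust.robust_weights[spikes].mean() < 0.2
        err_r = abs(robust.beta[0] - 1.5)
        err_p = abs(plain.beta[0] - 1.5)
        assert err_r < err_p

    def test_se_matches_empirical_spread_of_estimates(self, design):
        """Over repeated AR(1) realizations, the mean model SE of a condition
        coefficient agrees with the empirical SD of its estimates within 15%."""
        rng = np.random.default_rng(8)
        c = design.contrast_vector(CONDITIONS[3])
        estimates, ses = [], []
        for _ in range(500):
            y = lfilter([1.0], [1.0, -0.8], rng.normal(0, 0.5, design.n_samples + 100))[100:]
            res = contrast(fit_ar_iwls(y, design, robust=False), c)
            estimates.append(res.estimate)
            ses.append(res.se)
        ratio = np.mean(ses) / np.std(estimates)
        assert 0.85 < ratio < 1.15

    def test_noise_free_simulation_recovered_exactly(
        self, montage, short_schedule, silent_noise
    ):
        """With noise and between-subject variability off, the fitted
        condition coefficients equal the injected amplitudes to <= 1e-6 uM."""
        from fnirsglm.simulate import SubjectTruth, simulate_subject
        from fnirsglm.first_level import fit_channels

        rng = np.random.default_rng(13)
        beta = rng.uniform(-2, 4, (montage.n_channels, len(CONDITIONS)))
        truth = SubjectTruth(
            beta_true=beta, conditions=CONDITIONS, subject_offset_sd=0.0,
            noise=silent_noise,
        )
        hb, realized = simulate_subject(short_schedule, montage, truth, fs=5.0, seed=0)
        d = build_design(short_schedule, fs=5.0)
        fits = fit_channels(hb, d)
        for k, name in enumerate(montage.channel_names):
            np.testing.assert_allclose(fits[name].beta[:4], realized[k], atol=1e-6)

    def test_sklearn_estimator_contract(self, design):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, design.n_samples)
        est = ArIwlsGlm(max_ar_order=2, robust=False)
        assert est.get_params()["max_ar_order"] == 2
        est.set_params(max_ar_order=0)
        est.fit(design, y)
        assert est.coef_.shape == (8,)
        assert est.predict(design).shape == (design.n_samples,)
        assert est.dof_ > 0
        clone_params = ArIwlsGlm(**est.get_params()).get_params()
        assert clone_params == est.get_params()

    def test_length_mismatch_rejected(self, design):
        with pytest.raises(ValueError, match="samples"):
            fit_ar_iwls(np.zeros(10), design)


class TestContrast:
    def _fit(self):
        beta = np.array([1.0, 2.0])
        cov = np.diag([0.04, 0.09])
        return FirstLevelFit(
            beta=beta, beta_cov=cov, labels=("a", "b"), ar_order=0,
            ar_coeffs=np.empty(0), robust_weights=np.ones(50), dof=48.0,
            sigma2=1.0, n_iterations=1, converged=True,
        )

    def test_indicator_contrast_returns_that_coefficient(self):
        res = contrast(self._fit(), [0, 1])
        assert res.estimate == 2.0
        assert res.se == pytest.approx(0.3)
        assert res.t == pytest.approx(2.0 / 0.3)
        assert 0 < res.p < 1

    def test_zero_contrast_gives_null_result(self):
        res = contrast(self._fit(), [0, 0])
        assert res.estimate == 0 and res.t == 0 and res.p == 1.0

    def test_t_is_beta_over_se(self):
        assert t_from_beta_se(3.516, 0.714) == pytest.approx(3.516 / 0.714)
        assert t_from_beta_se(0.0, 0.0) == 0.0
        with pytest.raises(ZeroDivisionError):
            t_from_beta_se(1.0, 0.0)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            contrast(self._fit(), [1, 0, 0])
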