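import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiofractal import (CascadeParams, DqSpectrum, ECGRecord,
                           SpectrumConfig, SyntheticECGParams,
                           closed_form_dq_binomial, estimate_dq,
                           extract_indices, falpha_model, fit_falpha,
                           generate_binomial_cascade, generate_synthetic_ecg,
                           legendre_transform, spectrum_width)
from cardiofractal.errors import (CardioFractalError, EstimationError,
                                  FitFailureError, ParameterError)
from cardiofractal.mfspectrum import FAlphaFit, FAlphaPoints


def spectrum_from_closed_form(p=0.25, qmax=20.0, step=0.5):
    q = np.arange(-qmax, qmax + step / 2, step)
    dq = closed_form_dq_binomial(p, q)
    return DqSpectrum(q_grid=q, dq_values=np.asarray(dq),
                      valid_mask=np.ones(q.size, bool))


class TestLegendreTransform:
    def test_constant_dq_collapses_to_point(self):
        q = np.arange(-10.0, 10.5, 0.5)
        spec = DqSpectrum(q_grid=q, dq_values=np.full(q.size, 1.7),
                          valid_mask=np.ones(q.size, bool))
        pts = legendre_transform(spec)
        assert np.allclose(pts.alpha, 1.7, atol=1e-9)
        assert np.allclose(pts.f, 1.7, atol=1e-9)

    def test_binomial_alpha_and_f_at_q0(self):
        pts = legendre_transform(spectrum_from_closed_form(p=0.25))
        i0 = np.argmin(np.abs(pts.source_q))
        # analytic alpha(0) = (-log2 p - log2 (1-p)) / 2
        assert abs(pts.alpha[i0] - 1.2075187496) < 5e-3
        assert abs(pts.f[i0] - 1.0) < 0.01

    def test_f_bounded_by_d0(self):
        pts = legendre_transform(spectrum_from_closed_form(p=0.3))
        i0 = np.argmin(np.abs(pts.source_q))
        assert pts.f.max() <= pts.f[i0] + 0.02

    def test_too_few_valid_points(self):
        q = np.arange(-2.0, 2.5, 0.5)
        spec = DqSpectrum(q_grid=q, dq_values=np.ones(q.size),
                          valid_mask=np.zeros(q.size, bool))
        with pytest.raises(EstimationError):
            legendre_transform(spec)


class TestFitFAlpha:
    def exact_points(self, a1, a2, g1, g2, d0=1.0, n=40):
        w = a2 - a1
        alphas = np.linspace(a1 + 0.03 * w, a2 - 0.03 * w, n)
        f = falpha_model(alphas, a1, a2, g1, g2, d0)
        return FAlphaPoints(alpha=alphas, f=f,
                            source_q=np.linspace(10, -10, n))

    def test_exact_recovery(self):
        pts = self.exact_points(0.4, 2.0, 0.8, 1.3)
        fit = fit_falpha(pts, d0=1.0)
        assert abs(fit.alpha1 - 0.4) < 1e-3
        assert abs(fit.alpha2 - 2.0) < 1e-3
        assert abs(fit.gamma1 - 0.8) < 1e-3
        assert abs(fit.gamma2 - 1.3) < 1e-3
        assert fit.residual_rms < 1e-8

    @given(a1=st.floats(0.2, 0.9), width=st.floats(0.4, 1.6),
           g1=st.floats(0.3, 3.0), g2=st.floats(0.3, 3.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_recovery_property(self, a1, width, g1, g2):
        pts = self.exact_points(a1, a1 + width, g1, g2)
        fit = fit_falpha(pts, d0=1.0)
        assert max(abs(fit.alpha1 - a1), abs(fit.alpha2 - a1 - width),
                   abs(fit.gamma1 - g1), abs(fit.gamma2 - g2)) < 1e-3

    def test_symmetric_case_peak_at_midpoint(self):
        pts = self.exact_points(0.4, 2.0, 1.3, 1.3)
        fit = fit_falpha(pts, d0=1.0)
        assert abs(fit.alpha0 - (fit.alpha1 + fit.alpha2) / 2) < 1e-6

    def test_peak_value_equals_d0_by_construction(self):
        # the A-elimination algebra: f(alpha0) = d0 exactly
        fit = FAlphaFit(A=0.0, alpha1=0.3, alpha2=1.9, gamma1=0.7,
                        gamma2=2.1, d0=1.4, residual_rms=0.0, converged=True)
        assert np.isclose(float(fit(fit.alpha0)), 1.4, atol=1e-12)
        a = np.linspace(0.3, 1.9, 500)
        assert fit(a).max() <= 1.4 + 1e-9

    def test_single_alpha_degenerate(self):
        pts = FAlphaPoints(alpha=np.full(10, 1.0), f=np.linspace(0, 1, 10),
                           source_q=np.arange(10.0))
        with pytest.raises(FitFailureError):
            fit_falpha(pts, d0=1.0)

    def test_too_few_points(self):
        pts = FAlphaPoints(alpha=np.array([1.0, 1.1]), f=np.array([0.5, 0.6]),
                           source_q=np.array([1.0, 0.0]))
        with pytest.raises(ParameterError):
            fit_falpha(pts, d0=1.0)

    def test_width_and_unconverged_guard(self):
        fit = FAlphaFit(A=1.0, alpha1=0.4, alpha2=2.0, gamma1=1.0,
                        gamma2=1.0, d0=1.0, residual_rms=0.0, converged=True)
        assert np.isclose(spectrum_width(fit), 1.6)
        bad = FAlphaFit(A=1.0, alpha1=0.4, alpha2=2.0, gamma1=1.0,
                        gamma2=1.0, d0=1.0, residual_rms=1.0, converged=False)
        with pytest.raises(ParameterError):
            spectrum_width(bad)


class TestCascadeEndToEnd:
    def test_width_matches_analytic_alpha_range(self):
        m = generate_binomial_cascade(CascadeParams(p=0.25, levels=14))
        spec = estimate_dq(m, q_grid=np.arange(-20.0, 20.5, 0.5))
        pts = legendre_transform(spec)
        i0 = np.argmin(np.abs(pts.source_q))
        fit = fit_falpha(pts, d0=float(pts.f[i0]))
        assert abs(fit.width - np.log2(3.0)) < 0.15


class TestExtractIndices:
    CONFIG = SpectrumConfig(segment_seconds=None)

    def test_deterministic(self):
        params = SyntheticECGParams(duration=40.0, morphology_jitter_sd=0.1,
                                    rr_jitter_sd=0.03, noise_sd=0.01,
                                    baseline_wander_amp=0.05, seed=2)
        rec = generate_synthetic_ecg(params)
        a = extract_indices(rec, self.CONFIG)
        b = extract_indices(rec, self.CONFIG)
        assert a.as_dict() == b.as_dict()

    def test_short_record_fails_with_length_error(self):
        rec = ECGRecord(samples=np.sin(np.arange(500) * 0.1),
                        sampling_rate=250.0)
        with pytest.raises(CardioFractalError):
            extract_indices(rec, self.CONFIG)

    def test_periodic_signal_narrower_than_jittered(self):
        widths = {0.0: [], 0.15: []}
        for seed in range(5, 10):
            for jit in widths:
                params = SyntheticECGParams(
                    duration=40.0, morphology_jitter_sd=jit,
                    rr_jitter_sd=0.01, noise_sd=0.01,
                    baseline_wander_amp=0.05, seed=seed)
                try:
                    idx = extract_indices(generate_synthetic_ecg(params),
                                          self.CONFIG)
                    widths[jit].append(idx.width)
                except CardioFractalError:
                    pass
        assert len(widths[0.0]) >= 3 and len(widths[0.15]) >= 3
        assert np.mean(widths[0.0]) < np.mean(widths[0.15])
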