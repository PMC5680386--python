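import numpy as np
import pytest

from cardiofractal import (CascadeParams, D2Curve, ECGRecord,
                           choose_embedding_dim, closed_form_dq_binomial,
                           correlation_sum, delay_embed, estimate_d2,
                           estimate_dq, generate_binomial_cascade)
from cardiofractal.errors import (LengthError, NoSaturationError,
                                  ParameterError)


def brute_force_correlation_sum(points, r_grid, window):
    points = np.atleast_2d(points)
    n = points.shape[0]
    dists = []
    for i in range(n):
        for j in range(i + 1, n):
            if j - i > window:
                dists.append(np.max(np.abs(points[i] - points[j])))
    dists = np.asarray(dists)
    return np.array([(dists <= r).mean() for r in r_grid])


class TestCorrelationSum:
    def test_two_points_step_function(self):
        pts = np.array([[0.0], [1.0]])
        c = correlation_sum(pts, np.array([0.5, 1.0, 2.0]))
        assert np.array_equal(c, [0.0, 1.0, 1.0])

    def test_non_decreasing(self):
        rng = np.random.default_rng(0)
        pts = rng.random((300, 2))
        c = correlation_sum(pts, np.logspace(-3, 0.2, 20))
        assert np.all(np.diff(c) >= 0)

    @pytest.mark.parametrize("window", [0, 5])
    def test_matches_brute_force_exactly(self, window):
        rng = np.random.default_rng(3)
        pts = rng.random((120, 3))
        r_grid = np.logspace(-2, 0.2, 12)
        fast = correlation_sum(pts, r_grid, theiler_window=window)
        slow = brute_force_correlation_sum(pts, r_grid, window)
        assert np.allclose(fast, slow, atol=1e-14)

    def test_uniform_points_scale_with_dimension_one(self):
        rng = np.random.default_rng(5)
        pts = rng.random((100, 1))
        r_grid = np.logspace(-2, -0.5, 10)
        c = correlation_sum(pts, r_grid)
        slope = np.polyfit(np.log(r_grid), np.log(c), 1)[0]
        assert abs(slope - 1.0) < 0.1

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError):
            correlation_sum(np.zeros((10, 1)), np.array([]))


class TestEstimateD2:
    def test_circle_has_dimension_one(self):
        x = np.sin(2 * np.pi * np.arange(5000) / 50.0)
        rec = ECGRecord(samples=x, sampling_rate=1.0)
        curve = estimate_d2(rec, M_max=4)
        assert curve.saturated
        assert abs(curve.saturated_d2 - 1.0) < 0.1

    def test_too_short_for_m_max(self):
        rec = ECGRecord(samples=np.sin(np.arange(300) * 0.3),
                        sampling_rate=1.0)
        with pytest.raises(LengthError):
            estimate_d2(rec, M_max=8, tau=40)

    def test_m_max_validated(self):
        rec = ECGRecord(samples=np.sin(np.arange(5000) * 0.1),
                        sampling_rate=1.0)
        with pytest.raises(ParameterError):
            estimate_d2(rec, M_max=2)


class TestChooseEmbeddingDim:
    def make_curve(self, sat):
        return D2Curve(M_values=[1, 2, 3, 4], d2_values=[sat] * 4,
                       saturated_d2=sat, saturated=True, fit_diagnostics=[])

    @pytest.mark.parametrize("sat,expected", [(3.4, 4), (1.2, 2), (2.0, 3)])
    def test_smallest_integer_strictly_above(self, sat, expected):
        assert choose_embedding_dim(self.make_curve(sat)) == expected

    def test_unsaturated_curve_rejected(self):
        curve = D2Curve(M_values=[1, 2], d2_values=[1.0, 2.0],
                        saturated_d2=None, saturated=False,
                        fit_diagnostics=[])
        with pytest.raises(NoSaturationError):
            choose_embedding_dim(curve)


class TestEstimateDqMeasure:
    def test_binomial_cascade_matches_closed_form(self):
        m = generate_binomial_cascade(CascadeParams(p=0.25, levels=14))
        q = np.arange(-10.0, 10.5, 0.5)
        spec = estimate_dq(m, q_grid=q)
        assert spec.valid_mask.all()
        err = np.abs(spec.dq_values - closed_form_dq_binomial(0.25, q))
        assert err.max() < 0.05

    def test_uniform_measure_is_monofractal(self):
        m = np.full(2 ** 12, 2.0 ** -12)
        spec = estimate_dq(m, q_grid=np.arange(-5.0, 5.5, 0.5))
        assert np.abs(spec.dq_values - 1.0).max() < 0.02

    def test_dq_non_increasing_in_q(self):
        m = generate_binomial_cascade(CascadeParams(p=0.3, levels=12))
        spec = estimate_dq(m, q_grid=np.arange(-8.0, 8.5, 0.5))
        d = spec.dq_values[spec.valid_mask]
        assert np.all(np.diff(d) <= 0.02)

    def test_d0_of_full_support_measure(self):
        m = generate_binomial_cascade(CascadeParams(p=0.35, levels=12))
        spec = estimate_dq(m, q_grid=np.array([-1.0, -0.5, 0.0, 0.5, 2.0]))
        i0 = np.searchsorted(spec.q_grid, 0.0)
        assert abs(spec.dq_values[i0] - 1.0) < 0.02

    def test_invalid_measure_rejected(self):
        with pytest.raises(ParameterError):
            estimate_dq(np.array([0.5, 0.25, 0.25]))  # not a power of two
        with pytest.raises(ParameterError):
            estimate_dq(np.array([0.5, -0.5, 0.5, 0.5]))


class TestEstimateDqAttractor:
    def test_gp_d2_consistent_with_dq_at_q2(self, henon_record):
        curve = estimate_d2(henon_record, M_max=5, tau=1)
        att = delay_embed(henon_record, 2, 1)
        spec = estimate_dq(att, q_grid=np.arange(-2.0, 4.5, 0.5),
                           theiler_window=10)
        i2 = np.searchsorted(spec.q_grid, 2.0)
        assert spec.valid_mask[i2]
        assert abs(curve.saturated_d2 - spec.dq_values[i2]) < 0.1

    def test_valid_dq_non_increasing(self, henon_record):
        att = delay_embed(henon_record, 2, 1)
        spec = estimate_dq(att, q_grid=np.arange(-4.0, 8.5, 0.5),
                           theiler_window=10)
        d = spec.dq_values[spec.valid_mask]
        assert np.all(np.diff(d) <= 0.02)

    def test_small_attractor_rejected(self):
        rec = ECGRecord(samples=np.sin(np.arange(500) * 0.2),
                        sampling_rate=1.0)
        att = delay_embed(rec, 3, 2)
        with pytest.raises(LengthError):
            estimate_dq(att)
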