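import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiofractal import (CascadeParams, SyntheticECGParams,
                           closed_form_dq_binomial, ecg_preset,
                           generate_binomial_cascade, generate_chaotic_series,
                           generate_synthetic_ecg)
from cardiofractal.errors import ParameterError


class TestSyntheticECG:
    def test_noise_free_signal_is_strictly_periodic(self):
        params = SyntheticECGParams(duration=30, morphology_jitter_sd=0.0,
                                    rr_jitter_sd=0.0, noise_sd=0.0,
                                    baseline_wander_amp=0.0, seed=0)
        x = generate_synthetic_ecg(params).samples
        period = int(round(params.mean_rr * params.sampling_rate))
        # compare two interior beats sample-by-sample
        a = x[3 * period:4 * period]
        b = x[20 * period:21 * period]
        assert np.allclose(a, b, atol=1e-3 * np.abs(x).max())

    def test_expected_length(self):
        params = SyntheticECGParams(duration=30, seed=0)
        rec = generate_synthetic_ecg(params)
        assert len(rec) == round(params.sampling_rate * params.duration)

    def test_seeded_determinism(self):
        params = SyntheticECGParams(duration=30, morphology_jitter_sd=0.1,
                                    noise_sd=0.05, seed=7)
        a = generate_synthetic_ecg(params).samples
        b = generate_synthetic_ecg(params).samples
        assert np.array_equal(a, b)

    def test_high_jitter_preset_has_more_beat_amplitude_spread(self):
        period = 0.8
        out = {}
        for name in ("healthy", "unhealthy"):
            params = ecg_preset(name, duration=60.0, seed=3,
                                rr_jitter_sd=0.0, noise_sd=0.0,
                                baseline_wander_amp=0.0, mean_rr=period)
            x = generate_synthetic_ecg(params).samples
            n_per = int(period * params.sampling_rate)
            peaks = [x[i * n_per:(i + 1) * n_per].max()
                     for i in range(2, 60)]
            out[name] = np.std(peaks)
        assert out["healthy"] > out["unhealthy"]

    @pytest.mark.parametrize("bad", [
        dict(sampling_rate=0.0), dict(duration=-5.0),
        dict(duration=5.0),  # fewer than 20 beats
        dict(morphology_jitter_sd=-0.1),
        dict(wave_widths=(0.1, 0.1, 0.0, 0.1, 0.1)),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ParameterError):
            SyntheticECGParams(**bad)


class TestBinomialCascade:
    def test_equal_weights_give_uniform_measure(self):
        m = generate_binomial_cascade(CascadeParams(p=0.5, levels=10))
        assert np.allclose(m, 2.0 ** -10, atol=1e-15)

    @given(p=st.floats(0.05, 0.95), levels=st.integers(4, 14))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mass_conservation(self, p, levels):
        m = generate_binomial_cascade(CascadeParams(p=p, levels=levels))
        assert abs(m.sum() - 1.0) < 1e-12

    def test_largest_bin_is_max_weight_power(self):
        m = generate_binomial_cascade(CascadeParams(p=0.25, levels=14))
        assert np.isclose(m.max(), 0.75 ** 14, rtol=1e-12)

    def test_singularity_exponent_bounds_at_finest_level(self):
        p, levels = 0.3, 12
        m = generate_binomial_cascade(CascadeParams(p=p, levels=levels))
        exponents = np.log2(m) / (-levels)
        assert np.isclose(exponents.min(), -np.log2(max(p, 1 - p)))
        assert np.isclose(exponents.max(), -np.log2(min(p, 1 - p)))

    def test_shuffle_preserves_sorted_masses(self):
        a = generate_binomial_cascade(CascadeParams(p=0.3, levels=10))
        b = generate_binomial_cascade(CascadeParams(p=0.3, levels=10,
                                                    shuffle=True, seed=5))
        assert np.allclose(np.sort(a), np.sort(b))

    def test_invalid_weight_rejected(self):
        with pytest.raises(ParameterError):
            CascadeParams(p=1.5)


class TestClosedFormDq:
    def test_uniform_measure_has_all_dq_one(self):
        q = np.arange(-10, 11.0)
        assert np.allclose(closed_form_dq_binomial(0.5, q), 1.0)

    def test_d0_is_support_dimension(self):
        assert np.isclose(closed_form_dq_binomial(0.25, 0.0), 1.0)

    def test_d2_hand_value(self):
        # -log2(0.25^2 + 0.75^2) = -log2(0.625)
        assert np.isclose(closed_form_dq_binomial(0.25, 2.0),
                          -np.log2(0.625), atol=1e-12)

    def test_q1_is_entropy_limit_and_continuous(self):
        p = 0.25
        h = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
        assert np.isclose(closed_form_dq_binomial(p, 1.0), h)
        assert np.isclose(closed_form_dq_binomial(p, 1.0 + 1e-9), h, atol=1e-6)


class TestChaoticSeries:
    def test_logistic_stays_in_unit_interval(self):
        x = generate_chaotic_series("logistic", 5000, seed=0)
        assert np.all((x >= 0.0) & (x <= 1.0))

    def test_henon_trajectory_bounded(self):
        x = generate_chaotic_series("henon", 5000, seed=0)
        assert np.all(np.abs(x) < 2.0)

    def test_lorenz_seeds_differ(self):
        a = generate_chaotic_series("lorenz", 1000, seed=0)
        b = generate_chaotic_series("lorenz", 1000, seed=1)
        assert not np.array_equal(a, b)

    def test_same_seed_reproduces(self):
        a = generate_chaotic_series("henon", 2000, seed=3)
        b = generate_chaotic_series("henon", 2000, seed=3)
        assert np.array_equal(a, b)

    def test_unknown_system_rejected(self):
        with pytest.raises(ParameterError):
            generate_chaotic_series("roessler", 2000)

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            generate_chaotic_series("henon", 10)
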