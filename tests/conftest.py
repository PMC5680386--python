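import numpy as np
import pytest

from cardiofractal import (ECGRecord, SyntheticECGParams,
                           generate_chaotic_series, generate_synthetic_ecg)


def zscored_record(x: np.ndarray, rate: float = 1.0) -> ECGRecord:
    x = np.asarray(x, dtype=float)
    return ECGRecord(samples=(x - x.mean()) / x.std(), sampling_rate=rate)


@pytest.fixture(scope="session")
def henon_record() -> ECGRecord:
    return zscored_record(generate_chaotic_series("henon", 20000, seed=1))


@pytest.fixture(scope="session")
def periodic_ecg() -> ECGRecord:
    """Strictly periodic beat train: no jitter, no noise, no wander."""
    params = SyntheticECGParams(duration=60.0, morphology_jitter_sd=0.0,
                                rr_jitter_sd=0.0, noise_sd=0.0,
                                baseline_wander_amp=0.0, seed=1)
    return generate_synthetic_ecg(params)


def ar1_series(n: int, phi: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(n)
    x = np.zeros(n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i]
    return x
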