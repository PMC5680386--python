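"""Synthetic inputs for every stage of the pipeline.

Three families of test signals:

* ECG-like beat trains — a quasi-periodic sum of five Gaussian bumps
  (P, Q, R, S, T) per beat, with beat-to-beat RR jitter, per-beat
  morphological amplitude jitter, baseline wander and additive noise.
  Two presets differ only in how much the beat morphology varies, which
  is the knob that controls the signal's dynamical complexity.
* Binomial multiplicative cascades — measures whose generalized
  dimensions D_q and singularity spectrum f(alpha) are known in closed
  form, used as exact oracles for the multifractal estimators.
* Chaotic series (Henon, Lorenz, logistic) with well-known correlation
  dimensions, used as oracles for the Grassberger-Procaccia estimator
  and as nonlinear inputs for the surrogate test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ParameterError
from .preprocess import ECGRecord

__all__ = [
    "SyntheticECGParams",
    "CascadeParams",
    "generate_synthetic_ecg",
    "generate_binomial_cascade",
    "closed_form_dq_binomial",
    "closed_form_falpha_binomial",
    "generate_chaotic_series",
    "ecg_preset",
]


@dataclass(frozen=True)
class SyntheticECGParams:
    """Parameters of the quasi-periodic beat-train generator.

    Wave order is (P, Q, R, S, T). ``wave_centers`` are offsets in
    seconds relative to the R peak (negative = before R).
    ``morphology_jitter_sd`` is the sigma of a per-beat, per-wave
    lognormal multiplier on the wave amplitude, i.e. a *relative*
    amplitude jitter.
    """

    sampling_rate: float = 250.0
    duration: float = 120.0
    mean_rr: float = 0.8
    rr_jitter_sd: float = 0.04
    wave_amplitudes: tuple = (0.15, -0.1, 1.0, -0.25, 0.35)
    wave_widths: tuple = (0.04, 0.012, 0.016, 0.014, 0.07)
    wave_centers: tuple = (-0.2, -0.04, 0.0, 0.04, 0.3)
    morphology_jitter_sd: float = 0.0
    baseline_wander_amp: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")
        if self.duration < 20 * self.mean_rr:
            raise ParameterError(
                "duration must cover at least 20 beats "
                f"({self.duration} s < 20 x {self.mean_rr} s)"
            )
        if len(self.wave_amplitudes) != 5 or len(self.wave_widths) != 5 \
                or len(self.wave_centers) != 5:
            raise ParameterError("five waves (P,Q,R,S,T) are required")
        if any(w <= 0 for w in self.wave_widths):
            raise ParameterError("wave_widths must be positive")
        if self.morphology_jitter_sd < 0:
            raise ParameterError("morphology_jitter_sd must be >= 0")


#: Preset beat trains for the two study groups. The high-variability
#: preset stands in for healthy records (more complex dynamics), the
#: low-variability one for unhealthy records (reduced complexity).
_PRESETS = {
    "healthy": dict(morphology_jitter_sd=0.15, rr_jitter_sd=0.05,
                    baseline_wander_amp=0.05, noise_sd=0.01),
    "unhealthy": dict(morphology_jitter_sd=0.02, rr_jitter_sd=0.01,
                      baseline_wander_amp=0.05, noise_sd=0.01),
}


def ecg_preset(name: str, **overrides) -> SyntheticECGParams:
    """Return a named preset ('healthy' or 'unhealthy'), with overrides."""
    if name not in _PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    kwargs = dict(_PRESETS[name])
    kwargs.update(overrides)
    return SyntheticECGParams(**kwargs)


def generate_synthetic_ecg(params: SyntheticECGParams) -> ECGRecord:
    """Generate a quasi-periodic ECG-like beat train.

    Each beat is a sum of five Gaussian bumps whose amplitudes are
    scaled by per-beat lognormal jitter with sigma
    ``morphology_jitter_sd``. RR intervals are drawn as
    ``mean_rr + N(0, rr_jitter_sd)`` truncated to > 0.2 s. Deterministic
    given the seed.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.sampling_rate * params.duration))
    t = np.arange(n) / params.sampling_rate
    signal = np.zeros(n)

    amps = np.asarray(params.wave_amplitudes, dtype=float)
    widths = np.asarray(params.wave_widths, dtype=float)
    centers = np.asarray(params.wave_centers, dtype=float)

    # R-peak times: start half a beat in so the first P wave fits.
    r_time = 0.5 * params.mean_rr
    pad = 4 * widths.max() + max(abs(centers.min()), centers.max())
    while r_time < params.duration + pad:
        if params.morphology_jitter_sd > 0:
            jitter = rng.lognormal(0.0, params.morphology_jitter_sd, size=5)
        else:
            jitter = np.ones(5)
        beat_amps = amps * jitter
        lo = np.searchsorted(t, r_time + centers.min() - 4 * widths.max())
        hi = np.searchsorted(t, r_time + centers.max() + 4 * widths.max())
        tt = t[lo:hi, None] - (r_time + centers[None, :])
        signal[lo:hi] += np.sum(
            beat_amps[None, :] * np.exp(-0.5 * (tt / widths[None, :]) ** 2), axis=1
        )
        rr = params.mean_rr + rng.normal(0.0, params.rr_jitter_sd) \
            if params.rr_jitter_sd > 0 else params.mean_rr
        r_time += max(rr, 0.2)

    if params.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal += params.baseline_wander_amp * np.sin(2 * np.pi * 0.25 * t + phase)
    if params.noise_sd > 0:
        signal += rng.normal(0.0, params.noise_sd, size=n)

    return ECGRecord(samples=signal, sampling_rate=params.sampling_rate,
                     channel="synthetic", group_label="unknown")


@dataclass(frozen=True)
class CascadeParams:
    """Binomial multiplicative cascade: weight ``p`` and dyadic depth."""

    p: float = 0.25
    levels: int = 14
    seed: int = 0
    shuffle: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ParameterError("p must lie strictly in (0, 1)")
        if self.levels < 1:
            raise ParameterError("levels must be a positive integer")


def generate_binomial_cascade(params: CascadeParams) -> np.ndarray:
    """Deterministic binomial cascade measure on ``2**levels`` bins.

    Mass is split recursively with weights (p, 1-p), p always assigned
    to the left half, so the multifractal spectrum of the output is the
    exact closed form of :func:`closed_form_dq_binomial`. With
    ``shuffle=True`` the (p, 1-p) order is randomized independently at
    every node; a per-level permutation of weight order leaves all box
    sums, hence all D_q, unchanged.
    """
    masses = np.array([1.0])
    rng = np.random.default_rng(params.seed)
    for level in range(params.levels):
        left = np.full(masses.size, params.p)
        if params.shuffle:
            flip = rng.random(masses.size) < 0.5
            left[flip] = 1.0 - params.p
        out = np.empty(masses.size * 2)
        out[0::2] = masses * left
        out[1::2] = masses * (1.0 - left)
        masses = out
    return masses


def closed_form_dq_binomial(p: float, q) -> np.ndarray | float:
    """Analytic generalized dimensions of the binomial cascade.

    ``D_q = log2(p^q + (1-p)^q) / (1 - q)`` for q != 1, with the
    Shannon-entropy limit at q = 1.
    """
    if not 0.0 < p < 1.0:
        raise ParameterError("p must lie strictly in (0, 1)")
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 0
    q = np.atleast_1d(q)
    out = np.empty_like(q)
    near1 = np.isclose(q, 1.0)
    with np.errstate(over="ignore"):
        out[~near1] = np.log2(p ** q[~near1] + (1 - p) ** q[~near1]) / (1.0 - q[~near1])
    out[near1] = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
    return float(out[0]) if scalar else out


def closed_form_falpha_binomial(p: float, q) -> tuple[np.ndarray, np.ndarray]:
    """Analytic (alpha(q), f(alpha(q))) of the binomial cascade.

    alpha(q) = -(p^q ln p + (1-p)^q ln(1-p)) / ((p^q + (1-p)^q) ln 2),
    f = q*alpha - (q-1)*D_q. Used as the end-to-end oracle for the
    Legendre-transform stage.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    pq, cq = p ** q, (1 - p) ** q
    alpha = -(pq * np.log(p) + cq * np.log(1 - p)) / ((pq + cq) * np.log(2))
    tau = (q - 1.0) * closed_form_dq_binomial(p, q)
    return alpha, q * alpha - tau


_CHAOS_DEFAULTS = {
    "henon": dict(a=1.4, b=0.3),
    "logistic": dict(r=4.0),
    "lorenz": dict(sigma=10.0, rho=28.0, beta=8.0 / 3.0, dt=0.02),
}


def generate_chaotic_series(system: str, n: int, params: dict | None = None,
                            seed: int = 0) -> np.ndarray:
    """Scalar observable from a standard chaotic system.

    The seed perturbs the initial condition; a transient of at least
    1000 iterates (or the equivalent integration time for Lorenz) is
    discarded before recording ``n`` samples.
    """
    if system not in _CHAOS_DEFAULTS:
        raise ParameterError(
            f"unknown system {system!r}; choose from {sorted(_CHAOS_DEFAULTS)}")
    if n < 1000:
        raise ParameterError("n must be >= 1000")
    p = dict(_CHAOS_DEFAULTS[system])
    if params:
        p.update(params)
    rng = np.random.default_rng(seed)
    transient = 1000

    if system == "logistic":
        x = 0.1 + 0.8 * rng.random()
        out = np.empty(n)
        for _ in range(transient):
            x = p["r"] * x * (1.0 - x)
        for i in range(n):
            x = p["r"] * x * (1.0 - x)
            out[i] = x
        return out

    if system == "henon":
        x, y = 0.1 * rng.standard_normal(2)
        out = np.empty(n)
        for _ in range(transient):
            x, y = 1.0 - p["a"] * x * x + y, p["b"] * x
        for i in range(n):
            x, y = 1.0 - p["a"] * x * x + y, p["b"] * x
            out[i] = x
        return out

    # Lorenz: integrate past the transient, then sample x every dt.
    sigma, rho, beta, dt = p["sigma"], p["rho"], p["beta"], p["dt"]

    def rhs(_t, s):
        x, y, z = s
        return [sigma * (y - x), x * (rho - z) - y, x * y - beta * z]

    s0 = np.array([1.0, 1.0, 20.0]) + 0.5 * rng.standard_normal(3)
    t_transient = transient * dt
    t_end = t_transient + n * dt
    t_eval = t_transient + dt * np.arange(n)
    sol = solve_ivp(rhs, (0.0, t_end), s0, t_eval=t_eval, rtol=1e-8,
                    atol=1e-10, max_step=dt, dense_output=False)
    return sol.y[0]
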