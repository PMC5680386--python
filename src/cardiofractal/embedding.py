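"""Phase-space reconstruction by delay embedding.

A scalar series s(t_k) is unfolded into vectors
(s_i, s_{i+tau}, ..., s_{i+(M-1)tau}) in an M-dimensional embedding
space. The delay tau is chosen as the first lag at which the sample
autocorrelation decays to 1/e (a standard deterministic rule), and the
embedded cloud can be rotated onto its principal axes by SVD for
display and for variance-ordered coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError, LengthError, ParameterError
from .preprocess import ECGRecord

__all__ = ["Attractor", "estimate_delay", "delay_embed", "svd_project",
           "autocorrelation"]


@dataclass(frozen=True)
class Attractor:
    """Delay-embedded point set with its (M, tau) provenance."""

    points: np.ndarray  # (n_vec, M)
    M: int
    tau: int
    source_length: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if self.M < 1 or self.tau < 1:
            raise ParameterError("M and tau must be >= 1")
        expected = self.source_length - (self.M - 1) * self.tau
        if pts.shape != (expected, self.M):
            raise ParameterError(
                f"points shape {pts.shape} inconsistent with "
                f"(source_length - (M-1)*tau, M) = ({expected}, {self.M})")

    def __len__(self) -> int:
        return self.points.shape[0]


def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation for lags 0..max_lag (FFT-based)."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(spec * np.conj(spec))[: max_lag + 1]
    if acf[0] <= 0:
        raise DegenerateSignalError("autocorrelation undefined for constant signal")
    return acf / acf[0]


def estimate_delay(record: ECGRecord, m_max: int = 8) -> int:
    """Delay tau = first lag where the autocorrelation drops to <= 1/e.

    Capped at ``len(record) // (2 * m_max)`` so that an embedding of up
    to ``m_max`` dimensions still leaves most of the series usable.
    """
    x = record.samples
    if x.size < 100:
        raise LengthError("need at least 100 samples to estimate a delay")
    cap = max(1, x.size // (2 * m_max))
    acf = autocorrelation(x, min(x.size - 1, cap))
    below = np.nonzero(acf[1:] <= 1.0 / np.e)[0]
    if below.size == 0:
        return cap
    return int(below[0]) + 1


def delay_embed(record: ECGRecord, M: int, tau: int) -> Attractor:
    """Embed the series with dimension ``M`` and delay ``tau``."""
    if M < 1 or tau < 1:
        raise ParameterError("M and tau must be >= 1")
    x = record.samples
    n_vec = x.size - (M - 1) * tau
    if n_vec < 1:
        raise LengthError(
            f"series of length {x.size} too short for M={M}, tau={tau}")
    idx = np.arange(n_vec)[:, None] + tau * np.arange(M)[None, :]
    return Attractor(points=x[idx], M=M, tau=tau, source_length=x.size)


def svd_project(attractor: Attractor, k: int) -> np.ndarray:
    """Project the column-centered point cloud onto its top-k principal axes.

    Output columns are ordered by decreasing singular value and are
    mutually uncorrelated; with ``k == M`` the map is an isometry of the
    centered cloud.
    """
    if not 1 <= k <= attractor.M:
        raise ParameterError(f"k must be in [1, M={attractor.M}]")
    pts = attractor.points - attractor.points.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    return pts @ vt[:k].T
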