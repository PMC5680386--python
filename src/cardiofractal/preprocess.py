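"""Loading, conditioning and linear screening of ECG records.

The conditioning contract used throughout the package: take a fixed-
length segment from the start of the record (the method is designed for
short clinical recordings of one to two minutes), remove baseline
wander with a zero-phase high-pass filter, and standardize to zero mean
and unit variance so that amplitude units never enter the downstream
scaling analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .errors import (ConfigError, DegenerateSignalError, LengthError,
                     ParameterError, ParseError)

__all__ = ["ECGRecord", "load_ecg", "condition", "peak_frequency"]


@dataclass(frozen=True)
class ECGRecord:
    """A uniformly sampled scalar signal with its sampling rate.

    ``group_label`` is 'healthy', 'unhealthy' or 'unknown'.
    """

    samples: np.ndarray
    sampling_rate: float
    channel: str = ""
    group_label: str = "unknown"
    subject_id: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        if samples.ndim != 1 or samples.size < 2:
            raise ParameterError("samples must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ParameterError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.sampling_rate


def load_ecg(path, format: str = "csv", sampling_rate: float | None = None,
             channel: str | None = None, **record_kwargs) -> ECGRecord:
    """Load an ECG record from disk.

    ``csv``/``txt`` files hold either one column of sample values or two
    columns ``time,value``; a sampling rate must then be supplied (or,
    for two-column files, it is inferred from the time stamps). ``wfdb``
    reads a PhysioNet WFDB record header/channel pair and requires the
    optional ``wfdb`` package.
    """
    path = Path(path)
    if format == "wfdb":
        try:
            import wfdb  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ConfigError(
                "WFDB input requires the optional 'wfdb' package") from exc
        record = wfdb.rdrecord(str(path))
        names = list(record.sig_name)
        if channel is None:
            idx = 0
        elif channel in names:
            idx = names.index(channel)
        else:
            raise LookupError(f"channel {channel!r} not in record ({names})")
        return ECGRecord(samples=np.asarray(record.p_signal[:, idx], dtype=float),
                         sampling_rate=float(record.fs),
                         channel=names[idx], **record_kwargs)

    if format not in ("csv", "txt"):
        raise ParameterError(f"unknown format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            try:
                values = [float(p) for p in parts]
            except ValueError:
                if lineno == 1:  # tolerate a single header line
                    continue
                raise ParseError(f"{path}:{lineno}: non-numeric content {line!r}")
            if not all(np.isfinite(values)):
                raise ParseError(f"{path}:{lineno}: non-finite value in {line!r}")
            rows.append(values)
    if not rows:
        raise ParseError(f"{path}: no numeric data")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ParseError(f"{path}: inconsistent column count")
    data = np.asarray(rows, dtype=float)
    if ncol == 1:
        if sampling_rate is None:
            raise ConfigError(
                "single-column input needs an explicit sampling_rate")
        samples, rate = data[:, 0], float(sampling_rate)
    elif ncol == 2:
        samples = data[:, 1]
        if sampling_rate is not None:
            rate = float(sampling_rate)
        else:
            dt = np.diff(data[:, 0])
            if dt.size == 0 or np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt.mean():
                raise ConfigError(
                    "cannot infer sampling rate from non-uniform time column")
            rate = 1.0 / dt.mean()
    else:
        raise ParseError(f"{path}: expected 1 or 2 columns, found {ncol}")
    return ECGRecord(samples=samples, sampling_rate=rate,
                     channel=channel or "", **record_kwargs)


def condition(record: ECGRecord, segment_seconds: float = 120.0,
              highpass_hz: float = 0.5) -> ECGRecord:
    """Segment, detrend and standardize a record.

    Keeps the first ``segment_seconds`` of signal, removes baseline
    wander with a zero-phase sharp-cutoff spectral high-pass at
    ``highpass_hz`` (skipped if ``highpass_hz <= 0``), and z-scores the
    result. The 0/1 frequency response makes the operation exactly
    idempotent and free of the slow edge transients an IIR filter
    would leave in short records.
    """
    n_keep = int(round(segment_seconds * record.sampling_rate))
    if n_keep < 2:
        raise ParameterError("segment_seconds too small for this sampling rate")
    if record.samples.size < n_keep:
        raise LengthError(
            f"record of {record.duration:.1f} s shorter than requested "
            f"segment of {segment_seconds:.1f} s")
    x = record.samples[:n_keep].astype(float)

    if highpass_hz > 0:
        nyq = record.sampling_rate / 2.0
        if highpass_hz >= nyq:
            raise ParameterError("highpass_hz must be below Nyquist")
        spectrum = np.fft.rfft(x - x.mean())
        freqs = np.fft.rfftfreq(x.size, 1.0 / record.sampling_rate)
        spectrum[freqs < highpass_hz] = 0.0
        x = np.fft.irfft(spectrum, n=x.size)

    sd = x.std()
    if sd < 1e-12:
        raise DegenerateSignalError("constant signal cannot be standardized")
    x = (x - x.mean()) / sd
    return replace(record, samples=x)


def peak_frequency(record: ECGRecord) -> float:
    """Frequency (Hz) of maximum power in the Hann-tapered periodogram.

    The DC bin is excluded from the peak search; resolution is
    ``sampling_rate / length``.
    """
    x = record.samples
    if x.size < 64:
        raise LengthError("need at least 64 samples for a spectrum")
    if np.allclose(x, 0.0):
        raise DegenerateSignalError("all-zero signal has no spectral peak")
    freqs, power = sps.periodogram(x, fs=record.sampling_rate, window="hann",
                                   detrend=False)
    idx = 1 + int(np.argmax(power[1:]))
    return float(freqs[idx])
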