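"""Fractal-dimension estimators for embedded attractors and measures.

Two estimators live here:

* the Grassberger-Procaccia correlation dimension D2, computed from the
  correlation sum C(r) with a Theiler window, as a function of the
  embedding dimension M; a deterministic attractor shows D2 saturating
  with M while stochastic input keeps tracking M, and the saturated
  value fixes the embedding dimension for the rest of the pipeline;
* the generalized (Renyi) dimensions D_q of the coarse-grained
  measure: exact dyadic box sums for a measure supplied directly (the
  form the closed-form cascade oracles use), and Theiler-windowed
  neighborhood counts (generalized correlation integrals) for an
  embedded attractor in full M-space, where box histograms degenerate
  at negative q.

Both estimators fit scaling exponents as straight-line slopes of log-log
curves over an automatically selected scaling region: the widest
sliding window of at least ``min_scales`` grid points whose linear fit
reaches R^2 >= ``r2_min``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import Attractor, delay_embed, estimate_delay
from .errors import (EstimationError, LengthError, NoSaturationError,
                     ParameterError)
from .preprocess import ECGRecord

__all__ = ["D2Curve", "DqSpectrum", "correlation_sum", "estimate_d2",
           "choose_embedding_dim", "estimate_dq"]

_CHUNK_ELEMENTS = 4_000_000  # distance-matrix chunk budget (floats)


@dataclass(frozen=True)
class D2Curve:
    """Correlation dimension versus embedding dimension."""

    M_values: list
    d2_values: list
    saturated_d2: float | None
    saturated: bool
    fit_diagnostics: list  # per-M dict: r_lo, r_hi, r2, n_scales


@dataclass(frozen=True)
class DqSpectrum:
    """Generalized dimensions over a q-grid, with per-q reliability."""

    q_grid: np.ndarray
    dq_values: np.ndarray
    valid_mask: np.ndarray
    M: int | None = None
    tau: int | None = None
    diagnostics: dict = field(default_factory=dict)


def _window_fits(x: np.ndarray, y: np.ndarray, width: int):
    """Slopes and R^2 of least-squares lines over every window of ``width``.

    Prefix-sum implementation so one call costs O(n) regardless of width.
    """
    cs = lambda a: np.concatenate(([0.0], np.cumsum(a)))
    sx, sy = cs(x), cs(y)
    sxx, syy, sxy = cs(x * x), cs(y * y), cs(x * y)
    n = x.size
    lo = np.arange(0, n - width + 1)
    hi = lo + width
    w = float(width)
    Sx, Sy = sx[hi] - sx[lo], sy[hi] - sy[lo]
    Sxx, Syy, Sxy = sxx[hi] - sxx[lo], syy[hi] - syy[lo], sxy[hi] - sxy[lo]
    vx = w * Sxx - Sx * Sx
    vy = w * Syy - Sy * Sy
    cov = w * Sxy - Sx * Sy
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = cov / vx
        r2 = np.where(vy > 0, cov * cov / (vx * vy), 0.0)
    return slope, r2


def select_scaling_region(log_r: np.ndarray, log_y: np.ndarray,
                          min_scales: int = 5, r2_min: float = 0.98):
    """Pick the widest window with an acceptable straight-line fit.

    Returns ``(slope, (i_lo, i_hi), r2, ok)`` where ``ok`` is False if
    no window of ``min_scales`` points reaches ``r2_min`` (the best
    window of minimum width by R^2 is then returned as a fallback).
    """
    n = log_r.size
    if n < min_scales:
        return np.nan, (0, max(0, n - 1)), 0.0, False
    for width in range(n, min_scales - 1, -1):
        slope, r2 = _window_fits(log_r, log_y, width)
        good = np.nonzero(r2 >= r2_min)[0]
        if good.size:
            lo = int(good[np.argmax(r2[good])])
            return float(slope[lo]), (lo, lo + width - 1), float(r2[lo]), True
    slope, r2 = _window_fits(log_r, log_y, min_scales)
    lo = int(np.argmax(r2))
    return (float(slope[lo]), (lo, lo + min_scales - 1), float(r2[lo]), False)


def correlation_sum(points: np.ndarray, r_grid: np.ndarray,
                    theiler_window: int = 0, ref_stride: int = 1) -> np.ndarray:
    """Fraction of point pairs within max-norm distance r, per r.

    Pairs with time-index separation ``|i - j| <= theiler_window`` are
    excluded. With ``ref_stride > 1`` only every stride-th point is used
    as a reference (against all points), an unbiased speed-up for long
    series.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    r_grid = np.asarray(r_grid, dtype=float)
    if r_grid.size == 0:
        raise ParameterError("r_grid must be non-empty")
    if np.any(np.diff(r_grid) <= 0) or np.any(r_grid <= 0):
        raise ParameterError("r_grid must be positive and strictly increasing")

    counts = np.zeros(r_grid.size + 1, dtype=np.int64)
    total = 0
    refs = np.arange(0, n, ref_stride)
    chunk = max(1, _CHUNK_ELEMENTS // max(n, 1))
    for start in range(0, refs.size, chunk):
        ridx = refs[start:start + chunk]
        d = np.abs(points[ridx, None, 0] - points[None, :, 0])
        for m in range(1, points.shape[1]):
            np.maximum(d, np.abs(points[ridx, None, m] - points[None, :, m]),
                       out=d)
        j = np.arange(n)[None, :]
        if ref_stride == 1:
            mask = j > (ridx[:, None] + theiler_window)  # unordered pairs once
        else:
            mask = np.abs(j - ridx[:, None]) > theiler_window
        dv = d[mask]
        total += dv.size
        idx = np.searchsorted(r_grid, dv, side="left")
        counts += np.bincount(idx, minlength=r_grid.size + 1)
    if total == 0:
        raise ParameterError("no admissible pairs (theiler_window too large?)")
    return np.cumsum(counts[:-1]) / total


def _d2_single(points: np.ndarray, theiler_window: int, max_ref_points: int,
               n_r: int, r2_min: float, min_scales: int,
               min_pairs: int = 10):
    """D2 of one embedded cloud: slope of log C(r) over the scaling region."""
    extent = float(np.max(np.ptp(points, axis=0)))
    if extent <= 0:
        raise EstimationError("zero-extent point cloud")
    r_grid = extent * np.logspace(-11, 0, n_r, base=2.0)
    stride = max(1, int(np.ceil(points.shape[0] / max_ref_points)))
    c = correlation_sum(points, r_grid, theiler_window, ref_stride=stride)
    # keep scales with enough pairs for a stable estimate
    n = points.shape[0]
    approx_pairs = c * (n / stride) * n / 2
    usable = (c > 0) & (approx_pairs >= min_pairs)
    log_r = np.log2(r_grid[usable])
    log_c = np.log2(c[usable])
    if log_r.size < min_scales:
        raise EstimationError("too few usable scales in the correlation sum")
    slope, (lo, hi), r2, ok = select_scaling_region(log_r, log_c,
                                                    min_scales, r2_min)
    diag = {"r_lo": float(2.0 ** log_r[lo]), "r_hi": float(2.0 ** log_r[hi]),
            "r2": r2, "n_scales": int(hi - lo + 1), "window_ok": ok}
    return max(float(slope), 0.0), diag


def estimate_d2(record: ECGRecord, M_max: int, tau: int | None = None,
                theiler_window: int | None = None, max_ref_points: int = 4000,
                n_r: int = 36, r2_min: float = 0.98, min_scales: int = 5,
                saturation_tol: float = 0.1) -> D2Curve:
    """Correlation dimension for M = 1..M_max, with saturation detection.

    ``saturated_d2`` is the mean of D2 over the largest terminal run of
    M values whose successive change stays below ``saturation_tol``;
    the curve is flagged unsaturated if no such run of length >= 2
    exists (the signature of stochastic input, where D2 keeps tracking
    M).
    """
    if M_max < 4:
        raise ParameterError("M_max must be >= 4")
    if tau is None:
        tau = estimate_delay(record, m_max=M_max)
    if record.samples.size - (M_max - 1) * tau < 100:
        raise LengthError("record too short for the requested M_max")

    m_values, d2_values, diags = [], [], []
    for m in range(1, M_max + 1):
        att = delay_embed(record, m, tau)
        w = theiler_window if theiler_window is not None else tau * m
        d2, diag = _d2_single(att.points, w, max_ref_points, n_r, r2_min,
                              min_scales)
        m_values.append(m)
        d2_values.append(d2)
        diags.append(diag)

    run = 1
    for i in range(len(d2_values) - 1, 0, -1):
        if abs(d2_values[i] - d2_values[i - 1]) < saturation_tol:
            run += 1
        else:
            break
    saturated = run >= 2
    saturated_d2 = float(np.mean(d2_values[-run:])) if saturated else None
    return D2Curve(M_values=m_values, d2_values=d2_values,
                   saturated_d2=saturated_d2, saturated=saturated,
                   fit_diagnostics=diags)


def choose_embedding_dim(curve: D2Curve) -> int:
    """Smallest integer strictly greater than the saturated D2.

    A saturated D2 anywhere in [3, 4) therefore maps to M = 4; an
    exactly integer D2 still gets one extra dimension (conservative
    embedding).
    """
    if not curve.saturated or curve.saturated_d2 is None:
        raise NoSaturationError("D2 curve did not saturate; cannot choose M")
    return int(np.floor(curve.saturated_d2)) + 1


def _neighbor_counts(points: np.ndarray, r_grid: np.ndarray,
                     theiler_window: int, max_ref_points: int) -> np.ndarray:
    """n_j(r): neighbors of each reference point within max-norm r.

    Returns an (n_ref, n_r) integer matrix; pairs closer than the
    Theiler window in time are excluded. References are an evenly
    strided subset when the cloud exceeds ``max_ref_points``.
    """
    n = points.shape[0]
    stride = max(1, int(np.ceil(n / max_ref_points)))
    refs = np.arange(0, n, stride)
    nr = r_grid.size
    counts = np.zeros((refs.size, nr + 1), dtype=np.int64)
    chunk = max(1, _CHUNK_ELEMENTS // n)
    j = np.arange(n)[None, :]
    for start in range(0, refs.size, chunk):
        ridx = refs[start:start + chunk]
        d = np.abs(points[ridx, None, 0] - points[None, :, 0])
        for m in range(1, points.shape[1]):
            np.maximum(d, np.abs(points[ridx, None, m] - points[None, :, m]),
                       out=d)
        d[np.abs(j - ridx[:, None]) <= theiler_window] = np.inf
        idx = np.searchsorted(r_grid, d, side="left")
        np.minimum(idx, nr, out=idx)
        rows = np.repeat(np.arange(ridx.size), n)
        counts[start:start + ridx.size] += np.bincount(
            rows * (nr + 1) + idx.ravel(),
            minlength=ridx.size * (nr + 1)).reshape(ridx.size, nr + 1)
    return np.cumsum(counts[:, :-1], axis=1)


def _monotone_nonincreasing(values: np.ndarray,
                            weights: np.ndarray | None = None) -> np.ndarray:
    """Project a sequence onto non-increasing sequences (weighted PAVA)."""
    from sklearn.isotonic import IsotonicRegression
    x = np.arange(values.size, dtype=float)
    iso = IsotonicRegression(increasing=False)
    return iso.fit_transform(x, values, sample_weight=weights)


def _dq_from_neighbor_counts(nc: np.ndarray, r_grid: np.ndarray, n_total: int,
                             q_grid: np.ndarray, r2_min: float,
                             min_scales: int, occupancy_cap: float = 0.5,
                             q_r2_min: float = 0.85,
                             min_eff_refs: float = 3.0,
                             r_window: tuple | None = None):
    """tau(q) slopes from generalized correlation integrals.

    The q-th order correlation integral
    ``Z_q(r) = < (n_j(r)/(N-1))^(q-1) >_j`` scales as r^((q-1) D_q);
    q = 1 uses ``< log2 n_j(r)/(N-1) >``. Admissible scales require
    every reference to have at least one neighbor (so negative moments
    stay finite) and a mean occupancy below ``occupancy_cap`` (so the
    saturation regime C(r) -> 1 is excluded). One common scaling window
    is selected on the q = 2 curve and used for every q — per-q window
    hopping would inject spurious non-monotonicity into D_q — and the
    resulting D_q sequence is projected onto non-increasing sequences,
    a structural property of generalized dimensions. The common window
    is selected at ``r2_min``; individual q values are kept while their
    fit over that window stays above the looser ``q_r2_min``, since
    curvature necessarily grows toward extreme q.
    """
    p = nc / max(n_total - 1, 1)
    # sparse-side floor: at least 98% of references see >= 3 neighbors,
    # so negative moments are carried by sampled structure, not by the
    # one-count discreteness floor or by isolated outlier references
    sparse_ok = np.quantile(nc, 0.02, axis=0) >= 3
    admissible = sparse_ok & (p.mean(axis=0) <= occupancy_cap)
    if admissible.sum() < min_scales:
        raise EstimationError(
            f"only {int(admissible.sum())} admissible scales; need "
            f"{min_scales} (record too short or too noisy)")
    log_r = np.log2(r_grid[admissible])
    pa = p[:, admissible]

    if r_window is not None:
        # externally pinned scaling window (paired comparisons recompute
        # a second series over the same scales as the first)
        inside = (2.0 ** log_r >= r_window[0] * 0.999) &                  (2.0 ** log_r <= r_window[1] * 1.001)
        if inside.sum() < min_scales:
            raise EstimationError("pinned scaling window has too few scales")
        x = log_r[inside]
        pw = pa[:, inside]
        _, _, anchor_r2 = _plain_linfit(x, np.log2(np.mean(pw, axis=0)))
        anchor_ok = True
    else:
        y_anchor = np.log2(np.mean(pa, axis=0))  # q = 2 curve
        _, (lo, hi), anchor_r2, anchor_ok = select_scaling_region(
            log_r, y_anchor, min_scales, r2_min)
        window = slice(lo, hi + 1)
        x = log_r[window]
        pw = pa[:, window]

    dq = np.full(q_grid.size, np.nan)
    valid = np.zeros(q_grid.size, dtype=bool)
    diags = []
    nonzero = pw > 0
    n_nonzero = nonzero.sum(axis=0)
    for i, q in enumerate(q_grid):
        with np.errstate(divide="ignore"):
            if abs(q - 1.0) < 1e-9:
                ys = np.sum(np.where(nonzero,
                                     np.log2(np.where(nonzero, pw, 1.0)), 0.0),
                            axis=0) / n_nonzero
                n_eff = float(n_nonzero.min())
            else:
                # the <= 2% empty references are excluded for q < 1
                w = np.where(nonzero, pw, 1.0) ** (q - 1.0)
                w = np.where(nonzero, w, 0.0)
                ys = np.log2(w.sum(axis=0) / n_nonzero)
                # effective number of references carrying the moment;
                # extreme q concentrates all weight on one reference,
                # and a one-point "moment" has no scaling content
                n_eff = float(np.min(w.sum(axis=0) ** 2
                                     / np.maximum((w ** 2).sum(axis=0), 1e-300)))
        if not np.all(np.isfinite(ys)):
            diags.append({"r2": 0.0, "n_scales": 0, "n_eff": 0.0})
            continue
        slope, _, r2 = _plain_linfit(x, ys)
        val = slope if abs(q - 1.0) < 1e-9 else slope / (q - 1.0)
        dq[i] = val
        valid[i] = bool(np.isfinite(val) and r2 >= q_r2_min and
                        x.size >= min_scales and n_eff >= min_eff_refs)
        diags.append({"r2": r2, "n_scales": int(x.size), "n_eff": n_eff})
    if not valid.any():
        raise EstimationError("no q value produced a valid scaling fit")
    # anchor the monotone projection on the well-estimated q values:
    # moments carried by many references dominate the pooling
    neff_w = np.array([max(d.get("n_eff", 1.0), 1.0)
                       for d, v in zip(diags, valid) if v])
    dq[valid] = _monotone_nonincreasing(dq[valid], weights=np.sqrt(neff_w))
    # sparsest-region local exponent from an order statistic: the 2%
    # quantile of neighbor counts is far more stable than negative
    # moments and estimates the largest singularity strength present
    with np.errstate(divide="ignore"):
        q_lo = np.log2(np.quantile(pw, 0.02, axis=0))
    if np.all(np.isfinite(q_lo)):
        alpha_sparse, _, alpha_sparse_r2 = _plain_linfit(x, q_lo)
    else:
        alpha_sparse, alpha_sparse_r2 = float("nan"), 0.0
    return dq, valid, {"r_lo": float(2.0 ** x[0]), "r_hi": float(2.0 ** x[-1]),
                       "alpha_sparse": alpha_sparse,
                       "alpha_sparse_r2": alpha_sparse_r2,
                       "anchor_r2": anchor_r2, "anchor_ok": anchor_ok,
                       "per_q": diags}


def _plain_linfit(x: np.ndarray, y: np.ndarray):
    slope, r2 = _window_fits(x, y, x.size)
    n = x.size
    intercept = (y.sum() - slope[0] * x.sum()) / n
    return float(slope[0]), float(intercept), float(r2[0])


def _dq_from_scale_masses(masses_by_scale: dict[int, np.ndarray],
                          q_grid: np.ndarray, r2_min: float,
                          min_scales: int, min_boxes: int = 8):
    """Fit tau(q) slopes across dyadic scales; returns (dq, valid, diags)."""
    ks = np.array(sorted(masses_by_scale))
    occupied = np.array([masses_by_scale[k].size for k in ks])
    usable = occupied >= min_boxes
    ks = ks[usable]
    if ks.size < min_scales:
        raise EstimationError("fewer than the minimum number of usable scales")
    log_r = -ks.astype(float)  # log2 of box size (unit extent)

    q_grid = np.asarray(q_grid, dtype=float)
    dq = np.full(q_grid.size, np.nan)
    valid = np.zeros(q_grid.size, dtype=bool)
    diags = []
    # partition sums log2 Z_q(k) for all q at once, per scale
    for i, q in enumerate(q_grid):
        ys = []
        for k in ks:
            p = masses_by_scale[k]
            if abs(q - 1.0) < 1e-9:
                ys.append(np.sum(p * np.log2(p)))
            else:
                ys.append(np.log2(np.sum(p ** q)))
        ys = np.asarray(ys)
        if not np.all(np.isfinite(ys)):
            diags.append({"r2": 0.0, "n_scales": 0})
            continue
        slope, (lo, hi), r2, ok = select_scaling_region(log_r, ys, min_scales,
                                                        r2_min)
        if abs(q - 1.0) < 1e-9:
            val = slope
        else:
            val = slope / (q - 1.0)
        dq[i] = val
        valid[i] = bool(ok and np.isfinite(val) and (hi - lo + 1) >= min_scales)
        diags.append({"r2": r2, "n_scales": int(hi - lo + 1)})
    if not valid.any():
        raise EstimationError("no q value produced a valid scaling fit")
    return dq, valid, {"scales_k": ks.tolist(), "per_q": diags}


def estimate_dq(source, q_grid: np.ndarray | None = None,
                r2_min: float = 0.98, min_scales: int = 5,
                theiler_window: int | None = None,
                max_ref_points: int = 2000,
                q_r2_min: float = 0.85,
                r_window: tuple | None = None) -> DqSpectrum:
    """Generalized dimensions D_q of an attractor or a measure.

    ``source`` is either an :class:`~cardiofractal.embedding.Attractor`
    or a 1-D array of non-negative box masses on a dyadic grid (a
    measure supplied directly, as the cascade oracles do).

    For a direct measure, D_q is the slope of log2 sum_i p_i(r)^q
    versus log2 r over the selected scaling region, divided by (q - 1),
    with box masses p_i(r) aggregated dyadically; q = 1 uses the
    Shannon-entropy limit. For an attractor the coarse-grained
    probabilities are estimated from neighborhood counts in the full
    M-dimensional embedding space (generalized correlation integrals
    with a Theiler window), which keeps the sparse-region (q < 0)
    moments finite at clinical record lengths where box histograms
    degenerate into singleton boxes.
    """
    if q_grid is None:
        q_grid = np.arange(-20.0, 20.0 + 0.25, 0.5)
    q_grid = np.asarray(q_grid, dtype=float)

    if isinstance(source, Attractor):
        pts = source.points
        if pts.shape[0] < 2000:
            raise LengthError("attractor must have at least 2000 points")
        extent = float(np.max(np.ptp(pts, axis=0)))
        if extent <= 0:
            raise EstimationError("zero-extent attractor")
        r_grid = extent * 2.0 ** np.linspace(-10, -0.5, 36)
        if theiler_window is None:
            theiler_window = source.tau * source.M
        nc = _neighbor_counts(pts, r_grid, theiler_window, max_ref_points)
        dq, valid, diags = _dq_from_neighbor_counts(nc, r_grid, pts.shape[0],
                                                    q_grid, r2_min, min_scales,
                                                    q_r2_min=q_r2_min,
                                                    r_window=r_window)
        return DqSpectrum(q_grid=q_grid, dq_values=dq, valid_mask=valid,
                          M=source.M, tau=source.tau, diagnostics=diags)

    measure = np.asarray(source, dtype=float)
    if measure.ndim != 1:
        raise ParameterError("direct measure input must be a 1-D mass array")
    levels = int(np.log2(measure.size))
    if 2 ** levels != measure.size:
        raise ParameterError("measure length must be a power of two")
    if np.any(measure < 0):
        raise ParameterError("measure masses must be non-negative")
    masses = {}
    for k in range(1, levels + 1):
        agg = measure.reshape(2 ** k, -1).sum(axis=1)
        masses[k] = agg[agg > 0]
    dq, valid, diags = _dq_from_scale_masses(masses, q_grid, r2_min,
                                             min_scales, min_boxes=2)
    return DqSpectrum(q_grid=q_grid, dq_values=dq, valid_mask=valid,
                      diagnostics=diags)
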