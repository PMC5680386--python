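# Methods

This note documents the models, estimators and numerical choices behind
`cardiofractal`, what the synthetic generators do and do not emulate,
and the known limitations of each stage.

## Signal model and conditioning

A record is a uniformly sampled scalar series with its sampling rate.
Conditioning takes the first fixed-length segment (default 120 s — the
method targets short clinical recordings; any length covering a few
dozen beats works), removes baseline wander with a zero-phase
sharp-cutoff spectral high-pass (default 0.5 Hz), and z-scores the
result. The high-pass is implemented as a 0/1 mask on the real FFT
rather than an IIR filter: the mask makes conditioning exactly
idempotent and, on short records, avoids the seconds-long edge
transients of a Butterworth filtfilt, which are large enough
(~1% of signal scale) to masquerade as beat-to-beat variability in the
downstream scaling analysis. The cutoff and segment length are
configurable; `highpass_hz = 0` skips detrending entirely, appropriate
for synthetic signals generated without drift.

## Delay embedding

The delay τ is the first lag at which the sample autocorrelation falls
to 1/e — a deterministic, parameter-free rule — capped at
len/(2·M_max) so the embedding keeps most of the series. Alternatives
(mutual-information minimum, false nearest neighbors) are deliberately
out of scope. The embedding dimension defaults to the fixed value
M = 4, which is consistent with saturated correlation dimensions below
4 for short ECG segments; an automatic mode chooses the smallest
integer strictly greater than the saturated D₂ (strict, so an exactly
integer D₂ still gets one extra dimension). SVD projection of the
column-centered point cloud provides variance-ordered display axes;
centering is applied so the axes order by variance.

## Correlation dimension

D₂(M) is the slope of log C(r) versus log r, with C(r) the fraction of
max-norm point pairs within r, excluding pairs closer in time than a
Theiler window (default τ·M). For long series only every k-th point
serves as a reference (k chosen to keep roughly a few thousand
references); this subsampling leaves C(r) unbiased. The scaling region
is chosen automatically: the widest window of at least 5 grid points
(36 log-spaced radii spanning ~11 octaves) whose straight-line fit
reaches R² ≥ 0.98, ties broken by R²; if no window qualifies, the best
minimum-width window is used and flagged in the diagnostics.
Saturation is declared when the terminal run of |D₂(M+1) − D₂(M)| <
0.1 has length ≥ 2; its mean is the saturated D₂. Stochastic input
fails this test because D₂ keeps tracking M.

## Generalized dimensions D_q

Two input forms are supported, with different estimators:

* **Measures supplied directly** (e.g. the binomial cascade oracle on
  2^k dyadic bins): box masses are aggregated dyadically and
  D_q = slope of log₂ Σ p_i(r)^q over log₂ r divided by (q−1), with
  the Shannon-entropy limit at q = 1. On exactly scaling measures this
  is exact to rounding.
* **Embedded attractors**: coarse-grained probabilities come from
  neighborhood counts n_j(r) around ~2000 reference points (max-norm,
  Theiler window), through the generalized correlation integrals
  ⟨(n_j(r)/(N−1))^{q−1}⟩ ~ r^{(q−1)D_q}. At clinical record lengths
  (10³–10⁴ embedded points in 4-D) box histograms degenerate for
  q < 0 — singleton and boundary boxes dominate and produce
  structurally impossible spectra — while neighborhood counts remain
  finite and interpretable; correlation-integral estimation is also
  the established algorithmic route for time series.

Numerical safeguards for the attractor estimator, each of which was
necessary in practice:

* **Admissible scales**: at least 98% of references must see ≥ 3
  neighbors (negative moments must ride on sampled structure, not the
  one-count discreteness floor) and mean occupancy must stay below 0.5
  (excludes the saturation regime C(r) → 1).
* **One common scaling window for all q**, selected on the q = 2 curve
  with the same widest-window R² ≥ 0.98 rule: per-q window hopping
  injects spurious non-monotonicity into D_q. Individual q values are
  flagged invalid when their fit over that window drops below
  R² = 0.85 (curves necessarily bend toward extreme q) or when the
  moment's effective reference count (Σw)²/Σw² falls below 3 — a
  one-reference "moment" carries no scaling information.
* **Monotonicity projection**: the valid D_q sequence is projected
  onto non-increasing sequences by weighted PAVA (weights √N_eff, so
  well-estimated dense-side values anchor the pooling); D_q
  non-increasing in q is a structural property of generalized
  dimensions, not an empirical hypothesis.

## Legendre transform and the f(α) fit

τ(q) = (q−1)D_q over the valid q values is made non-decreasing
(isotonic regression) and replaced by its least concave majorant
before central finite differencing; the transform requires a concave
differentiable τ, and estimator noise otherwise folds the (α, f)
curve. Both projections are identities on exactly scaling input (all
cascade oracles pass through unchanged).

The closed form f(α) = A(α−α₁)^γ₁(α₂−α)^γ₂ has four independent
parameters: A is eliminated analytically by the stationarity condition
df/dα = 0, which puts the maximum at α₀ = (γ₁α₂+γ₂α₁)/(γ₁+γ₂), where
f is constrained to equal D₀. The fit is trust-region least squares
with bounds (α₁ below the data, α₂ above it, γ ∈ [0.05, 10]), three
deterministic starts, and points from q < −10 down-weighted ×0.5
(the sparse side carries more numerical error). Failure modes —
optimizer failure, residual RMS > 0.1, or points not spanning both
sides of the maximum — raise a typed error; batch drivers record such
records as discarded, mirroring how poorly fitting cases are dropped
from cohort analyses.

**Right-endpoint anchor.** On attractor input the descending (q < 0)
branch is usually too thin to pin α₂ by itself, leaving the endpoint
unidentified (fits run to their bounds). The record pipeline therefore
adds one pseudo-observation f = 0 at the sparsest-region local
exponent — the slope of the 2nd-percentile neighbor count versus r, an
order statistic that is far more stable than any negative moment — and
bounds α ∈ (0, 2M). This anchor is what α₂ means (the exponent of the
sparsest structure present, where f → 0) measured directly. Fits of
directly supplied (α, f) data (including all closed-form oracles) use
no anchor and recover exact parameters to ~1e−3 or better.

## Surrogate screening

IAAFT surrogates alternate spectrum and amplitude adjustment from a
seeded random shuffle, ending on an amplitude step, so the sorted
values equal the original's exactly; convergence (relative L2 spectrum
distance < 1e−3 within 1000 iterations) is tracked but non-convergent
members are kept — they still embody the null. The test statistic is
the D₂ curve; the null is rejected iff the original D₂ is strictly
below all n surrogates at every M ≥ 3, a one-sided rank test at level
1/(n+1) per dimension (default n = 19, level 0.05). With estimator
noise across correlated dimensions the empirical type-I rate stays
below 0.1 in the package's own checks.

## Classification

The "clustering" step is supervised: an RBF-kernel soft-margin SVM on
the 2-D index plane, features standardized by training-set mean/sd
(α and γ scales otherwise dominate the kernel), kernel width
γ_RBF = 1/(2·median pairwise distance²) on the standardized points,
C = 1. Splits are stratified so both classes appear on each side.
Accuracy = t_p × t_n deliberately scores a degenerate
everything-one-class classifier as zero regardless of class balance.
Decision regions are rasterized and the zero-level boundary extracted
by marching squares.

## Beat replication

R peaks come from a Pan–Tompkins-style chain (5–15 Hz band-pass,
derivative, squaring, 150 ms moving average, threshold 4× the median
envelope, 250 ms refractory distance, refinement to the local signal
maximum); beats span mid-RR to mid-RR. Tiling a beat to record length
uses whole copies truncated at the target, with a 5-sample linear
crossfade at each splice (switchable off) so splice steps do not
inject broadband artifacts. For the replicated series the delay and
embedding dimension are pinned to the full record's values — δα₁ is a
paired comparison and should not reflect a different delay choice on
an artificially periodic signal — while the D_q scaling window is
re-selected per series by the usual rule, since an exactly periodic
series legitimately scales over a different radius range than its
noisy parent (an `r_window` override exists in the config for callers
who want fully pinned scales). Replicated fits that fail are dropped
from the mean and counted; more than half failing invalidates the
record's result.

## Synthetic data: what it emulates and what it does not

The beat-train generator is five Gaussian bumps (P, Q, R, S, T) per
beat, RR intervals N(mean_rr, rr_jitter_sd) truncated at 0.2 s,
per-beat lognormal amplitude jitter (σ = morphology_jitter_sd),
sinusoidal baseline wander and white noise. Defaults: 250 Hz, mean RR
0.8 s, amplitudes (0.15, −0.1, 1, −0.25, 0.35), widths (40, 12, 16,
14, 70) ms — ordinary textbook ECG morphology. The presets differ in
morphology variability ("healthy"-like: σ = 0.15, RR jitter 0.05 s;
"unhealthy"-like: σ = 0.02, RR jitter 0.01 s), encoding the finding
that healthy dynamics are the more complex; this is a fixture
convention, not a physiological claim. What the generator does not
emulate: real pathological waveform classes (ectopy, conduction
blocks), respiratory modulation structure, measurement artifacts, or
the distinction between stationary richness and slow morphology drift
— in real cohorts the within-record variability index is elevated for
unhealthy records, while in this generator it simply grows with the
morphology-jitter knob. Passing tests therefore demonstrate that the
estimators respond correctly to controlled complexity, not that the
presets reproduce clinical populations.

The binomial cascade (weights p, 1−p, deterministic placement) is the
exact multifractal oracle: D_q = log₂(p^q + (1−p)^q)/(1−q), α range
[−log₂ max(p,1−p), −log₂ min(p,1−p)], width log₂((1−p)/p) for
p < 0.5. Chaotic fixtures (Hénon a=1.4 b=0.3, Lorenz σ=10 ρ=28 β=8/3
sampled at dt=0.02, logistic r=4) discard ≥1000 transient steps; the
seed perturbs the initial condition only.

## Problem sizes used in the checks

The packaged verification runs use: cascade p = 0.25 with 14 levels;
Hénon and Lorenz series of 20 000 points (reference subsampling to
1000–3000 points for pair counting); i.i.d.-noise D₂ up to M = 8 at
n = 20 000; the type-I-rate check on 50 AR(1) (φ = 0.7) series of
1200 points with 19 surrogates each; synthetic beat trains of 45–60 s
at 250 Hz, with 8–10 replicated beats per record and ten seeds per
morphology-jitter level. These sizes keep every estimator in its
validated regime while the full suite completes on a single CPU in
well under half an hour.

## Known limitations

* The sparse-side indices (α₂, γ₂, width) are anchored extrapolations
  on record input; they order complexity correctly but their absolute
  values are less certain than α₁, γ₁, α₀ — consistent with
  concentrating inference on the dense-side indices.
* About 1 in 20–30 synthetic records at high morphology jitter fails
  the residual threshold and is discarded; batch outputs record these
  as data.
* δα₁ in the strictly periodic limit is only as clean as the
  conditioning: detrending a drift-free signal adds small spurious
  beat-to-beat differences, hence the recommendation to disable the
  high-pass for synthetic drift-free input.
* The τ per record is data-driven; cross-record comparability of
  indices partly depends on it. Fixing τ via config is supported.
* WFDB input is optional and untested here beyond the adapter; all
  quantitative validation uses synthetic input.
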