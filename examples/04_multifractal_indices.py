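"""From a record to its multifractal index vector.

Validates the D_q -> Legendre -> parametric-fit chain on the binomial
cascade (whose spectrum is known exactly), then runs the full pipeline
on two synthetic beat trains and prints the four indices. The width
alpha2 - alpha1 measures the range of scaling exponents on the
attractor — the complexity index that separates the groups.
"""

import numpy as np

from cardiofractal import (CascadeParams, SpectrumConfig,
                           ecg_preset, estimate_dq, extract_indices,
                           fit_falpha, generate_binomial_cascade,
                           generate_synthetic_ecg, legendre_transform)

# exact oracle: the cascade's alpha range is log2(0.75/0.25) = log2 3
measure = generate_binomial_cascade(CascadeParams(p=0.25, levels=14))
spec = estimate_dq(measure, q_grid=np.arange(-20.0, 20.5, 0.5))
pts = legendre_transform(spec)
i0 = np.argmin(np.abs(pts.source_q))
fit = fit_falpha(pts, d0=float(pts.f[i0]))
print(f"cascade spectrum width = {fit.width:.4f} "
      f"(analytic log2 3 = {np.log2(3):.4f})")

config = SpectrumConfig(segment_seconds=None)
for name in ("healthy", "unhealthy"):
    rec = generate_synthetic_ecg(ecg_preset(name, duration=60.0, seed=6))
    idx = extract_indices(rec, config)
    print(f"\n{name}-like beat train (60 s):")
    print(f"  alpha1={idx.alpha1:.3f}  alpha0={idx.alpha0:.3f}  "
          f"alpha2={idx.alpha2:.3f}")
    print(f"  gamma1={idx.gamma1:.3f}  gamma2={idx.gamma2:.3f}  "
          f"width={idx.width:.3f}  (fit rms {idx.residual_rms:.3f})")
print("\nThe high-variability (healthy-like) train needs a wider range of "
      "scaling exponents: larger width = more complex dynamics.")
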