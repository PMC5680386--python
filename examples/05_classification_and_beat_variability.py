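"""Group separation and within-record variability, end to end.

Runs the full pipeline over a small synthetic cohort: index extraction
per record, SVC classification in the (alpha1, gamma1) plane with
blind-prediction accuracy tp x tn, and the beat-replication index
delta_alpha1 for each record.
"""

import numpy as np

from cardiofractal import (PipelineConfig, RecordSpec, SpectrumConfig,
                           run_all)

records = tuple(
    [RecordSpec(preset="healthy", label="healthy", seed=i, duration=40.0,
                subject_id=f"h{i}") for i in range(5)]
    + [RecordSpec(preset="unhealthy", label="unhealthy", seed=100 + i,
                  duration=40.0, subject_id=f"u{i}") for i in range(5)])

summary = run_all(PipelineConfig(
    records=records, spectrum=SpectrumConfig(segment_seconds=None),
    train_fractions=(0.5,), n_realizations=10, n_beats=8, seed=1))

print(f"{summary['n_successful']} of {summary['n_records']} records "
      f"analyzed ({len(summary['failures'])} stage failures recorded)")
for group, widths in sorted(summary["width_by_group"].items()):
    print(f"  {group:>9} widths: "
          + ", ".join(f"{w:.2f}" for w in widths))
ev = summary["classification"][0]
print(f"mean blind accuracy (tp x tn, 10 stratified splits, half "
      f"training): {ev['mean_accuracy']:.3f}")
deltas = [abs(b["delta_alpha1"]) for b in summary["beat_replication"]]
print(f"|delta_alpha1| across records: median {np.median(deltas):.3f}, "
      f"max {max(deltas):.3f}")
print("Wider healthy-like spectra and high blind accuracy reproduce the "
      "intended group separation on synthetic data.")
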