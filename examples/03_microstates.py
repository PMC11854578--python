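"""Microstate analysis of one recording.

Extracts maps at Global Field Power peaks, clusters them into four
polarity-invariant template topographies with the modified K-means,
backfits the templates onto every time point and prints the temporal
statistics (duration, occurrence, coverage, transition probabilities).
"""

import numpy as np

from eegsel.microstate import gfp, gfp_peaks, microstates_for_recording
from eegsel.preprocess import PreprocessConfig, run_preprocess
from eegsel.synth import control_profile, generate_recording

rec = run_preprocess(
    generate_recording(control_profile(), duration_s=12, fs=256, seed=3),
    PreprocessConfig(),
)

g = gfp(rec)
peaks = gfp_peaks(g, fs=rec.fs, min_separation_ms=10)
print(f"GFP peaks: {len(peaks)} over {rec.duration_s:g} s "
      f"({len(peaks) / rec.duration_s:.1f} per second)")

model, labels, stats, flags = microstates_for_recording(rec, k=4, seed=0)
print(f"fitted k=4 microstates, GEV = {model.gev:.2f}"
      + (" (flagged: below the 0.5 floor)" if flags["low_gev"] else ""))
for j in range(4):
    print(f"  class {j}: coverage {stats.coverage[j]:.2f}, "
          f"mean duration {stats.mean_duration_ms[j]:.0f} ms, "
          f"{stats.occurrence_per_s[j]:.1f} occurrences/s")
print("transition matrix rows sum to", np.round(stats.transitions.sum(axis=1), 3))
# Classes are ordered by descending coverage; durations of tens of ms are
# the expected scale for resting-state microstates.
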