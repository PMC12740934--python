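"""Synthetic ECG: generation, beat detection and apnea-segment extraction.

Generates one 20-minute recording whose minutes 5-14 carry the slow cyclic
RR-interval modulation typical of recurrent apneas, runs the full
preprocessing chain, and prints what each stage produced.
"""

import numpy as np

from spikeformer.ecg import (
    bandpass_ecg,
    correct_beat_series,
    detect_r_peaks,
    make_apnea_segments,
)
from spikeformer.synth import SynthECGSpec, gen_ecg

spec = SynthECGSpec(
    duration_min=20,
    base_hr=65,
    apnea_minutes=frozenset(range(5, 15)),
    seed=7,
)
record, truth, minute_labels = gen_ecg(spec)
print(f"generated {record.duration:.0f} s of ECG at {record.fs:.0f} Hz, "
      f"{len(truth.r_times)} programmed beats")

filtered = bandpass_ecg(record)
beats = correct_beat_series(detect_r_peaks(filtered))
err = abs(len(beats.r_times) - len(truth.r_times))
print(f"detected {len(beats.r_times)} beats ({err} off the programmed count); "
      f"{int(beats.flagged.sum())} RR intervals repaired")

segments = make_apnea_segments(beats, minute_labels, record_id="demo")
print(f"{len(segments)} five-minute segments "
      f"({segments.n_faulty} dropped at the recording boundary), "
      f"{int(segments.labels.sum())} labelled apneic")

apnea_sd = segments.features[segments.labels == 1, 0].std(axis=1).mean()
normal_sd = segments.features[segments.labels == 0, 0].std(axis=1).mean()
print(f"RRI-channel variability  apnea {apnea_sd:.3f} s  vs  normal {normal_sd:.3f} s")
print("\nApnea minutes show the smooth 0.025 Hz RRI oscillation, normal minutes "
      "only\nwhite jitter - exactly the structure the classifier learns to separate.")
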