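"""Motor-imagery EEG: common average reference and the ERD class signal.

Generates synthetic 22-channel epochs with lateralised mu-rhythm
attenuation, applies CAR and mu-band filtering, and measures how well a
training-free band-power discriminant separates left- from right-hand
trials.
"""

import numpy as np

from spikeformer.eeg import car_filter, mu_lateralization_score
from spikeformer.metrics import rank_auc
from spikeformer.synth import SynthEEGSpec, gen_eeg

epochs = gen_eeg(SynthEEGSpec(n_trials=120, erd_depth=0.6, seed=3))
print(f"{len(epochs)} epochs of shape {epochs.epochs.shape[1:]} "
      f"({(epochs.labels == 0).sum()} left / {(epochs.labels == 1).sum()} right)")

referenced = car_filter(epochs.epochs)
print("channel mean after CAR:", float(np.abs(referenced.mean(axis=1)).max()))

score = mu_lateralization_score(referenced)
auc = rank_auc(1 - epochs.labels, score)
print(f"mu-band lateralisation AUC (left vs right): {auc:.3f}")
print(
    "\nImagining one hand suppresses the mu rhythm over the opposite "
    "hemisphere\n(event-related desynchronisation); the log-power asymmetry "
    "alone separates the\nclasses, which is the structure the spiking "
    "Transformer exploits when trained."
)
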