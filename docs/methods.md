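# Methods

## The model

`spikeformer` classifies fixed-length physiological signal segments with a
hybrid of a spiking neural network and a Transformer.  The spiking unit is a
stateless hard threshold applied elementwise: a unit emits `S = 1` when its
input ("membrane potential") `V` reaches the threshold and `0` otherwise,
with the tie at equality resolved toward firing for determinism.  The unit
deliberately has no membrane time loop, leak, reset or refractory state —
the sequence axis of the data carries time, and the spiking unit replaces
ordinary activation functions inside an otherwise conventional architecture.

Because the threshold has zero gradient almost everywhere, training uses a
sigmoid **surrogate gradient**: the backward pass propagates

    dS/dV ≈ σ(V − threshold) · (1 − σ(V − threshold)) · temp

where σ is the unit-temperature logistic and `temp` (default 5.0) sets the
sharpness.  A smoothed firing probability `σ(temp·(V − threshold))` is also
exposed; it converges pointwise to the hard threshold as `temp → ∞`.  The
two forms place the temperature differently (inside the sigmoid for the
probability, outside for the gradient); they agree only up to scaling, and
we implement both exactly as defined, using the second for backpropagation.
The threshold (default 0.5) and temperature are fixed, not learned.

**Spiking multi-head attention (SMHA)** is standard multi-head scaled
dot-product attention,

    Attention(Q, K, V) = softmax(QKᵀ/√d_k) V,

whose output — after head concatenation and the output projection — passes
through the spiking unit, so the attended representation is a binary,
event-like code.  Softmax uses max-subtraction stabilisation; all four
projections carry biases; no masking is used because every task is
whole-segment classification.  Applying the spiking unit after the output
projection (rather than per head) follows from treating the whole attention
expression as the spiking unit's input.

**Architecture.**  Input segments pass through a three-layer 1-D CNN
(filters 32, 64, 64; kernel 17; same padding; max-pool 2 per stage), giving
a 64-wide feature sequence one-eighth the input length.  Fixed sinusoidal
positional encoding (zero parameters) is added.  One encoder block
(pre-norm: LayerNorm → SMHA → residual; LayerNorm → FFN 64→128→64 with the
spiking activation between the linear maps → residual) feeds one decoder
block (spiking self-attention, standard cross-attention over the encoder
output, spiking FFN).  The decoder is non-autoregressive: classification
has no target sequence, so the decoder consumes the same CNN feature
sequence and attends to the encoder memory.  Mean-pooling over the sequence
and a dense head (sigmoid for binary, softmax otherwise) produce the class
probabilities.  The CNN nonlinearity is the spiking unit by default
(configurable to ReLU); post-norm residual ordering is available behind a
flag.

With two input channels this reference configuration has exactly **189,473
trainable parameters**: 105,696 in the CNN (1,120 + 34,880 + 69,696),
33,472 per encoder block (16,640 attention + 16,576 FFN + 256 norm), 50,240
per decoder block (2×16,640 + 16,576 + 384) and 65 in the head.  The
unstated depth/width choices (d_model 64, 4 heads, FFN 128, one block each,
mean-pool, no final norm) were pinned jointly so that this total lands on
the published "189K" budget; that count is the calibration anchor for the
architecture.

**Ablation variants** build from the same configuration: `snn_only` removes
the attention sublayers (spiking CNN + spiking FFN blocks only; 139,169
parameters) and `transformer_only` replaces every spiking activation with
ReLU at identical parameter count.

**Implementation.**  The network and its training loop run on a small
reverse-mode autodiff engine over numpy arrays (`spikeformer.autograd`),
with im2col-based convolution, batched matmul attention and float32
parameters; the spiking activation registers the surrogate as its custom
backward.  Gradients were verified against centred finite differences for
every primitive.

## Training protocol

Adam, initial learning rate 1e-3, batch size 16, up to 100 epochs.  Early
stopping ends training after 30 epochs without validation-loss improvement
and the best-validation weights are restored.  The learning rate is halved
after 10 non-improving epochs (reduce-on-plateau, floor 1e-5; the factor,
patience and floor are this package's choices — only the strategy is
prescribed).  Binary tasks use logit-stable binary cross-entropy,
multi-class tasks categorical cross-entropy.  Everything is seeded: model
initialisation and the dropout stream at construction, batch shuffling in
the trainer, so identical seeds give identical weights.

Split protocols: five-fold cross-validation stratified by label and grouped
by recording for the minute-labelled ECG corpus (grouping prevents
recording-level leakage; the published protocol does not say whether folds
are segment- or recording-level, and grouping is the conservative choice);
8:1:1 train/validation/test for the window-labelled corpus; and a session
split for motor imagery where the evaluation session is re-split 80/20 with
the test share rounded down (144 epochs → 115/29).

## ECG preprocessing

Recordings are band-pass filtered 0.5–40 Hz with a zero-phase FIR filter
(symmetric taps applied by FFT convolution; ~16 s of taps so 0.1 Hz
baseline drift is attenuated ≥ 20 dB — only "a FIR bandpass filter" is
prescribed, the band and order are ours) and z-scored per recording.
R peaks come from a Hamilton-style detector: 8–16 Hz band-limited
differentiation, rectification, 80 ms moving-window integration, dual
adaptive QRS/noise thresholds (threshold fraction 0.3125 between the
running noise and QRS peak means), a 200 ms refractory period and a
search-back pass that revisits sub-threshold candidates when an RR gap
exceeds 1.5× the recent mean.  Peak positions are refined to the local
signal maximum.

RR-interval artifacts are flagged when an interval deviates more than 20%
from the 5-point running median (the method is prescribed, the constant is
ours) and repaired by cubic interpolation over neighbouring valid
intervals; R amplitudes at flagged beats are interpolated identically.
More than 50% flagged intervals aborts the recording as unusable.

For minute-labelled recordings, each labelled minute yields one segment:
the 5-minute context centred on that minute is resampled by cubic
interpolation onto a uniform 3 Hz grid, giving 900 RRI and 900 R-amplitude
points (3 Hz is forced by 900 points over 300 s); the label is the central
minute's.  Segments are dropped as faulty when the context leaves the
recording, fewer than 100 beats fall in the window, more than 50% of its
RRIs were artifact-flagged, or any corrected RRI leaves [0.3, 3.0] s.  The
published segment counts imply such a rule without stating it; these
constants are exposed in the quality configuration.  For second-labelled
recordings, overlapping 11 s windows with a 1 s stride carry the raw
normalised signal, labelled by the window's 2nd second (an apnea is ≥ 10 s
of cessation, so an 11 s window spans a full event).  Minority-class
oversampling by random duplication is applied to training/validation
indices only, never across a test boundary.

## EEG preprocessing

Common average referencing subtracts the instantaneous cross-channel mean
from every channel (`x_i ← x_i − mean_j x_j`), removing reference-shared
noise; it is idempotent and commutes with the subsequent linear band-pass.
Mu (8–14 Hz) and beta (15–30 Hz) rhythms are extracted with a zero-phase
FIR band-pass, by default as a single 8–30 Hz pass (a dual-band option
exists; the source protocol does not state whether the bands were
concatenated).  Trials are epoched 0.5–4.5 s after the cue (1,000 samples
at 250 Hz; the window is this package's choice, exposed in configuration),
EOG channels are dropped rather than regressed, and only the left/right-hand
classes are kept (the binary task; 4-class decoding is out of scope).

## Evaluation

Per-segment: accuracy, sensitivity (apnea positive), specificity,
precision, F1, Cohen's kappa ((p_o − p_e)/(1 − p_e) with confusion-matrix
marginals) and rank-based AUC (Mann–Whitney statistic, tie-aware; verified
to equal the trapezoidal ROC integral).  The decision threshold is 0.5.

Per-recording: the apnea-hypopnea index `AHI = 60·N/T` over the T labelled
minutes of a recording, of which N are called apneic; a recording is
screened as sleep apnea when AHI **strictly exceeds** 5 events/hour (the
boundary goes to normal).  Recording-level accuracy/sensitivity/specificity
(SA positive), AUC over predicted AHI, and the Pearson correlation between
predicted and true AHI lists complete the report; correlation is reported
as missing when either list has zero variance.

## Synthetic data

The ECG generator emits Gaussian QRS-like pulses (30 ms full width at half
maximum, unit amplitude) at programmed beat times.  Inside "apnea" minutes
the RR series oscillates sinusoidally at 0.025 Hz with 0.12 s amplitude —
mimicking the ~30–60 s cyclic cardiovascular response to recurrent apneas,
a premise of ECG-based screening rather than a published parameter — and
the R amplitude is co-modulated ±10% so both feature channels are
informative.  Normal minutes carry white RR jitter (sd 0.05 s) only.  A
cohort helper draws the per-recording heart rate from 55–85 bpm and the
apnea burden from 0–70% of minutes placed in contiguous 3–10 minute
episodes, so per-recording AHI spans normal (≤ 5) through severe and the
predicted-vs-true AHI correlation is meaningful.  The generator returns the
programmed beat times and labels, so detector accuracy is measured against
ground truth.

The EEG generator emits 22-channel epochs of 1/f (pink) noise plus a
9–13 Hz rhythm over the two lateral sensorimotor channel groups; the group
contralateral to the imagined hand is attenuated by `erd_depth` in power
(default 0.6).  At `erd_depth = 0` the classes are indistinguishable by
construction (a null check); at the default the mu-band lateralisation
discriminant separates classes with AUC > 0.9 without any training.

What the generators do **not** model: real QRS morphology and its
pathological variants, non-apneic heart-rate variability structure
(respiratory sinus arrhythmia, circadian drift), movement and electrode
artifacts, EEG volume conduction, eye blinks and non-stationary background
rhythms, or annotation noise.  Passing the end-to-end tests therefore
demonstrates that the architecture, gradients, preprocessing and evaluation
plumbing are correct and that the model can learn the kind of slow cyclic
versus broadband-noise distinction the task rests on — not that the
published accuracies on the real corpora are reproduced.  Reproducing those
requires downloading the three public datasets and running the same
pipeline through the provided readers.

## Problem sizes and numerics

The default end-to-end experiment trains on 40 synthetic recordings of 60
minutes (≈ 2,240 usable segments after boundary minutes are dropped),
split 70/10/20 by recording, for up to 10 epochs (ablations 6) — the task
is learned within the first few epochs, and these sizes keep a full run in
a few CPU-minutes while exercising every component at full model size.
Float32 is used for network parameters and activations (float64 for
gradient checks); softmax and binary cross-entropy use the standard
max-subtraction/logit-stable forms; layer-norm epsilon is 1e-5; Adam uses
(0.9, 0.999, 1e-8).  Degenerate inputs are defined: flat-line ECG yields an
empty flagged beat series, single-channel CAR returns zeros with a warning,
single-class AUC and zero-variance correlation are reported as missing
rather than raised.

## Known limitations

The spiking unit is rate-free and stateless; no leaky integration,
refractoriness or spike encoding of the inputs is modelled, and no
neuromorphic-hardware export exists.  The WFDB/EDF support covers exactly
the single-signal formats those corpora use (format 16/212 signals, MIT
minute annotations, one-channel EDF fixtures), not the full specifications.
GDF files are read through `mne`; no GDF writer exists in this environment,
so the GDF reader's round-trip is untested (epoching is tested on in-memory
sessions instead).  Training on one CPU in numpy is minutes-per-run at the
default sizes; there is no GPU path.
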