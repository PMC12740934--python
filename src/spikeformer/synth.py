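"""Synthetic ECG and EEG generators with the statistical structure the
classifiers exploit.

The ECG generator emits trains of Gaussian QRS-like pulses whose RR-interval
series carries, inside "apnea" minutes, a slow sinusoidal modulation (default
0.025 Hz, mimicking the ~30-60 s cardiovascular oscillation that accompanies
recurrent apneas) and, inside "normal" minutes, white RR jitter only.  R-wave
amplitude is co-modulated by ±10% in apnea minutes so both feature channels
are informative.  Ground-truth beat times and minute labels are returned so
detector accuracy can be measured against the programmed series.

The EEG generator emits 22-channel epochs of pink noise plus an 8-14 Hz mu
rhythm over the two lateral sensorimotor channel groups; the group
contralateral to the imagined hand is attenuated (event-related
desynchronisation).  It does not model volume conduction, eye artifacts or
non-stationary background rhythms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ecg import BeatSeries, ECGRecord
from .eeg import (
    BCI2A_EEG_CHANNELS,
    EEGEpochSet,
    EEGSession,
    LEFT_MOTOR_CHANNELS,
    RIGHT_MOTOR_CHANNELS,
)

__all__ = [
    "SynthECGSpec",
    "SynthEEGSpec",
    "gen_ecg",
    "gen_eeg",
    "gen_eeg_session",
    "make_ecg_dataset",
    "random_apnea_minutes",
]


@dataclass(frozen=True)
class SynthECGSpec:
    """Recipe for one synthetic single-lead ECG recording.

    ``cyclic_mod_amp``/``cyclic_mod_freq`` define the RRI oscillation inside
    apnea minutes (seconds / Hz); ``jitter_sd`` the white RRI noise inside
    normal minutes.  ``base_hr`` is the mean heart rate in bpm.
    """

    duration_min: int = 60
    fs: float = 100.0
    base_hr: float = 60.0
    apnea_minutes: frozenset[int] = frozenset()
    cyclic_mod_amp: float = 0.12
    cyclic_mod_freq: float = 0.025
    jitter_sd: float = 0.05
    qrs_width_s: float = 0.030
    amp_mod_frac: float = 0.10
    signal_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not self.cyclic_mod_amp < 0.5 * 60.0 / self.base_hr:
            raise ValueError("cyclic modulation amplitude must be < half the base RRI")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def gen_ecg(spec: SynthECGSpec) -> tuple[ECGRecord, BeatSeries, np.ndarray]:
    """Generate one recording; returns (record, ground-truth beats, minute labels)."""
    rng = np.random.default_rng(spec.seed)
    base_rri = 60.0 / spec.base_hr
    duration = 60.0 * spec.duration_min
    apnea = spec.apnea_minutes

    r_times = [0.3]
    while True:
        t = r_times[-1]
        minute = int(t // 60.0)
        if minute in apnea:
            rri = base_rri + spec.cyclic_mod_amp * np.sin(
                2.0 * np.pi * spec.cyclic_mod_freq * t
            )
        else:
            rri = base_rri + rng.normal(0.0, spec.jitter_sd)
        rri = max(rri, 0.3)
        if t + rri >= duration - 0.3:
            break
        r_times.append(t + rri)
    r_times = np.asarray(r_times)

    amps = np.ones(len(r_times))
    for i, t in enumerate(r_times):
        if int(t // 60.0) in apnea:
            amps[i] += spec.amp_mod_frac * np.sin(
                2.0 * np.pi * spec.cyclic_mod_freq * t
            )

    n = int(duration * spec.fs)
    tgrid = np.arange(n) / spec.fs
    sig = np.zeros(n)
    sigma = spec.qrs_width_s / 2.355  # FWHM -> Gaussian sigma
    half = int(4 * sigma * spec.fs) + 1
    for t, a in zip(r_times, amps):
        c = int(round(t * spec.fs))
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        sig[lo:hi] += a * np.exp(-0.5 * ((tgrid[lo:hi] - t) / sigma) ** 2)
    if spec.signal_noise_sd > 0:
        sig += rng.normal(0.0, spec.signal_noise_sd, size=n)

    labels = np.array(
        [1 if m in apnea else 0 for m in range(spec.duration_min)], dtype=np.int64
    )
    truth = BeatSeries(r_times, np.diff(r_times), amps)
    record = ECGRecord(sig, spec.fs, minute_labels=labels)
    return record, truth, labels


def random_apnea_minutes(
    duration_min: int, fraction: float, rng: np.random.Generator
) -> frozenset[int]:
    """Place apnea episodes as contiguous blocks of 3-10 minutes."""
    target = int(round(fraction * duration_min))
    minutes: set[int] = set()
    guard = 0
    while len(minutes) < target and guard < 1000:
        guard += 1
        length = int(rng.integers(3, 11))
        start = int(rng.integers(0, max(duration_min - length, 1)))
        minutes.update(range(start, min(start + length, duration_min)))
    return frozenset(sorted(minutes)[:target])


def make_ecg_dataset(
    n_recordings: int = 40,
    duration_min: int = 60,
    seed: int = 1,
    apnea_fraction_range: tuple[float, float] = (0.0, 0.7),
    base_hr_range: tuple[float, float] = (55.0, 85.0),
) -> list[tuple[ECGRecord, BeatSeries, np.ndarray]]:
    """A cohort of synthetic recordings with varied apnea burden and heart rate.

    Apnea fractions span ``apnea_fraction_range`` so per-recording AHI varies
    enough for a meaningful predicted-vs-true correlation; fractions below
    5/60 yield AHI <= 5, i.e. screening-normal recordings, so the cohort
    mixes apneic and normal subjects.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_recordings):
        frac = rng.uniform(*apnea_fraction_range)
        spec = SynthECGSpec(
            duration_min=duration_min,
            base_hr=float(rng.uniform(*base_hr_range)),
            apnea_minutes=random_apnea_minutes(duration_min, frac, rng),
            seed=int(rng.integers(2**31)),
        )
        record, truth, labels = gen_ecg(spec)
        record.record_id = f"synth{i:03d}"
        out.append((record, truth, labels))
    return out


# ---------------------------------------------------------------------------
# EEG


@dataclass(frozen=True)
class SynthEEGSpec:
    """Recipe for synthetic motor-imagery EEG epochs.

    ``erd_depth`` is the fractional attenuation of 8-14 Hz band *power* on
    the channel group contralateral to the imagined hand (0 = no class
    signal, 1 = rhythm fully suppressed).
    """

    n_trials: int = 144
    fs: float = 250.0
    n_channels: int = 22
    epoch_len: int = 1000
    erd_depth: float = 0.6
    rhythm_amp: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError("erd_depth must be in [0, 1]")


def _pink_noise(rng: np.random.Generator, shape: tuple, fs: float) -> np.ndarray:
    """1/f-shaped noise along the last axis, unit variance."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f[0] = f[1]
    spec /= np.sqrt(f)
    pink = np.fft.irfft(spec, n=n, axis=-1)
    return pink / (pink.std(axis=-1, keepdims=True) + 1e-12)


def _make_epoch(
    rng: np.random.Generator, spec: SynthEEGSpec, label: int
) -> np.ndarray:
    """One (C, T) epoch; label 0 = left hand, 1 = right hand."""
    t = np.arange(spec.epoch_len) / spec.fs
    x = spec.noise_sd * _pink_noise(rng, (spec.n_channels, spec.epoch_len), spec.fs)
    freq = rng.uniform(9.0, 13.0)
    atten = np.sqrt(1.0 - spec.erd_depth)  # power -> amplitude
    for group, attenuated in (
        (LEFT_MOTOR_CHANNELS, label == 1),  # left cortex: contralateral to right hand
        (RIGHT_MOTOR_CHANNELS, label == 0),
    ):
        amp = spec.rhythm_amp * (atten if attenuated else 1.0)
        for ch in group:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            x[ch] += amp * np.sin(2.0 * np.pi * freq * t + phase)
    return x


def gen_eeg(spec: SynthEEGSpec) -> EEGEpochSet:
    """Generate balanced, shuffled epochs with ground-truth labels."""
    rng = np.random.default_rng(spec.seed)
    half = spec.n_trials // 2
    labels = np.array([0] * half + [1] * (spec.n_trials - half), dtype=np.int64)
    rng.shuffle(labels)
    epochs = np.stack([_make_epoch(rng, spec, int(lab)) for lab in labels])
    names = list(BCI2A_EEG_CHANNELS[: spec.n_channels])
    return EEGEpochSet(epochs, labels, spec.fs, names)


def gen_eeg_session(
    spec: SynthEEGSpec, trial_spacing_s: float = 8.0, cue_offset_s: float = 2.0
) -> tuple[EEGSession, list[tuple[int, int]]]:
    """A continuous session (22 EEG + 3 EOG channels) with cue events.

    Trials are spaced ``trial_spacing_s`` apart; the imagery rhythm occupies
    0.5-4.5 s after each cue.  Returns the session and ``(cue_sample,
    class_id)`` events, suitable for testing trial epoching.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n_total = int((spec.n_trials * trial_spacing_s + cue_offset_s + 2.0) * fs)
    n_ch = spec.n_channels + 3
    data = spec.noise_sd * _pink_noise(rng, (n_ch, n_total), fs)
    half = spec.n_trials // 2
    labels = np.array([0] * half + [1] * (spec.n_trials - half), dtype=np.int64)
    rng.shuffle(labels)
    events = []
    for k, lab in enumerate(labels):
        cue = int((k * trial_spacing_s + cue_offset_s) * fs)
        events.append((cue, int(lab)))
        start = cue + int(0.5 * fs)
        epoch = _make_epoch(rng, spec, int(lab))
        data[: spec.n_channels, start : start + spec.epoch_len] = epoch
    names = list(BCI2A_EEG_CHANNELS[: spec.n_channels]) + [
        "EOG-left", "EOG-central", "EOG-right",
    ]
    return EEGSession(data, fs, names), events
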