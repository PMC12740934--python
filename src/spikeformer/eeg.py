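"""EEG spatial and spectral preprocessing for motor imagery.

Common average referencing (CAR) subtracts the instantaneous mean across all
channels from every channel, removing noise shared through the reference
electrode:

    x_i_CAR(t) = x_i(t) - (1/C) * sum_j x_j(t)

Band-pass filtering then isolates the sensorimotor mu (8-14 Hz) and beta
(15-30 Hz) rhythms whose event-related desynchronisation carries the
left/right-hand class information; by default both are extracted in a single
8-30 Hz pass.  Trial epoching cuts the motor-imagery period (0.5-4.5 s after
the cue) out of a continuous session, keeps the left/right-hand classes and
drops the EOG channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "EEGSession",
    "EEGEpochSet",
    "BCI2A_EEG_CHANNELS",
    "BANDS",
    "LEFT_MOTOR_CHANNELS",
    "RIGHT_MOTOR_CHANNELS",
    "car_filter",
    "bandpass_mu_beta",
    "epoch_trials",
    "mu_lateralization_score",
]

# 22-channel montage of the four-class motor-imagery benchmark
BCI2A_EEG_CHANNELS = (
    "Fz", "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
    "P1", "Pz", "P2", "POz",
)

BANDS: dict[str, tuple[float, float]] = {
    "mu": (8.0, 14.0),
    "beta": (15.0, 30.0),
    "combined": (8.0, 30.0),
}

LEFT_HAND, RIGHT_HAND = 0, 1

# channel indices over the left / right sensorimotor cortex in the montage
# above (around C3 and C4 respectively)
LEFT_MOTOR_CHANNELS = (6, 7, 8, 13)
RIGHT_MOTOR_CHANNELS = (10, 11, 12, 17)


@dataclass
class EEGSession:
    """A continuous multi-channel recording (channels x samples)."""

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("session data must be (channels, samples)")


@dataclass
class EEGEpochSet:
    """Labelled trials: epochs (n_trials, channels, samples) + class ids."""

    epochs: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_trials, channels, samples)")
        if len(self.labels) != len(self.epochs):
            raise ValueError("labels and epochs disagree in length")

    def __len__(self) -> int:
        return len(self.epochs)


def car_filter(epochs: np.ndarray) -> np.ndarray:
    """Common average reference: subtract the cross-channel mean per sample.

    Accepts (channels, samples) or (n_trials, channels, samples); the channel
    axis is the second-to-last.  After CAR the channel mean is exactly zero
    at every time point; applying CAR twice equals applying it once.
    """
    x = np.asarray(epochs, dtype=float)
    if x.ndim < 2:
        raise ValueError("need at least (channels, samples)")
    c_axis = x.ndim - 2
    if x.shape[c_axis] == 1:
        warnings.warn("CAR with a single channel is degenerate (all-zero output)")
    return x - x.mean(axis=c_axis, keepdims=True)


def bandpass_mu_beta(
    epochs: np.ndarray,
    band: str | tuple[float, float] = "combined",
    fs: float = 250.0,
    numtaps: int | None = None,
) -> np.ndarray:
    """Zero-phase FIR band-pass per channel over the named or explicit band.

    ``band`` is one of ``"mu"`` (8-14 Hz), ``"beta"`` (15-30 Hz),
    ``"combined"`` (8-30 Hz) or an explicit ``(low, high)`` pair.
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    if hi >= fs / 2 or lo <= 0:
        raise ValueError(f"band edges ({lo}, {hi}) must lie inside (0, fs/2)")
    x = np.asarray(epochs, dtype=float)
    if numtaps is None:
        numtaps = int(2 * fs) | 1
    if x.shape[-1] <= numtaps:
        numtaps = (x.shape[-1] // 2) | 1
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs, window="hamming")
    shape = (1,) * (x.ndim - 1) + (-1,)
    return sps.fftconvolve(x, taps.reshape(shape), mode="same", axes=-1)


def epoch_trials(
    session: EEGSession,
    events: list[tuple[int, int]],
    tmin: float = 0.5,
    tmax: float = 4.5,
    classes: tuple[int, ...] = (LEFT_HAND, RIGHT_HAND),
    drop_eog: bool = True,
) -> EEGEpochSet:
    """Cut the imagery period ``[tmin, tmax)`` after each cue into epochs.

    Keeps only the requested classes (left/right hand by default) and drops
    channels whose name starts with ``EOG``.  Trials whose window leaves the
    recording raise an error listing the offending trial ids.
    """
    if not events:
        raise ValueError("no events supplied")
    fs = session.fs
    n_samp = int(round((tmax - tmin) * fs))
    keep_ch = [
        i
        for i, name in enumerate(session.channel_names)
        if not (drop_eog and name.upper().startswith("EOG"))
    ] or list(range(session.data.shape[0]))
    bad = [
        k
        for k, (onset, _) in enumerate(events)
        if onset + int(tmin * fs) < 0
        or onset + int(tmin * fs) + n_samp > session.data.shape[1]
    ]
    if bad:
        raise ValueError(f"trial windows leave the recording for trials {bad}")
    epochs, labels = [], []
    for onset, cls in events:
        if cls not in classes:
            continue
        s0 = onset + int(tmin * fs)
        epochs.append(session.data[keep_ch, s0 : s0 + n_samp])
        labels.append(cls)
    names = [session.channel_names[i] for i in keep_ch] if session.channel_names else []
    if not epochs:
        return EEGEpochSet(
            np.empty((0, len(keep_ch), n_samp)), np.empty(0, dtype=np.int64), fs, names
        )
    return EEGEpochSet(np.stack(epochs), np.array(labels), fs, names)


def mu_lateralization_score(
    epochs: np.ndarray,
    fs: float = 250.0,
    left=LEFT_MOTOR_CHANNELS,
    right=RIGHT_MOTOR_CHANNELS,
) -> np.ndarray:
    """Left-minus-right mu-band log-power per trial.

    A simple event-related-desynchronisation readout: imagining the right
    hand suppresses the left-cortex mu rhythm, lowering the score, and vice
    versa.  Used as an independent (training-free) discriminant for the
    lateralised class structure.
    """
    mu = bandpass_mu_beta(epochs, "mu", fs=fs)
    power = (mu**2).mean(axis=-1)
    return np.log(power[:, list(left)].mean(axis=1)) - np.log(
        power[:, list(right)].mean(axis=1)
    )


def dual_band_stack(epochs: np.ndarray, fs: float = 250.0) -> np.ndarray:
    """Stack separate mu- and beta-filtered copies along the channel axis.

    The alternative to the default single 8-30 Hz pass: each trial becomes
    (2*C, T) with the mu-band channels first.
    """
    mu = bandpass_mu_beta(epochs, "mu", fs=fs)
    beta = bandpass_mu_beta(epochs, "beta", fs=fs)
    return np.concatenate([mu, beta], axis=-2)
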