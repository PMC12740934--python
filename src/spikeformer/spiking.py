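"""Threshold spiking activation with a sigmoid surrogate gradient.

The forward pass is a hard threshold: a unit emits a spike (1) whenever its
membrane potential reaches the threshold, and stays silent (0) otherwise.
Because this step function has zero gradient almost everywhere, training uses
a *surrogate gradient*: the backward pass pretends the activation were a
sigmoid and propagates

    dS/dV ≈ sigma(V - threshold) * (1 - sigma(V - threshold)) * temp

where ``sigma`` is the unit-temperature logistic function and ``temp``
controls the sharpness of the approximation.  A smoothed firing probability
``sigma(temp * (V - threshold))`` is also exposed; it converges pointwise to
the hard threshold as ``temp`` grows.

Note the two conventions differ: the smoothed probability places ``temp``
inside the sigmoid, while the surrogate gradient is the unit-temperature
sigmoid derivative scaled by ``temp``.  Both are implemented exactly as
stated; the backward pass uses the latter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, _sigmoid

__all__ = [
    "SpikeActivationConfig",
    "spike_forward",
    "smoothed_firing_probability",
    "surrogate_gradient",
    "spiking_activation",
]


@dataclass(frozen=True)
class SpikeActivationConfig:
    """Parameters of the spiking unit.

    threshold
        Membrane-potential level at which a spike is emitted (dimensionless).
    temp
        Temperature controlling the sharpness of the surrogate sigmoid; must
        be positive.  Larger values concentrate the surrogate gradient around
        the threshold.
    """

    threshold: float = 0.5
    temp: float = 5.0

    def __post_init__(self):
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if not (self.temp > 0):
            raise ValueError("temp must be > 0")


def _check_finite(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float) if not isinstance(v, np.ndarray) else v
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential contains non-finite values")
    return v


def spike_forward(v, cfg: SpikeActivationConfig = SpikeActivationConfig()) -> np.ndarray:
    """Hard-threshold spike generation: 1 where ``v >= threshold``, else 0.

    The tie at ``v == threshold`` emits a spike (>= convention).
    """
    v = _check_finite(np.asarray(v))
    return (v >= cfg.threshold).astype(v.dtype if v.dtype.kind == "f" else np.float64)

def smoothed_firing_probability(
    v, cfg: SpikeActivationConfig = SpikeActivationConfig()
) -> np.ndarray:
    """Smoothed firing probability ``sigma(temp * (v - threshold))`` in (0, 1)."""
    v = _check_finite(np.asarray(v, dtype=float))
    return _sigmoid(cfg.temp * (v - cfg.threshold))


def surrogate_gradient(
    v, cfg: SpikeActivationConfig = SpikeActivationConfig()
) -> np.ndarray:
    """Sigmoid surrogate derivative ``sigma(v-th) * (1 - sigma(v-th)) * temp``.

    ``sigma`` here is the plain unit-temperature logistic.  Strictly positive,
    symmetric about the threshold, maximal (``temp/4``) at the threshold.
    """
    v = _check_finite(np.asarray(v, dtype=float))
    s = _sigmoid(v - cfg.threshold)
    return s * (1.0 - s) * cfg.temp


def spiking_activation(
    v: Tensor, cfg: SpikeActivationConfig = SpikeActivationConfig()
) -> Tensor:
    """Autodiff spiking activation (straight-through with surrogate backward).

    Forward equals :func:`spike_forward`; the backward pass multiplies
    incoming gradients elementwise by :func:`surrogate_gradient`.
    """
    if not isinstance(v, Tensor):
        v = Tensor(np.asarray(v, dtype=float))
    data = v.data
    if not np.all(np.isfinite(data)):
        raise ValueError("membrane potential contains non-finite values")
    out_data = (data >= cfg.threshold).astype(data.dtype)

    def backward(g):
        s = _sigmoid(data - cfg.threshold)
        return (g * (s * (1.0 - s) * cfg.temp).astype(data.dtype, copy=False),)

    return Tensor._from_op(out_data, (v,), backward)
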