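"""Scaled dot-product attention, multi-head attention, and its spiking variant.

Spiking multi-head attention (SMHA) is ordinary multi-head scaled dot-product
attention whose output is passed through the hard-threshold spiking unit, so
the attended representation becomes a binary, event-like code:

    SMHA(Q, K, V) = S(MultiHead(Q, K, V))

where ``S`` is the spiking activation of :mod:`spikeformer.spiking`.  The
spiking unit is applied after the output projection.  No masking is used:
every task here is whole-segment classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .nn import Linear, Module
from .spiking import SpikeActivationConfig, spiking_activation

__all__ = [
    "AttentionConfig",
    "scaled_dot_attention",
    "MultiHeadAttention",
    "SpikingMultiHeadAttention",
]


@dataclass(frozen=True)
class AttentionConfig:
    d_model: int = 64
    n_heads: int = 4
    dropout_rate: float = 0.0

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


def scaled_dot_attention(q, k, v):
    """softmax(Q K^T / sqrt(d_k)) V.

    Accepts 2-D matrices ([L_q, d_k], [L_k, d_k], [L_k, d_v]) or arbitrarily
    batched stacks of them; softmax is taken over the key axis with the usual
    max-subtraction stabilisation.  Returns ``(output, weights)``.
    """
    q = q if isinstance(q, Tensor) else Tensor(np.asarray(q, dtype=float))
    k = k if isinstance(k, Tensor) else Tensor(np.asarray(k, dtype=float))
    v = v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=float))
    if q.shape[-1] != k.shape[-1]:
        raise ValueError("query and key widths differ")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError("key and value lengths differ")
    d_k = q.shape[-1]
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    weights = scores.softmax(axis=-1)
    return weights @ v, weights


class MultiHeadAttention(Module):
    """Standard multi-head attention with biased projections W_q, W_k, W_v, W_o."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d = cfg.d_model
        self.w_q = Linear(d, d, rng)
        self.w_k = Linear(d, d, rng)
        self.w_v = Linear(d, d, rng)
        self.w_o = Linear(d, d, rng)

    def forward(self, q_in: Tensor, k_in: Tensor, v_in: Tensor) -> Tensor:
        d, h = self.cfg.d_model, self.cfg.n_heads
        for name, x in (("query", q_in), ("key", k_in), ("value", v_in)):
            if x.shape[-1] != d:
                raise ValueError(f"{name} width {x.shape[-1]} != d_model {d}")
        squeeze = q_in.ndim == 2
        if squeeze:  # promote [L, d] to a batch of one
            q_in, k_in, v_in = (x.reshape(1, *x.shape) for x in (q_in, k_in, v_in))
        B, Lq, _ = q_in.shape
        Lk = k_in.shape[1]
        dk = d // h

        def split(x, L):
            return x.reshape(B, L, h, dk).transpose(0, 2, 1, 3)  # (B, h, L, dk)

        q = split(self.w_q(q_in), Lq)
        k = split(self.w_k(k_in), Lk)
        v = split(self.w_v(v_in), Lk)
        ctx, _ = scaled_dot_attention(q, k, v)  # (B, h, Lq, dk)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, Lq, d)
        out = self.w_o(ctx)
        return out.reshape(Lq, d) if squeeze else out


class SpikingMultiHeadAttention(Module):
    """Multi-head attention followed by the spiking unit; output is in {0, 1}."""

    def __init__(
        self,
        attn_cfg: AttentionConfig,
        spike_cfg: SpikeActivationConfig,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.mha = MultiHeadAttention(attn_cfg, rng)
        self.spike_cfg = spike_cfg

    def forward(self, q_in: Tensor, k_in: Tensor, v_in: Tensor) -> Tensor:
        return spiking_activation(self.mha(q_in, k_in, v_in), self.spike_cfg)
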