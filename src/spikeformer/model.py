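"""The hybrid spiking/Transformer classifier for physiological time series.

Architecture (front to back):

1. A three-layer 1-D CNN (filters 32, 64, 64; kernel 17; max-pool 2 after
   each stage) extracts local temporal features and shrinks the sequence by
   a factor of 8.  Its 64-wide output feeds the attention stack directly.
2. Fixed sinusoidal positional encoding is added (zero parameters).
3. A Transformer encoder block whose self-attention is *spiking* multi-head
   attention (SMHA) and whose feed-forward network carries the spiking
   activation between its two linear maps (pre-norm residual blocks).
4. A decoder block: spiking self-attention on the same feature sequence,
   standard multi-head cross-attention over the encoder output, spiking FFN.
   The decoder is non-autoregressive — classification has no target
   sequence, so it consumes the CNN features and attends to the encoder.
5. Mean-pooling over the sequence and a dense head: a single sigmoid unit
   for binary tasks, or a softmax row for multi-class.

With the default widths (d_model 64, 4 heads, FFN 128, one encoder + one
decoder block) and two input channels, the model has exactly 189,473
trainable parameters.

Ablation variants built from the same config:

- ``snn_only``   — attention sublayers removed; spiking CNN + spiking FFN
  stack only.
- ``transformer_only`` — identical wiring, spiking activations replaced by
  ReLU (a conventional Transformer).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .autograd import Tensor, no_grad
from .attention import AttentionConfig, MultiHeadAttention, SpikingMultiHeadAttention
from .nn import DTYPE, Conv1d, LayerNorm, Linear, Module
from .spiking import SpikeActivationConfig, spiking_activation

__all__ = [
    "ModelConfig",
    "positional_encoding",
    "CNNFrontend",
    "EncoderBlock",
    "DecoderBlock",
    "SpikingTransformerClassifier",
    "build_model",
]

VARIANTS = ("spiking_transformer", "snn_only", "transformer_only")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the classifier.

    ``in_channels`` is task dependent: 2 for the RR-interval/R-amplitude
    feature segments, 1 for raw ECG windows, 22 for EEG epochs.
    ``n_classes=1`` selects a sigmoid head (binary), otherwise softmax.
    """

    conv_filters: tuple[int, int, int] = (32, 64, 64)
    conv_kernel: int = 17
    pool_size: int = 2
    in_channels: int = 2
    d_model: int = 64
    n_heads: int = 4
    ffn_width: int = 128
    n_encoder_blocks: int = 1
    n_decoder_blocks: int = 1
    dropout_rate: float = 0.1
    n_classes: int = 1
    cnn_activation: str = "spike"  # "spike" | "relu"
    pre_norm: bool = True
    spike: SpikeActivationConfig = field(default_factory=SpikeActivationConfig)

    def __post_init__(self):
        if self.conv_filters[-1] != self.d_model:
            raise ValueError("last conv filter count must equal d_model")
        if min(self.n_encoder_blocks, self.n_decoder_blocks) < 1:
            raise ValueError("encoder/decoder depths must be >= 1")
        if self.cnn_activation not in ("spike", "relu"):
            raise ValueError("cnn_activation must be 'spike' or 'relu'")

    @property
    def min_input_length(self) -> int:
        return 8 * self.conv_kernel

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_filters"] = list(self.conv_filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["conv_filters"] = tuple(d["conv_filters"])
        if isinstance(d.get("spike"), dict):
            d["spike"] = SpikeActivationConfig(**d["spike"])
        return cls(**d)


def positional_encoding(length: int, d_model: int) -> np.ndarray:
    """Fixed sinusoidal positional encoding, shape (length, d_model).

    Even columns carry ``sin(pos / 10000^(2i/d))``, odd columns the matching
    cosine; values lie in [-1, 1] and the encoding has no parameters.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    pos = np.arange(length, dtype=np.float64)[:, None]
    i = np.arange(0, d_model, 2, dtype=np.float64)
    angle = pos / np.power(10000.0, i / d_model)
    pe = np.zeros((length, d_model), dtype=np.float64)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle[:, : d_model // 2])
    return pe


class CNNFrontend(Module):
    """Three stages of (same-padded conv, nonlinearity, max-pool)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        chans = (cfg.in_channels, *cfg.conv_filters)
        self.convs = [
            Conv1d(chans[i], chans[i + 1], cfg.conv_kernel, rng) for i in range(3)
        ]
        self.cfg = cfg

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] < self.cfg.min_input_length:
            raise ValueError(
                f"input length {x.shape[-1]} < minimum {self.cfg.min_input_length}"
            )
        for conv in self.convs:
            x = conv(x)
            if self.cfg.cnn_activation == "spike":
                x = spiking_activation(x, self.cfg.spike)
            else:
                x = x.relu()
            x = x.maxpool1d(self.cfg.pool_size)
        return x  # (B, d_model, L // 8)


class FeedForward(Module):
    """d_model -> ffn_width -> d_model with the spiking (or ReLU) activation between."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, spiking: bool):
        super().__init__()
        self.lin1 = Linear(cfg.d_model, cfg.ffn_width, rng)
        self.lin2 = Linear(cfg.ffn_width, cfg.d_model, rng)
        self.spike_cfg = cfg.spike
        self.spiking = spiking

    def forward(self, x: Tensor) -> Tensor:
        h = self.lin1(x)
        h = spiking_activation(h, self.spike_cfg) if self.spiking else h.relu()
        return self.lin2(h)


class _Block(Module):
    """Shared residual/dropout plumbing."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        self._drop_rng: np.random.Generator | None = None

    def _dropout(self, x: Tensor) -> Tensor:
        if self.training and self.cfg.dropout_rate > 0 and self._drop_rng is not None:
            return x.dropout(self.cfg.dropout_rate, self._drop_rng)
        return x

    def _residual(self, x: Tensor, sublayer, norm: LayerNorm) -> Tensor:
        if self.cfg.pre_norm:
            return x + self._dropout(sublayer(norm(x)))
        return norm(x + self._dropout(sublayer(x)))


class EncoderBlock(_Block):
    """Pre-norm: LN -> SMHA -> residual; LN -> spiking FFN -> residual."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, spiking: bool = True):
        super().__init__(cfg)
        attn_cfg = AttentionConfig(cfg.d_model, cfg.n_heads, cfg.dropout_rate)
        if spiking:
            self.attn = SpikingMultiHeadAttention(attn_cfg, cfg.spike, rng)
        else:
            self.attn = MultiHeadAttention(attn_cfg, rng)
        self.ffn = FeedForward(cfg, rng, spiking)
        self.norm1 = LayerNorm(cfg.d_model)
        self.norm2 = LayerNorm(cfg.d_model)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.cfg.d_model:
            raise ValueError(f"feature width {x.shape[-1]} != d_model {self.cfg.d_model}")
        x = self._residual(x, lambda y: self.attn(y, y, y), self.norm1)
        x = self._residual(x, self.ffn, self.norm2)
        return x


class DecoderBlock(_Block):
    """Spiking self-attention, standard cross-attention over the encoder memory, spiking FFN."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, spiking: bool = True):
        super().__init__(cfg)
        attn_cfg = AttentionConfig(cfg.d_model, cfg.n_heads, cfg.dropout_rate)
        if spiking:
            self.self_attn = SpikingMultiHeadAttention(attn_cfg, cfg.spike, rng)
        else:
            self.self_attn = MultiHeadAttention(attn_cfg, rng)
        self.cross_attn = MultiHeadAttention(attn_cfg, rng)
        self.ffn = FeedForward(cfg, rng, spiking)
        self.norm1 = LayerNorm(cfg.d_model)
        self.norm2 = LayerNorm(cfg.d_model)
        self.norm3 = LayerNorm(cfg.d_model)

    def forward(self, x: Tensor, memory: Tensor) -> Tensor:
        if x.shape[-1] != self.cfg.d_model or memory.shape[-1] != self.cfg.d_model:
            raise ValueError("feature width != d_model")
        x = self._residual(x, lambda y: self.self_attn(y, y, y), self.norm1)
        x = self._residual(x, lambda y: self.cross_attn(y, memory, memory), self.norm2)
        x = self._residual(x, self.ffn, self.norm3)
        return x


class FFNOnlyBlock(_Block):
    """Attention-free block used by the SNN-only ablation."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__(cfg)
        self.ffn = FeedForward(cfg, rng, spiking=True)
        self.norm = LayerNorm(cfg.d_model)

    def forward(self, x: Tensor, memory: Tensor | None = None) -> Tensor:
        return self._residual(x, self.ffn, self.norm)


class SpikingTransformerClassifier(Module):
    """CNN front-end + spiking Transformer encoder/decoder + pooled dense head."""

    def __init__(
        self,
        cfg: ModelConfig,
        seed: int = 0,
        variant: str = "spiking_transformer",
    ):
        super().__init__()
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        self.cfg = cfg
        self.variant = variant
        rng = np.random.default_rng(seed)
        self._drop_rng = np.random.default_rng(rng.integers(2**31))
        # the SNN-only ablation always uses spiking CNN activations; the
        # Transformer-only ablation always uses ReLU
        if variant == "transformer_only":
            cfg = replace(cfg, cnn_activation="relu")
            self.cfg = cfg
        spiking = variant != "transformer_only"
        self.cnn = CNNFrontend(cfg, rng)
        if variant == "snn_only":
            self.encoder = [FFNOnlyBlock(cfg, rng) for _ in range(cfg.n_encoder_blocks)]
            self.decoder = [FFNOnlyBlock(cfg, rng) for _ in range(cfg.n_decoder_blocks)]
        else:
            self.encoder = [
                EncoderBlock(cfg, rng, spiking) for _ in range(cfg.n_encoder_blocks)
            ]
            self.decoder = [
                DecoderBlock(cfg, rng, spiking) for _ in range(cfg.n_decoder_blocks)
            ]
        for blk in (*self.encoder, *self.decoder):
            blk._drop_rng = self._drop_rng
        self.head = Linear(cfg.d_model, cfg.n_classes, rng)
        self._pe_cache: dict[int, np.ndarray] = {}

    # -- forward --------------------------------------------------------------

    def _pos_enc(self, length: int) -> np.ndarray:
        if length not in self._pe_cache:
            self._pe_cache[length] = positional_encoding(length, self.cfg.d_model).astype(
                DTYPE
            )
        return self._pe_cache[length]

    def forward_logits(self, batch) -> Tensor:
        x = batch if isinstance(batch, Tensor) else Tensor(
            np.asarray(batch, dtype=DTYPE)
        )
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} channels, got {x.shape[1]}"
            )
        feats = self.cnn(x).swapaxes(1, 2)  # (B, L', d_model)
        feats = feats + Tensor(self._pos_enc(feats.shape[1]))
        mem = feats
        for blk in self.encoder:
            mem = blk(mem)
        y = feats
        for blk in self.decoder:
            y = blk(y, mem)
        pooled = y.mean(axis=1)  # (B, d_model)
        logits = self.head(pooled)
        if not np.all(np.isfinite(logits.data)):
            raise RuntimeError("non-finite activations in forward pass")
        return logits

    def forward(self, batch) -> Tensor:
        """Class probabilities: sigmoid column (binary) or softmax rows."""
        logits = self.forward_logits(batch)
        if self.cfg.n_classes == 1:
            return logits.sigmoid()
        return logits.softmax(axis=-1)

    def predict_proba(self, batch, batch_size: int = 64) -> np.ndarray:
        """Inference-mode probabilities as a plain array."""
        was_training = self.training
        self.eval()
        outs = []
        x = np.asarray(batch, dtype=DTYPE)
        with no_grad():
            for i in range(0, len(x), batch_size):
                outs.append(self.forward(x[i : i + batch_size]).data)
        if was_training:
            self.train()
        return np.concatenate(outs, axis=0)

    # -- persistence ----------------------------------------------------------

    def save(self, path):
        """Write weights (.npz) plus a plain-text config sidecar (.yaml)."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        sidecar = {
            "model": self.cfg.to_dict(),
            "variant": self.variant,
            "n_parameters": int(self.n_parameters()),
        }
        sidecar["model"]["spike"] = asdict(self.cfg.spike)
        path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))

    @classmethod
    def load(cls, path) -> "SpikingTransformerClassifier":
        path = Path(path)
        sidecar = yaml.safe_load(path.with_suffix(".yaml").read_text())
        cfg = ModelConfig.from_dict(sidecar["model"])
        model = cls(cfg, variant=sidecar["variant"])
        with np.load(path.with_suffix(".npz")) as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
        return model


def build_model(
    cfg: ModelConfig, seed: int = 0, variant: str = "spiking_transformer"
) -> SpikingTransformerClassifier:
    return SpikingTransformerClassifier(cfg, seed=seed, variant=variant)
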