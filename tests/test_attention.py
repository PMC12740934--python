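"""Attention: scaled dot-product oracle, multi-head contract, spiking variant."""

import numpy as np
import pytest

from spikeformer.attention import (
    AttentionConfig,
    MultiHeadAttention,
    SpikingMultiHeadAttention,
    scaled_dot_attention,
)
from spikeformer.autograd import Tensor
from spikeformer.spiking import SpikeActivationConfig, spike_forward


def brute_force_attention(q, k, v):
    """Independent double-loop reference for softmax(QK^T/sqrt(d_k))V."""
    Lq, dk = q.shape
    Lk, dv = k.shape[0], v.shape[1]
    out = np.zeros((Lq, dv))
    weights = np.zeros((Lq, Lk))
    for i in range(Lq):
        logits = np.array([np.dot(q[i], k[j]) / np.sqrt(dk) for j in range(Lk)])
        e = np.exp(logits - logits.max())
        w = e / e.sum()
        weights[i] = w
        for j in range(Lk):
            out[i] += w[j] * v[j]
    return out, weights


class TestScaledDotAttention:
    def test_identical_keys_give_uniform_weights(self, rng):
        q = rng.standard_normal((3, 4))
        k = np.tile(rng.standard_normal(4), (5, 1))
        v = rng.standard_normal((5, 2))
        out, w = scaled_dot_attention(q, k, v)
        np.testing.assert_allclose(w.data, np.full((3, 5), 0.2), atol=1e-12)
        np.testing.assert_allclose(out.data, np.tile(v.mean(0), (3, 1)), atol=1e-12)

    def test_single_key_gets_full_weight(self, rng):
        q = rng.standard_normal((3, 4))
        k = rng.standard_normal((1, 4))
        v = rng.standard_normal((1, 6))
        out, w = scaled_dot_attention(q, k, v)
        np.testing.assert_array_equal(w.data, np.ones((3, 1)))
        np.testing.assert_allclose(out.data, np.tile(v[0], (3, 1)), atol=1e-12)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            Lq, Lk, dk, dv = rng.integers(1, 6, size=4)
            q = rng.standard_normal((Lq, dk))
            k = rng.standard_normal((Lk, dk))
            v = rng.standard_normal((Lk, dv))
            out, w = scaled_dot_attention(q, k, v)
            ref_out, ref_w = brute_force_attention(q, k, v)
            np.testing.assert_allclose(out.data, ref_out, atol=1e-6)
            np.testing.assert_allclose(w.data, ref_w, atol=1e-6)

    def test_rows_sum_to_one(self, rng):
        q, k, v = (rng.standard_normal(s) for s in ((7, 3), (9, 3), (9, 4)))
        _, w = scaled_dot_attention(q, k, v)
        np.testing.assert_allclose(w.data.sum(axis=-1), np.ones(7), atol=1e-6)

    def test_shift_invariance_of_logits(self, rng):
        # adding a constant to every logit row leaves the weights unchanged;
        # realised by shifting all keys by a common vector has no such
        # guarantee, so shift the scores directly via a rank-one key change
        q = rng.standard_normal((4, 3))
        k = rng.standard_normal((6, 3))
        v = rng.standard_normal((6, 5))
        out1, w1 = scaled_dot_attention(q, k, v)
        # q -> q + c * ones shifts each score row by a row-constant only if
        # keys share a common component; instead verify via direct logits
        logits = q @ k.T / np.sqrt(3)
        shifted = logits + 17.3
        sm = lambda z: np.exp(z - z.max(-1, keepdims=True)) / np.exp(
            z - z.max(-1, keepdims=True)
        ).sum(-1, keepdims=True)
        np.testing.assert_allclose(sm(logits), sm(shifted), atol=1e-12)
        np.testing.assert_allclose(w1.data, sm(logits), atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            scaled_dot_attention(
                rng.standard_normal((3, 4)),
                rng.standard_normal((5, 3)),
                rng.standard_normal((5, 2)),
            )
        with pytest.raises(ValueError):
            scaled_dot_attention(
                rng.standard_normal((3, 4)),
                rng.standard_normal((5, 4)),
                rng.standard_normal((4, 2)),
            )


class TestMultiHeadAttention:
    def test_identity_projections_reduce_to_scaled_dot(self, rng):
        cfg = AttentionConfig(d_model=4, n_heads=1)
        mha = MultiHeadAttention(cfg, rng)
        for lin in (mha.w_q, mha.w_k, mha.w_v, mha.w_o):
            lin.weight.data = np.eye(4, dtype=np.float32)
            lin.bias.data = np.zeros(4, dtype=np.float32)
        q = rng.standard_normal((3, 4)).astype(np.float32)
        k = rng.standard_normal((5, 4)).astype(np.float32)
        v = rng.standard_normal((5, 4)).astype(np.float32)
        out = mha(Tensor(q), Tensor(k), Tensor(v))
        ref, _ = scaled_dot_attention(q, k, v)
        np.testing.assert_allclose(out.data, ref.data, atol=1e-5)

    def test_permutation_equivariance_without_positions(self, rng):
        cfg = AttentionConfig(d_model=8, n_heads=2)
        mha = MultiHeadAttention(cfg, rng)
        x = rng.standard_normal((6, 8)).astype(np.float32)
        perm = rng.permutation(6)
        out = mha(Tensor(x), Tensor(x), Tensor(x)).data
        out_perm = mha(Tensor(x[perm]), Tensor(x[perm]), Tensor(x[perm])).data
        np.testing.assert_allclose(out[perm], out_perm, atol=1e-5)

    def test_parameter_count(self, rng):
        cfg = AttentionConfig(d_model=64, n_heads=4)
        mha = MultiHeadAttention(cfg, rng)
        assert mha.n_parameters() == 4 * (64 * 64 + 64) == 16640

    def test_width_mismatch_rejected(self, rng):
        mha = MultiHeadAttention(AttentionConfig(d_model=8, n_heads=2), rng)
        bad = Tensor(rng.standard_normal((3, 7)))
        with pytest.raises(ValueError):
            mha(bad, bad, bad)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            AttentionConfig(d_model=64, n_heads=5)


class TestSpikingMultiHeadAttention:
    def test_output_is_binary(self, rng, spike_cfg):
        smha = SpikingMultiHeadAttention(
            AttentionConfig(d_model=8, n_heads=2), spike_cfg, rng
        )
        x = Tensor(rng.standard_normal((4, 8)).astype(np.float32))
        out = smha(x, x, x)
        assert set(np.unique(out.data)) <= {0.0, 1.0}

    def test_saturated_input_fires_everywhere(self, rng, spike_cfg):
        smha = SpikingMultiHeadAttention(
            AttentionConfig(d_model=4, n_heads=1), spike_cfg, rng
        )
        # force the attention output far above threshold via the output bias
        smha.mha.w_o.bias.data = np.full(4, 100.0, dtype=np.float32)
        x = Tensor(rng.standard_normal((3, 4)).astype(np.float32))
        np.testing.assert_array_equal(smha(x, x, x).data, np.ones((3, 4)))

    def test_composition_equals_spike_of_mha(self, rng, spike_cfg):
        smha = SpikingMultiHeadAttention(
            AttentionConfig(d_model=8, n_heads=2), spike_cfg, rng
        )
        x = Tensor(np.random.default_rng(0).standard_normal((5, 8)).astype(np.float32))
        mha_out = smha.mha(x, x, x).data
        np.testing.assert_array_equal(
            smha(x, x, x).data, spike_forward(mha_out, spike_cfg)
        )

    def test_sparsity_nonincreasing_in_threshold(self, rng):
        x = Tensor(rng.standard_normal((6, 8)).astype(np.float32))
        rng0 = np.random.default_rng(0)
        smha = SpikingMultiHeadAttention(
            AttentionConfig(d_model=8, n_heads=2), SpikeActivationConfig(), rng0
        )
        mha_out = smha.mha(x, x, x).data
        fracs = [
            spike_forward(mha_out, SpikeActivationConfig(threshold=th)).mean()
            for th in np.linspace(-2, 2, 9)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
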