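"""Model assembly: parameter budget, shapes, positional encoding, variants."""

import numpy as np
import pytest

from spikeformer.autograd import Tensor
from spikeformer.model import (
    CNNFrontend,
    DecoderBlock,
    EncoderBlock,
    ModelConfig,
    SpikingTransformerClassifier,
    positional_encoding,
)


@pytest.fixture(scope="module")
def ref_model():
    return SpikingTransformerClassifier(ModelConfig(), seed=0)


def count(module):
    return sum(p.data.size for p in module.parameters())


class TestParameterBudget:
    def test_cnn_per_layer_counts(self, ref_model):
        # (in * out * k) + out per layer, kernel 17, channels 2->32->64->64
        expected = [2 * 32 * 17 + 32, 32 * 64 * 17 + 64, 64 * 64 * 17 + 64]
        actual = [count(c) for c in ref_model.cnn.convs]
        assert actual == expected == [1120, 34880, 69696]
        assert count(ref_model.cnn) == 105696

    def test_encoder_block_count(self, ref_model):
        # 16,640 attention + 16,576 FFN + 2 * 128 layer norms
        assert count(ref_model.encoder[0]) == 16640 + 16576 + 256 == 33472

    def test_decoder_block_count(self, ref_model):
        # two attention modules + FFN + 3 layer norms
        assert count(ref_model.decoder[0]) == 2 * 16640 + 16576 + 384 == 50240

    def test_total_reference_budget(self, ref_model):
        tally = (
            count(ref_model.cnn)
            + count(ref_model.encoder[0])
            + count(ref_model.decoder[0])
            + count(ref_model.head)
        )
        assert tally == ref_model.n_parameters() == 189473

    def test_count_invariant_to_input_length(self, ref_model):
        n0 = ref_model.n_parameters()
        for L in (300, 900, 1500):
            x = np.zeros((1, 2, L), dtype=np.float32)
            ref_model.predict_proba(x)
            assert ref_model.n_parameters() == n0


class TestPositionalEncoding:
    def test_position_zero_is_sin0_cos1(self):
        pe = positional_encoding(10, 64)
        np.testing.assert_array_equal(pe[0, 0::2], np.zeros(32))
        np.testing.assert_array_equal(pe[0, 1::2], np.ones(32))

    def test_deterministic_and_bounded(self):
        a = positional_encoding(50, 64)
        b = positional_encoding(50, 64)
        np.testing.assert_array_equal(a, b)
        assert a.min() >= -1.0 and a.max() <= 1.0

    def test_matches_direct_formula(self):
        pe = positional_encoding(10, 64)
        for pos in range(10):
            for i in range(0, 64, 2):
                angle = pos / 10000 ** (i / 64)
                assert pe[pos, i] == pytest.approx(np.sin(angle), abs=1e-12)
                assert pe[pos, i + 1] == pytest.approx(np.cos(angle), abs=1e-12)


class TestCNNFrontend:
    def test_output_length_three_floor_halvings(self, ref_model):
        x = Tensor(np.zeros((2, 2, 900), dtype=np.float32))
        out = ref_model.cnn(x)
        assert out.shape == (2, 64, 112)  # 900 -> 450 -> 225 -> 112

    def test_short_input_rejected(self, ref_model):
        with pytest.raises(ValueError):
            ref_model.cnn(Tensor(np.zeros((1, 2, 100), dtype=np.float32)))

    def test_constant_zero_input_gives_bias_response(self, rng):
        cfg = ModelConfig(cnn_activation="relu", dropout_rate=0.0)
        cnn = CNNFrontend(cfg, rng)
        out1 = cnn(Tensor(np.zeros((1, 2, 200), dtype=np.float32))).data
        out2 = cnn(Tensor(np.zeros((1, 2, 200), dtype=np.float32))).data
        np.testing.assert_array_equal(out1, out2)
        # interior of each channel is constant (same-padding edge effects aside)
        interior = out1[0, :, 5:-5]
        assert np.allclose(interior, interior[:, :1])


class TestBlocks:
    def test_encoder_preserves_shape(self, rng):
        cfg = ModelConfig(dropout_rate=0.0)
        blk = EncoderBlock(cfg, rng)
        blk.eval()
        x = Tensor(rng.standard_normal((2, 10, 64)).astype(np.float32))
        assert blk(x).shape == (2, 10, 64)

    def test_deterministic_with_dropout_off(self, rng):
        cfg = ModelConfig(dropout_rate=0.0)
        blk = EncoderBlock(cfg, np.random.default_rng(3))
        blk.eval()
        x = Tensor(rng.standard_normal((1, 8, 64)).astype(np.float32))
        np.testing.assert_array_equal(blk(x).data, blk(x).data)

    def test_decoder_single_memory_row(self, rng):
        # L_k = 1: cross-attention weights are exactly 1, so its sublayer
        # output is the projected memory row for every query position
        cfg = ModelConfig(dropout_rate=0.0)
        blk = DecoderBlock(cfg, np.random.default_rng(4))
        blk.eval()
        mem = Tensor(rng.standard_normal((1, 1, 64)).astype(np.float32))
        x = Tensor(rng.standard_normal((1, 6, 64)).astype(np.float32))
        y = blk._residual(x, lambda q: blk.cross_attn(q, mem, mem), blk.norm2)
        contribution = (y.data - x.data)[0]
        np.testing.assert_allclose(
            contribution, np.tile(contribution[0], (6, 1)), atol=1e-5
        )

    def test_width_mismatch_rejected(self, rng):
        blk = EncoderBlock(ModelConfig(), rng)
        with pytest.raises(ValueError):
            blk(Tensor(np.zeros((1, 5, 32), dtype=np.float32)))


class TestForward:
    def test_binary_probabilities(self, ref_model, rng):
        x = rng.standard_normal((3, 2, 900)).astype(np.float32)
        p = ref_model.predict_proba(x)
        assert p.shape == (3, 1)
        assert np.all((p > 0) & (p < 1))

    def test_softmax_head_rows_sum_to_one(self, rng):
        cfg = ModelConfig(n_classes=4, dropout_rate=0.0)
        model = SpikingTransformerClassifier(cfg, seed=1)
        p = model.predict_proba(rng.standard_normal((3, 2, 300)).astype(np.float32))
        assert p.shape == (3, 4)
        np.testing.assert_allclose(p.sum(axis=-1), np.ones(3), atol=1e-6)

    def test_forward_deterministic_in_eval(self, ref_model, rng):
        x = rng.standard_normal((2, 2, 900)).astype(np.float32)
        np.testing.assert_array_equal(
            ref_model.predict_proba(x), ref_model.predict_proba(x)
        )

    def test_channel_mismatch_rejected(self, ref_model, rng):
        with pytest.raises(ValueError):
            ref_model.predict_proba(rng.standard_normal((1, 3, 900)))


class TestVariantsAndPersistence:
    @pytest.mark.parametrize("variant", ["snn_only", "transformer_only"])
    def test_ablation_variants_build_and_run(self, variant, rng):
        model = SpikingTransformerClassifier(ModelConfig(), seed=0, variant=variant)
        p = model.predict_proba(rng.standard_normal((2, 2, 300)).astype(np.float32))
        assert p.shape == (2, 1)
        if variant == "snn_only":
            assert model.n_parameters() < 189473  # attention removed

    def test_transformer_only_uses_relu_cnn(self):
        model = SpikingTransformerClassifier(
            ModelConfig(), seed=0, variant="transformer_only"
        )
        assert model.cfg.cnn_activation == "relu"

    def test_checkpoint_roundtrip(self, tmp_path, ref_model, rng):
        x = rng.standard_normal((2, 2, 900)).astype(np.float32)
        before = ref_model.predict_proba(x)
        ref_model.save(tmp_path / "ckpt")
        loaded = SpikingTransformerClassifier.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(loaded.predict_proba(x), before)


class TestPostNorm:
    def test_post_norm_block_builds_and_runs(self, rng):
        cfg = ModelConfig(dropout_rate=0.0, pre_norm=False)
        blk = EncoderBlock(cfg, np.random.default_rng(0))
        blk.eval()
        x = Tensor(rng.standard_normal((1, 6, 64)).astype(np.float32))
        out = blk(x)
        assert out.shape == (1, 6, 64)
        # post-norm output is layer-normalised: per-position mean ~ 0
        assert np.abs(out.data.mean(axis=-1)).max() < 1e-5
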