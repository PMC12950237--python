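"""Architecture contracts: exact sequence-length law (against an independent
floor-arithmetic oracle), transformer properties, fusion contracts, variant
nesting and checkpointing."""

import numpy as np
import pytest

from eegart import nn
from eegart.model import (
    FUSION_STRATEGIES,
    VARIANTS,
    LGNet,
    ModelConfig,
    TransformerConfig,
    WeightedFusion,
    build_model,
    fuse_total,
    load_checkpoint,
    save_checkpoint,
)
from eegart.nn import tensor as T
from eegart.tfr import stft_spectrogram


# -- independent floor-arithmetic oracle --------------------------------

def _o(l, k, s):
    return (l - k) // s + 1


def oracle_time_T(L):
    return _o(_o(_o(_o(L, 8, 4), 4, 2), 4, 2), 2, 1)


def oracle_tf_dims(bins, frames):
    h, w = bins, frames - 2          # conv (1,3)
    h, w = h - 1, w - 1              # pool (2,2) stride 1
    h = h - 2                        # conv (3,1)
    h, w = h - 1, w - 1              # pool (2,2) stride 1
    return h, w


@pytest.fixture(scope="module")
def full_model():
    return build_model(ModelConfig(num_classes=6, seed=0))


@pytest.fixture(scope="module")
def batch(full_model):
    rng = np.random.default_rng(0)
    x = rng.standard_normal((2, 1000)).astype(np.float32)
    return x, full_model.compute_spectrograms(x)


class TestShapeLaw:
    def test_reference_configuration_stage_by_stage(self, full_model, batch):
        """4 s at 250 Hz: T=59, T1=57, Hout*Wout=1464, T2=1200, T3=175,
        T4=4128, fused length 4303 — measured on live tensors."""
        m = full_model
        m.eval()
        x, spec = batch
        assert oracle_time_T(1000) == 59
        fa = m.time_conv(nn.Tensor(x[:, None, :]))
        assert fa.shape == (2, 59, 40)
        ftr = m.td_transformer(fa)
        assert ftr.shape == (2, 59, 40)
        fb = m.td_deep(ftr)
        assert fb.shape == (2, 59 - 2, 40)
        f_td = m.td_fusion([fa, ftr, fb])
        assert f_td.shape == (2, 175, 40)          # 2T + T1

        h_o, w_o = oracle_tf_dims(126, 16)
        assert (h_o, w_o, h_o * w_o) == (122, 12, 1464)
        g = m.tf_conv(nn.Tensor(spec))
        assert g.shape == (2, 40, 122, 12)
        fa2 = T.transpose(T.reshape(g, (2, 40, 1464)), (0, 2, 1))
        ftr2 = m.tfd_transformer(fa2)
        assert ftr2.shape == (2, 1464, 40)
        fb2 = m.tf_deep(ftr2, 122, 12)
        assert fb2.shape == (2, (122 - 2) * (12 - 2), 40)   # T2 = 1200
        f_tfd = m.tfd_fusion([fa2, ftr2, fb2])
        assert f_tfd.shape == (2, 2 * 1464 + 1200, 40)      # T4 = 4128
        fused = fuse_total(f_td, f_tfd)
        assert fused.shape == (2, 175 + 4128, 40)           # 4303
        logits = m.classifier(fused)
        assert logits.shape == (2, 6)

    def test_one_second_segment_time_branch(self):
        assert oracle_time_T(250) == 12
        m = build_model(ModelConfig(segment_seconds=1.0, variant="cnn", num_classes=6))
        out = m.time_conv(nn.Tensor(np.zeros((1, 1, 250), dtype=np.float32)))
        assert out.shape == (1, 12, 40)

    def test_too_short_input_raises_with_stage(self):
        m = build_model(ModelConfig(variant="cnn", num_classes=6))
        with pytest.raises(ValueError):
            m.time_conv(nn.Tensor(np.zeros((1, 1, 4), dtype=np.float32)))


class TestTransformer:
    def _encoder(self, pos="none", seed=0):
        return nn.TransformerEncoder(2, 40, 5, 160, np.random.default_rng(seed),
                                     positional_encoding=pos)

    def test_shape_preserved(self, rng):
        enc = self._encoder()
        x = nn.Tensor(rng.standard_normal((3, 17, 40)).astype(np.float32))
        assert enc(x).shape == (3, 17, 40)

    def test_wrong_width_rejected(self, rng):
        enc = self._encoder()
        with pytest.raises(ValueError):
            enc(nn.Tensor(rng.standard_normal((1, 5, 39)).astype(np.float32)))

    def test_attention_rows_sum_to_one(self, rng):
        enc = self._encoder()
        x = nn.Tensor(rng.standard_normal((2, 9, 40)).astype(np.float32))
        probs = enc.layers[0].attention_probs(x)
        assert probs.shape == (2, 5, 9, 9)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_permutation_equivariance_without_positional_encoding(self):
        rng = np.random.default_rng(7)
        enc = self._encoder()
        x = rng.standard_normal((1, 8, 40)).astype(np.float32)
        perm = rng.permutation(8)
        out_then_perm = enc(nn.Tensor(x)).data[:, perm]
        perm_then_out = enc(nn.Tensor(x[:, perm])).data
        np.testing.assert_allclose(out_then_perm, perm_then_out, atol=1e-5)

    def test_sinusoidal_encoding_breaks_equivariance(self):
        rng = np.random.default_rng(8)
        enc = self._encoder(pos="sinusoidal")
        x = rng.standard_normal((1, 8, 40)).astype(np.float32)
        perm = np.roll(np.arange(8), 3)
        a = enc(nn.Tensor(x)).data[:, perm]
        b = enc(nn.Tensor(x[:, perm])).data
        assert not np.allclose(a, b, atol=1e-4)

    def test_heads_must_divide_width(self):
        with pytest.raises(ValueError):
            TransformerConfig(num_heads=7, d_model=40)


class TestFusion:
    def test_kernel1_fusion_preserves_concatenated_length(self, rng):
        from eegart.model import DomainFusion

        fuse = DomainFusion(40, np.random.default_rng(0))
        parts = [nn.Tensor(rng.standard_normal((2, n, 40)).astype(np.float32))
                 for n in (59, 59, 57)]
        assert fuse(parts).shape == (2, 175, 40)

    def test_channel_mismatch_rejected(self, rng):
        from eegart.model import DomainFusion

        fuse = DomainFusion(40, np.random.default_rng(0))
        with pytest.raises(ValueError):
            fuse([nn.Tensor(np.zeros((1, 4, 40), dtype=np.float32)),
                  nn.Tensor(np.zeros((1, 4, 32), dtype=np.float32))])

    def test_total_fusion_additivity_and_order(self, rng):
        a = nn.Tensor(rng.standard_normal((2, 175, 40)).astype(np.float32))
        b = nn.Tensor(rng.standard_normal((2, 4128, 40)).astype(np.float32))
        out = fuse_total(a, b)
        assert out.shape == (2, 4303, 40)
        np.testing.assert_array_equal(out.data[:, :175], a.data)

    def test_empty_operand_rejected(self):
        a = nn.Tensor(np.zeros((1, 5, 40), dtype=np.float32))
        b = nn.Tensor(np.zeros((1, 0, 40), dtype=np.float32))
        with pytest.raises(ValueError):
            fuse_total(a, b)

    def test_weighted_fusion_weights_sum_to_one(self, rng):
        wf = WeightedFusion(40, np.random.default_rng(1), mode="weighted")
        parts = [nn.Tensor(rng.standard_normal((3, n, 40)).astype(np.float32))
                 for n in (10, 20, 30)]
        pooled = [T.mean(p, axis=1) for p in parts]
        w = wf.weights(pooled).data
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)
        assert wf(parts).shape == (3, 1, 40)

    def test_weighted_fusion_convexity_on_identical_inputs(self, rng):
        """Identical feature groups: the weighted sum is the common pooled
        vector regardless of the learned weights."""
        wf = WeightedFusion(40, np.random.default_rng(2), mode="weighted")
        p = rng.standard_normal((2, 6, 40)).astype(np.float32)
        out = wf([nn.Tensor(p.copy()) for _ in range(3)])
        np.testing.assert_allclose(out.data[:, 0, :], p.mean(axis=1), atol=1e-5)

    def test_weighted_cnn_keeps_three_tokens(self, rng):
        wf = WeightedFusion(40, np.random.default_rng(3), mode="weighted_cnn")
        parts = [nn.Tensor(rng.standard_normal((2, n, 40)).astype(np.float32))
                 for n in (5, 9, 13)]
        assert wf(parts).shape == (2, 3, 40)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            WeightedFusion(40, np.random.default_rng(0), mode="maximal")


class TestClassifierHead:
    def test_zero_input_at_init_gives_uniform_probs(self, full_model, batch):
        m = build_model(ModelConfig(num_classes=6, seed=3))
        m.eval()
        probs = m.predict_proba(np.zeros((2, 1000), dtype=np.float32))
        np.testing.assert_allclose(probs.p, 1.0 / 6.0, atol=1e-6)

    def test_softmax_shift_invariance_and_normalization(self, rng):
        z = rng.standard_normal((5, 6))
        p1 = T.stable_softmax(z)
        p2 = T.stable_softmax(z + 123.4)
        np.testing.assert_allclose(p1, p2, atol=1e-9)
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-6)

    def test_probability_rows_sum_to_one(self, full_model, batch):
        x, spec = batch
        probs = full_model.predict_proba(x, spec)
        np.testing.assert_allclose(probs.p.sum(axis=1), 1.0, atol=1e-6)

    def test_width_mismatch_rejected(self, full_model):
        with pytest.raises(ValueError):
            full_model.classifier(nn.Tensor(np.zeros((1, 7, 40), dtype=np.float32)))


class TestVariantsAndParameters:
    def test_cnn_variant_has_no_attention_parameters(self):
        m = build_model(ModelConfig(variant="cnn", num_classes=6))
        assert not any("w_qkv" in k for k in m.named_parameters())

    def test_parameter_count_in_expected_range(self, full_model):
        assert 4e6 <= full_model.num_parameters() <= 4e7

    def test_parameter_count_grows_with_segment_length(self):
        counts = [build_model(ModelConfig(segment_seconds=s, num_classes=6)).num_parameters()
                  for s in (2.0, 4.0, 5.0)]
        assert counts[0] < counts[1] < counts[2]

    def test_variant_parameter_sets_strictly_nested(self):
        names, totals = {}, {}
        for v in VARIANTS:
            m = build_model(ModelConfig(variant=v, num_classes=6))
            names[v] = set(m.named_parameters())
            totals[v] = m.num_parameters()
        for a, b in zip(VARIANTS, VARIANTS[1:]):
            assert names[a] <= names[b], f"{a} not nested in {b}"
            assert totals[a] < totals[b], f"params did not grow {a} -> {b}"

    @pytest.mark.parametrize("strategy", FUSION_STRATEGIES)
    def test_every_fusion_strategy_forwards(self, strategy, batch):
        x, spec = batch
        m = build_model(ModelConfig(num_classes=6, fusion_strategy=strategy, seed=1))
        m.eval()
        probs = m.predict_proba(x, spec)
        np.testing.assert_allclose(probs.p.sum(axis=1), 1.0, atol=1e-6)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(num_classes=1)
        with pytest.raises(ValueError):
            ModelConfig(variant="resnet")
        with pytest.raises(ValueError):
            ModelConfig(fusion_strategy="sum")

    def test_config_round_trip(self):
        cfg = ModelConfig(variant="cnn_tf", num_classes=7, dropout=0.25)
        again = ModelConfig.from_dict(cfg.to_dict())
        assert again == cfg


class TestDeepConv2dContract:
    def test_flatten_unflatten_identity(self, rng):
        g = rng.standard_normal((2, 40, 5, 4)).astype(np.float32)
        seq = T.transpose(T.reshape(nn.Tensor(g), (2, 40, 20)), (0, 2, 1))
        back = T.reshape(T.transpose(seq, (0, 2, 1)), (2, 40, 5, 4))
        np.testing.assert_array_equal(back.data, g)

    def test_mismatched_sequence_length_rejected(self, full_model):
        bad = nn.Tensor(np.zeros((1, 100, 40), dtype=np.float32))
        with pytest.raises(ValueError):
            full_model.tf_deep(bad, 122, 12)


def test_checkpoint_round_trip(tmp_path, batch):
    x, spec = batch
    cfg = ModelConfig(variant="cnn_tf", num_classes=6, seed=9)
    m = build_model(cfg)
    m.eval()
    before = m.predict_proba(x).p
    path = tmp_path / "ckpt.npz"
    save_checkpoint(m, path, class_vocabulary=("A", "B", "C", "D", "E", "F"),
                    extra={"note": "test"})
    m2, vocab, extra = load_checkpoint(path)
    m2.eval()
    np.testing.assert_array_equal(m2.predict_proba(x).p, before)
    assert vocab == ("A", "B", "C", "D", "E", "F")
    assert extra["note"] == "test"
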