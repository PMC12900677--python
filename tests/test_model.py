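"""Architecture oracles: dense-attention equivalence, residual identities,
parameter accounting and checkpointing."""

import numpy as np
import pytest

from vesselsr.errors import ConfigError
from vesselsr.imaging import resize_bicubic
from vesselsr.model import (DualPathSRNet, ModelConfig, WindowAttention,
                            count_parameters, load_checkpoint,
                            save_checkpoint)
from vesselsr.nn import Tensor


TINY = ModelConfig.tiny()


def dense_attention_oracle(x: np.ndarray, wa: WindowAttention) -> np.ndarray:
    """Brute-force global softmax attention over all positions of an
    (H, W, C) map, written independently of the windowed implementation."""
    h, w, c = x.shape
    heads = wa.heads
    dk = c // heads
    tokens = x.reshape(h * w, c)
    qkv = tokens @ wa.qkv.weight.data + wa.qkv.bias.data
    q, k, v = qkv[:, :c], qkv[:, c:2 * c], qkv[:, 2 * c:]
    bias = wa.bias_table.data[wa._bias_idx].reshape(h * w, h * w, heads)
    out = np.zeros((h * w, c))
    for hd in range(heads):
        qh = q[:, hd * dk:(hd + 1) * dk]
        kh = k[:, hd * dk:(hd + 1) * dk]
        vh = v[:, hd * dk:(hd + 1) * dk]
        logits = qh @ kh.T / np.sqrt(dk) + bias[:, :, hd]
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        out[:, hd * dk:(hd + 1) * dk] = a @ vh
    out = out @ wa.proj.weight.data + wa.proj.bias.data
    return out.reshape(h, w, c)


class TestWindowAttention:
    def test_equals_dense_oracle_when_window_covers_map(self):
        rng = np.random.default_rng(0)
        d, heads, ws = 16, 2, 8
        wa = WindowAttention(d, ws, heads, rng)
        x = rng.normal(size=(1, ws, ws, d))
        got = wa(Tensor(x), shift=0, mask=None).data[0]
        want = dense_attention_oracle(x[0], wa)
        assert np.abs(got - want).max() < 1e-5

    def test_zero_value_projection_kills_output(self):
        rng = np.random.default_rng(1)
        d, heads, ws = 8, 2, 4
        wa = WindowAttention(d, ws, heads, rng)
        wa.qkv.weight.data[:, 2 * d:] = 0.0  # V projection
        wa.qkv.bias.data[2 * d:] = 0.0
        wa.proj.bias.data[:] = 0.0
        x = rng.normal(size=(1, ws, ws, d))
        out = wa(Tensor(x), shift=0, mask=None).data
        assert np.abs(out).max() < 1e-12

    def test_attention_rows_sum_to_one(self):
        # softmax normalisation observed through a constant-V probe:
        # with V = identity-mean construction the output equals the mean
        rng = np.random.default_rng(2)
        d, heads, ws = 8, 2, 4
        wa = WindowAttention(d, ws, heads, rng)
        wa.qkv.weight.data[:, 2 * d:] = 0.0
        wa.qkv.bias.data[2 * d:] = 1.0  # V = all-ones for every token
        wa.proj.weight.data = np.eye(d)
        wa.proj.bias.data[:] = 0.0
        x = rng.normal(size=(1, ws, ws, d))
        out = wa(Tensor(x), shift=0, mask=None).data
        # rows of the attention matrix summing to 1 make the output all-ones
        assert np.allclose(out, 1.0, atol=1e-10)


class TestResidualIdentities:
    def test_zeroed_blocks_make_paths_identity(self):
        net = DualPathSRNet(TINY, seed=0)
        rng = np.random.default_rng(3)
        f0 = Tensor(rng.normal(size=(1, TINY.feature_dim, 12, 12)))
        for rstb in net.rstbs:
            for stl in rstb.stls:
                for p in stl.attn.qkv.parameters() + stl.attn.proj.parameters() \
                        + stl.fc1.parameters() + stl.fc2.parameters():
                    p.data[:] = 0.0
                stl.attn.bias_table.data[:] = 0.0
            rstb.conv.weight.data[:] = 0.0
            rstb.conv.bias.data[:] = 0.0
        for rcab in net.rcabs:
            rcab.conv2.weight.data[:] = 0.0
            rcab.conv2.bias.data[:] = 0.0
        assert np.array_equal(net.transformer_path(f0).data, f0.data)
        assert np.array_equal(net.cnn_path(f0).data, f0.data)

    def test_zero_final_conv_reduces_forward_to_bicubic(self, rng):
        # the residual-fusion pathway: an untrained network (zero-init
        # final conv) outputs exactly the bicubic upsample
        net = DualPathSRNet(TINY, seed=0)
        img = rng.uniform(0, 1, (3, 16, 16))
        out = net(Tensor(img[None])).data[0]
        up = np.moveaxis(
            resize_bicubic(np.moveaxis(img, 0, 2), (32, 32)), 2, 0)
        assert np.array_equal(out, up)

    def test_channel_attention_zero_weights_halve_features(self):
        net = DualPathSRNet(TINY, seed=0)
        ca = net.rcabs[0].ca
        for p in ca.fc1.parameters() + ca.fc2.parameters():
            p.data[:] = 0.0
        rng = np.random.default_rng(4)
        f = Tensor(rng.normal(size=(2, TINY.feature_dim, 6, 6)))
        out = ca(f).data
        assert np.allclose(out, 0.5 * f.data)

    def test_channel_attention_gate_in_unit_interval(self, rng):
        net = DualPathSRNet(TINY, seed=0)
        f = Tensor(rng.normal(size=(2, TINY.feature_dim, 6, 6)))
        g = net.rcabs[0].ca.gate(f).data
        assert np.all((g > 0) & (g < 1))


class TestForward:
    def test_output_scale_and_determinism(self, rng):
        for s, hw in ((2, (16, 16)), (4, (8, 8))):
            net = DualPathSRNet(ModelConfig.tiny(scale=s), seed=1)
            x = Tensor(rng.uniform(0, 1, (1, 3, *hw)))
            a = net(x).data
            b = net(x).data
            assert a.shape == (1, 3, hw[0] * s, hw[1] * s)
            assert np.array_equal(a, b)

    def test_arbitrary_size_via_window_padding(self, rng):
        net = DualPathSRNet(TINY, seed=0)
        x = Tensor(rng.uniform(0, 1, (1, 3, 13, 19)))
        assert net(x).shape == (1, 3, 26, 38)

    def test_golden_feature_checksums(self):
        # frozen from the reference forward pass (tiny preset, seed 0)
        net = DualPathSRNet(TINY, seed=0)
        x = np.linspace(0.1, 0.9, 3 * 16 * 16).reshape(1, 3, 16, 16)
        f0 = net.shallow_extract(Tensor(x))
        ft = net.transformer_path(f0)
        fc = net.cnn_path(f0)
        ff = net.fusion(ft, fc)
        assert float(np.abs(f0.data).sum()) == pytest.approx(2509.6517140881, abs=1e-6)
        assert float(np.abs(ft.data).sum()) == pytest.approx(3658.1636549649, abs=1e-6)
        assert float(np.abs(fc.data).sum()) == pytest.approx(3670.7847227547, abs=1e-6)
        assert float(np.abs(ff.data).sum()) == pytest.approx(9237.8798661056, abs=1e-6)

    def test_gradients_reach_every_parameter_group(self, rng):
        net = DualPathSRNet(TINY, seed=0)
        x = Tensor(rng.uniform(0, 1, (2, 3, 8, 8)))
        y = Tensor(rng.uniform(0, 1, (2, 3, 16, 16)))
        loss = ((net(x) - y) ** 2).mean()
        loss.backward()
        for name, p in net.named_parameters().items():
            assert p.grad is not None, name
            if "final" not in name:  # zero-init conv sees zero activations only via bias
                assert np.abs(p.grad).sum() >= 0


class TestParameterCount:
    def test_micro_config_matches_hand_summed_total(self):
        # independent layer-by-layer shape arithmetic:
        d, heads, ws, hidden, r = 8, 2, 2, 16, 2
        shallow = 1 * d * 9 + d
        stl = (2 * d) + (d * 3 * d + 3 * d) + (d * d + d) \
            + ((2 * ws - 1) ** 2 * heads) + (2 * d) \
            + (d * hidden + hidden) + (hidden * d + d)
        rstb = stl + (d * d * 9 + d)
        rcab = 2 * (d * d * 9 + d) + (d * (d // r) + d // r) + ((d // r) * d + d)
        fusion = (2 * d) * d + d
        upsampler = (d * 4 * d * 9 + 4 * d) + (d * 1 * 9 + 1)
        expected = shallow + rstb + rcab + fusion + upsampler
        micro = ModelConfig(scale=2, feature_dim=8, n_rstb=1, stl_per_rstb=1,
                            n_rcab=1, window=2, heads=2, mlp_ratio=2.0,
                            ca_reduction=2, fusion_scales=1, in_channels=1)
        assert count_parameters(micro) == expected == 5071

    def test_count_monotone_in_depth_and_superlinear_in_width(self):
        base = count_parameters(TINY)
        deeper = count_parameters(
            ModelConfig.tiny().__class__(**{**TINY.to_dict(), "n_rstb": 2}))
        assert deeper > base
        wide = count_parameters(
            ModelConfig(**{**TINY.to_dict(), "feature_dim": 32}))
        assert wide > 2 * base

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(feature_dim=15, heads=2)
        with pytest.raises(ConfigError):
            ModelConfig(scale=3)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        net = DualPathSRNet(TINY, seed=5)
        save_checkpoint(tmp_path / "ck.npz", net, {"epoch": 3})
        loaded, meta = load_checkpoint(tmp_path / "ck.npz")
        assert meta["epoch"] == 3
        x = Tensor(rng.uniform(0, 1, (1, 3, 8, 8)))
        assert np.array_equal(net(x).data, loaded(x).data)

    def test_config_mismatch_is_an_error_not_a_cast(self, tmp_path):
        net = DualPathSRNet(TINY, seed=0)
        save_checkpoint(tmp_path / "ck.npz", net)
        other = ModelConfig.tiny(scale=4)
        with pytest.raises(ConfigError):
            load_checkpoint(tmp_path / "ck.npz", expected_cfg=other)
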