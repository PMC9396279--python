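"""MAFFB fusion math against straight-line NumPy/SciPy recomputation."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from fusionsynth.backbone import BackboneConfig, UNetBackbone
from fusionsynth.fusion import (ChannelAttention, FusionNetwork, MAFFB,
                                fuse_ops)
from fusionsynth.nn import Tensor


def attention_oracle(f_concat: np.ndarray, att: ChannelAttention) -> np.ndarray:
    """Straight-line recomputation of the channel-attention map:
    sigmoid(MLP(avgpool) + MLP(maxpool)) with the shared two-layer MLP."""
    w1 = att.fc1.weight.data[:, :, 0, 0]        # (hidden, 3C)
    w2 = att.fc2.weight.data[:, :, 0, 0]        # (3C, hidden)
    out = np.empty((f_concat.shape[0], f_concat.shape[1]))
    for n in range(f_concat.shape[0]):
        avg = f_concat[n].mean(axis=(1, 2))
        mx = f_concat[n].max(axis=(1, 2))
        pre = w2 @ np.maximum(w1 @ avg, 0) + w2 @ np.maximum(w1 @ mx, 0)
        out[n] = 1.0 / (1.0 + np.exp(-pre))
    return out[:, :, None, None]


def conv_bn_relu_oracle(x: np.ndarray, block) -> np.ndarray:
    """Eval-mode conv→BN→ReLU recomputed with scipy correlate2d."""
    conv, bn = block[0], block[1]
    w, b = conv.weight.data, conv.bias.data
    N, C, H, W = x.shape
    F = w.shape[0]
    out = np.zeros((N, F, H, W))
    for n in range(N):
        for f in range(F):
            acc = np.zeros((H, W))
            for c in range(C):
                acc += correlate2d(x[n, c], w[f, c], mode="same")
            out[n, f] = acc + b[f]
    mu = bn.running_mean[None, :, None, None]
    var = bn.running_var[None, :, None, None]
    g = bn.gamma.data[None, :, None, None]
    beta = bn.beta.data[None, :, None, None]
    out = (out - mu) / np.sqrt(var + bn.eps) * g + beta
    return np.maximum(out, 0)


def maffb_oracle(s1: np.ndarray, s2: np.ndarray, block: MAFFB,
                 f_prev: np.ndarray | None = None) -> np.ndarray:
    f_concat = np.concatenate(
        [s1 + s2, s1 * s2, np.maximum(s1, s2)], axis=1)
    gated = f_concat * attention_oracle(f_concat, block.attention)
    h = conv_bn_relu_oracle(gated, block.conv1)
    if f_prev is not None:
        h = np.concatenate([h, f_prev], axis=1)
    return conv_bn_relu_oracle(h, block.conv2)


class TestFuseOps:
    def test_direct_evaluation(self):
        s1 = Tensor(np.array([[1.0, 2.0]]))
        s2 = Tensor(np.array([[3.0, 4.0]]))
        fp, fx, fm = fuse_ops(s1, s2)
        np.testing.assert_array_equal(fp.data, [[4.0, 6.0]])
        np.testing.assert_array_equal(fx.data, [[3.0, 8.0]])
        np.testing.assert_array_equal(fm.data, [[3.0, 4.0]])

    def test_symmetry_is_bit_exact(self):
        rng = np.random.default_rng(0)
        s1, s2 = Tensor(rng.normal(size=(1, 3, 4, 4))), Tensor(rng.normal(size=(1, 3, 4, 4)))
        for a, b in zip(fuse_ops(s1, s2), fuse_ops(s2, s1)):
            assert np.array_equal(a.data, b.data)

    def test_zero_second_operand(self):
        s1 = Tensor(np.array([[-1.0, 2.0]]))
        z = Tensor(np.zeros((1, 2)))
        fp, fx, fm = fuse_ops(s1, z)
        np.testing.assert_array_equal(fp.data, s1.data)
        np.testing.assert_array_equal(fx.data, np.zeros((1, 2)))
        np.testing.assert_array_equal(fm.data, [[0.0, 2.0]])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            fuse_ops(Tensor(np.zeros((1, 2))), Tensor(np.zeros((1, 3))))


class TestChannelAttention:
    def test_global_pools_via_identity_mlp(self):
        # one channel, ratio 1, weights forced to 1: the gate becomes
        # sigmoid(relu(avgpool) + relu(maxpool)); for [[1,3],[5,7]] the
        # pooled descriptors are 4 (average) and 7 (max)
        att = ChannelAttention(1, np.random.default_rng(0), ratio=1)
        att.fc1.weight.data[:] = 1.0
        att.fc2.weight.data[:] = 1.0
        x = Tensor(np.array([[[[1.0, 3.0], [5.0, 7.0]]]]))
        got = float(att(x).data.squeeze())
        assert abs(got - 1.0 / (1.0 + np.exp(-(4.0 + 7.0)))) < 1e-12

    def test_zero_parameters_force_half(self):
        att = ChannelAttention(6, np.random.default_rng(0))
        att.fc1.weight.data[:] = 0.0
        att.fc2.weight.data[:] = 0.0
        x = Tensor(np.random.default_rng(1).normal(size=(2, 6, 4, 4)))
        np.testing.assert_array_equal(att(x).data,
                                      np.full((2, 6, 1, 1), 0.5))

    def test_gate_strictly_inside_unit_interval(self):
        att = ChannelAttention(9, np.random.default_rng(2))
        x = Tensor(np.random.default_rng(3).normal(size=(3, 9, 5, 5)) * 10)
        m = att(x).data
        assert (m > 0).all() and (m < 1).all()

    def test_matches_straight_line_oracle(self):
        rng = np.random.default_rng(4)
        att = ChannelAttention(12, rng)
        x = rng.normal(size=(2, 12, 4, 4))
        got = att(Tensor(x)).data
        np.testing.assert_allclose(got, attention_oracle(x, att), atol=1e-10)


class TestMAFFB:
    def test_full_block_matches_oracle_in_eval_mode(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            block = MAFFB(3, 3, rng, prev_channels=2).eval()
            # non-trivial eval statistics
            for m in block.modules():
                if hasattr(m, "running_mean"):
                    m._buffers["running_mean"][:] = rng.normal(size=m.num_features) * 0.1
                    m._buffers["running_var"][:] = rng.uniform(0.5, 2.0, m.num_features)
            s1 = rng.normal(size=(1, 3, 4, 4))
            s2 = rng.normal(size=(1, 3, 4, 4))
            fp = rng.normal(size=(1, 2, 4, 4))
            got = block(Tensor(s1), Tensor(s2), Tensor(fp)).data
            np.testing.assert_allclose(got, maffb_oracle(s1, s2, block, fp),
                                       atol=1e-9)

    def test_operand_order_is_irrelevant(self):
        rng = np.random.default_rng(6)
        block = MAFFB(4, 4, rng).eval()
        s1 = Tensor(rng.normal(size=(2, 4, 8, 8)))
        s2 = Tensor(rng.normal(size=(2, 4, 8, 8)))
        assert np.array_equal(block(s1, s2).data, block(s2, s1).data)

    def test_spatial_size_preserved(self):
        rng = np.random.default_rng(7)
        block = MAFFB(2, 5, rng)
        out = block(Tensor(rng.normal(size=(1, 2, 6, 6))),
                    Tensor(rng.normal(size=(1, 2, 6, 6))))
        assert out.data.shape == (1, 5, 6, 6)

    def test_f_prev_contract_enforced(self):
        rng = np.random.default_rng(8)
        s = Tensor(rng.normal(size=(1, 2, 4, 4)))
        with_prev = MAFFB(2, 2, rng, prev_channels=3)
        with pytest.raises(ValueError):
            with_prev(s, s)                        # missing f_prev
        with pytest.raises(ValueError):
            with_prev(s, s, Tensor(np.zeros((1, 3, 2, 2))))   # wrong spatial
        without = MAFFB(2, 2, rng)
        with pytest.raises(ValueError):
            without(s, s, Tensor(np.zeros((1, 2, 4, 4))))     # unexpected


class TestFusionNetwork:
    @pytest.fixture
    def setup(self, micro_config):
        r = np.random.default_rng(9)
        b1 = UNetBackbone(micro_config, r)
        b2 = UNetBackbone(micro_config, r)
        net = FusionNetwork(micro_config, r)
        x1 = Tensor(np.random.default_rng(1).normal(size=(1, 1, 16, 16)))
        x2 = Tensor(np.random.default_rng(2).normal(size=(1, 1, 16, 16)))
        return b1, b2, net, x1, x2

    def test_common_widths_follow_unique_widths(self, setup):
        b1, b2, net, x1, x2 = setup
        common = net(b1.encode(x1), b2.encode(x2))
        assert {lvl: t.data.shape[1] for lvl, t in common.items()} == \
            {0: 4, 1: 8, 2: 16}
        assert {lvl: t.data.shape[-1] for lvl, t in common.items()} == \
            {0: 16, 1: 8, 2: 4}

    def test_modality_permutation_invariance_bit_exact(self, setup):
        b1, b2, net, x1, x2 = setup
        net.eval()
        fs1, fs2 = b1.encode(x1), b2.encode(x2)
        a = net(fs1, fs2)
        b = net(fs2, fs1)
        for lvl in a:
            assert np.array_equal(a[lvl].data, b[lvl].data)

    def test_missing_tap_level_raises(self, setup):
        b1, b2, net, x1, x2 = setup
        fs1, fs2 = b1.encode(x1), b2.encode(x2)
        del fs1.levels[2]
        with pytest.raises(ValueError, match="tap level"):
            net(fs1, fs2)

    def test_gradients_reach_both_encoders(self, setup):
        b1, b2, net, x1, x2 = setup
        common = net(b1.encode(x1), b2.encode(x2))
        (common[2] ** 2).sum().backward()
        for enc in (b1, b2):
            g = enc.enc0[0].weight.grad
            assert g is not None and np.abs(g).sum() > 0
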