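"""CRA-MLP and PESA: activation branches, gates, residual identities,
attention normalization, and gradient flow."""

import numpy as np
import pytest

from stemseg.attention import CRAMLP, PESA, ChannelAttention, PositionEnhance
from stemseg.autograd import Tensor
from stemseg.nn import PReLU


@pytest.fixture
def prng():
    return np.random.default_rng(99)


class TestPReLU:
    def test_positive_branch_identity(self):
        act = PReLU(1, init=0.25)
        out = act(Tensor(np.full((1, 1, 1), 3.0)))
        assert out.data.item() == pytest.approx(3.0)

    def test_negative_branch_scales(self):
        act = PReLU(1, init=0.25)
        out = act(Tensor(np.full((1, 1, 1), -2.0)))
        assert out.data.item() == pytest.approx(-0.5)

    def test_zero_slope_reduces_to_relu(self, prng):
        act = PReLU(4, init=0.0)
        x = prng.standard_normal((2, 4, 10))
        np.testing.assert_allclose(act(Tensor(x)).data, np.maximum(x, 0),
                                   atol=1e-12)


class TestChannelAttention:
    def test_zero_input_gives_half_weights(self, prng):
        se = ChannelAttention(8, prng)
        omega = se(Tensor(np.zeros((2, 8, 5))))
        np.testing.assert_allclose(omega.data, 0.5, atol=1e-12)

    def test_weights_bounded_in_unit_interval(self, prng):
        se = ChannelAttention(16, prng)
        omega = se(Tensor(prng.standard_normal((3, 16, 7)) * 10))
        assert (omega.data > 0).all() and (omega.data < 1).all()

    def test_point_permutation_invariant(self, prng):
        se = ChannelAttention(8, prng)
        x = prng.standard_normal((1, 8, 20))
        a = se(Tensor(x)).data
        b = se(Tensor(x[:, :, prng.permutation(20)])).data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_indivisible_channels_rejected(self, prng):
        with pytest.raises(ValueError):
            ChannelAttention(6, prng, reduction=4)


class TestCRAMLP:
    def force_omega(self, block, value):
        """Pin the squeeze-excitation gate to a constant."""
        block.se.forward = lambda x: Tensor(
            np.full((x.shape[0], block.out_channels), value, dtype=np.float32))

    def test_omega_zero_is_residual_identity(self, prng):
        block = CRAMLP(4, [8, 8], prng).eval()
        self.force_omega(block, 0.0)
        x = Tensor(prng.standard_normal((2, 4, 10)).astype(np.float32))
        fd = block.stack(x)
        np.testing.assert_allclose(block(x).data, fd.data, atol=1e-6)

    def test_omega_one_doubles_features(self, prng):
        block = CRAMLP(4, [8, 8], prng).eval()
        self.force_omega(block, 1.0)
        x = Tensor(prng.standard_normal((2, 4, 10)).astype(np.float32))
        fd = block.stack(x)
        np.testing.assert_allclose(block(x).data, 2 * fd.data, atol=1e-5)

    def test_generic_omega_scales_per_channel(self, prng):
        block = CRAMLP(4, [8, 8], prng).eval()
        x = Tensor(prng.standard_normal((1, 4, 12)).astype(np.float32))
        fd = block.stack(x).data
        omega = block.se(block.stack(x)).data  # (1, 8)
        out = block(x).data
        mask = np.abs(fd) > 1e-4
        ratio = np.where(mask, out / np.where(mask, fd, 1.0), np.nan)
        for c in range(8):
            valid = mask[0, c]
            np.testing.assert_allclose(ratio[0, c][valid],
                                       1.0 + float(omega[0, c]), rtol=1e-4)

    def test_shape_preserved_across_widths(self, prng):
        for c in (8, 16, 32):
            block = CRAMLP(c, [c, c], prng)
            x = Tensor(prng.standard_normal((2, c, 6)).astype(np.float32))
            assert block(x).shape == (2, c, 6)


class TestPositionEnhance:
    def test_gate_in_unit_interval_and_shape(self, prng):
        for c in (64, 128, 256, 512, 1024):
            pe = PositionEnhance(c, prng)
            p = Tensor(prng.uniform(-1, 1, (1, 3, 6)).astype(np.float32))
            po = pe(p)
            assert po.shape == (1, c, 6)

    def test_zero_coordinates_give_zero_output(self, prng):
        pe = PositionEnhance(16, prng)
        po = pe(Tensor(np.zeros((2, 3, 5), dtype=np.float32)))
        np.testing.assert_allclose(po.data, 0.0, atol=1e-7)

    def test_gate_none_returns_plain_lift(self, prng):
        pe = PositionEnhance(16, prng, gate="none").eval()
        pe_gated = PositionEnhance(16, prng, gate="gram").eval()
        p = Tensor(prng.uniform(-1, 1, (1, 3, 8)).astype(np.float32))
        pi = pe.bn(pe.conv(p)).relu()
        np.testing.assert_allclose(pe(p).data, pi.data, atol=1e-7)


class TestPESA:
    def test_attention_rows_are_stochastic(self, prng):
        block = PESA(16, prng).eval()
        fused = Tensor(prng.standard_normal((2, 16, 12)).astype(np.float32))
        a = block.attention_matrix(fused).data
        assert (a >= 0).all()
        np.testing.assert_allclose(a.sum(axis=2), 1.0, atol=1e-6)

    def test_zero_cbr_is_residual_identity(self, prng):
        block = PESA(8, prng).eval()
        block.cbr_conv.weight.data[:] = 0
        block.cbr_conv.bias.data[:] = 0
        fi = Tensor(prng.standard_normal((1, 8, 10)).astype(np.float32))
        p = Tensor(prng.uniform(-1, 1, (1, 3, 10)).astype(np.float32))
        po = block.pos(p)
        fused = (po * fi).data
        np.testing.assert_allclose(block(fi, p).data, fused, atol=1e-6)

    def test_unit_position_gate_passes_features_through(self, prng):
        block = PESA(8, prng).eval()
        block.pos.forward = lambda p: Tensor(
            np.ones((p.shape[0], 8, p.shape[2]), dtype=np.float32))
        fi = Tensor(prng.standard_normal((1, 8, 6)).astype(np.float32))
        p = Tensor(prng.uniform(-1, 1, (1, 3, 6)).astype(np.float32))
        block.cbr_conv.weight.data[:] = 0
        block.cbr_conv.bias.data[:] = 0
        np.testing.assert_allclose(block(fi, p).data, fi.data, atol=1e-6)

    def test_identity_attention_with_value_identity_zeroes_offset(self, prng):
        """A = I and V = F' make the CBR input Fsa - F' exactly zero."""
        block = PESA(4, prng).eval()
        block.attention_matrix = lambda fused: Tensor(
            np.tile(np.eye(5, dtype=np.float32), (1, 1, 1)))
        block.wv.weight.data = np.eye(4, dtype=np.float32)
        fi = Tensor(prng.standard_normal((1, 4, 5)).astype(np.float32))
        p = Tensor(prng.uniform(-1, 1, (1, 3, 5)).astype(np.float32))
        po = block.pos(p)
        fused = po * fi
        fsa_minus = (block.wv(fused) @ Tensor(np.eye(5, dtype=np.float32))
                     - fused).data
        np.testing.assert_allclose(fsa_minus, 0.0, atol=1e-6)

    def test_shape_preserved_and_mismatch_rejected(self, prng):
        block = PESA(8, prng).eval()
        fi = Tensor(prng.standard_normal((2, 8, 9)).astype(np.float32))
        p = Tensor(prng.uniform(-1, 1, (2, 3, 9)).astype(np.float32))
        assert block(fi, p).shape == (2, 8, 9)
        with pytest.raises(ValueError, match="point counts"):
            block(fi, Tensor(np.zeros((2, 3, 4), dtype=np.float32)))


def test_gradient_flows_end_to_end(tiny_model_config, prng):
    """Residual paths keep a nonzero input-side gradient (no vanishing)."""
    from stemseg.backbone import StemSegNet
    from stemseg.losses import cross_entropy

    net = StemSegNet(tiny_model_config)
    x = prng.uniform(-1, 1, (1, 256, 3))
    y = prng.integers(0, 2, (1, 256))
    loss = cross_entropy(net.forward(x), y)
    net.zero_grad()
    loss.backward()
    lift_params = net.lift.parameters()
    grad_norm = sum(float(np.abs(p.grad).sum()) for p in lift_params
                    if p.grad is not None)
    assert grad_norm > 0
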