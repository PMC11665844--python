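"""Shape contracts, analytic zero/identity cases and brute-force oracles for
the four building blocks."""

import numpy as np
import pytest

from ddanet.autodiff import Tensor
from ddanet.blocks import (BlockConfig, CSABlock, ChannelAttention, DCPBlock,
                           ResidualBlock, SelfAttention, SpatialAttention)
from ddanet.errors import ConfigurationError, DimensionError
from ddanet.nn import BatchNorm2d
from ddanet.objective import total_loss


def _rng(seed=0):
    return np.random.default_rng(seed)


def _zero_convs(module):
    from ddanet.nn import Conv2d
    for m in module.modules():
        if isinstance(m, Conv2d):
            m.weight.data[:] = 0.0
            if m.bias is not None:
                m.bias.data[:] = 0.0


def _identity_norms(module):
    for m in module.modules():
        if isinstance(m, BatchNorm2d):
            m.reset_to_identity()
    module.eval()


class TestBlockConfig:
    def test_rejects_non_increasing_dilations(self):
        with pytest.raises(ConfigurationError, match="dilation"):
            BlockConfig(4, 4, dilation_rates=(2, 2))
        with pytest.raises(ConfigurationError, match="dilation"):
            BlockConfig(4, 4, dilation_rates=())

    def test_rejects_even_spatial_kernel(self):
        with pytest.raises(ConfigurationError, match="spatial_kernel"):
            BlockConfig(4, 4, spatial_kernel=4)


class TestDCPBlock:
    def test_halves_spatial_size_and_sets_channels(self):
        blk = DCPBlock(BlockConfig(64, 128), rng=_rng())
        out = blk(Tensor(_rng(1).random((1, 64, 32, 32))))
        assert out.shape == (1, 128, 16, 16)

    def test_zero_weights_give_zero_output(self):
        blk = DCPBlock(BlockConfig(4, 8), rng=_rng())
        _zero_convs(blk)
        _identity_norms(blk)
        out = blk(Tensor(_rng(2).random((2, 4, 8, 8))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_rejects_odd_spatial_size_naming_axis(self):
        blk = DCPBlock(BlockConfig(2, 4), rng=_rng())
        with pytest.raises(DimensionError, match="height"):
            blk(Tensor(np.zeros((1, 2, 7, 8))))
        with pytest.raises(DimensionError, match="width"):
            blk(Tensor(np.zeros((1, 2, 8, 7))))

    def test_rejects_channel_mismatch(self):
        blk = DCPBlock(BlockConfig(4, 8), rng=_rng())
        with pytest.raises(ValueError, match="channels"):
            blk(Tensor(np.zeros((1, 3, 8, 8))))

    def test_dilated_branch_receptive_field_is_nine_by_nine(self):
        # a rate-4 3×3 kernel spans an effective extent of 2·4+1 = 9 pixels
        blk = DCPBlock(BlockConfig(1, 1, dilation_rates=(4,)), rng=_rng())
        impulse = np.zeros((1, 1, 32, 32))
        impulse[0, 0, 16, 16] = 1.0
        response = blk.branch_convs[0](Tensor(impulse)).data[0, 0]
        nz_r, nz_c = np.nonzero(response != response[0, 0])  # vs bias background
        assert nz_r.size > 0
        assert nz_r.min() >= 12 and nz_r.max() <= 20
        assert nz_c.min() >= 12 and nz_c.max() <= 20
        assert nz_r.max() - nz_r.min() == 8 and nz_c.max() - nz_c.min() == 8


class TestSelfAttention:
    def test_preserves_shape(self):
        sam = SelfAttention(BlockConfig(16, 16, attention_key_reduction=8), rng=_rng())
        out = sam(Tensor(_rng(3).random((2, 16, 8, 8))))
        assert out.shape == (2, 16, 8, 8)

    def test_rejects_non_divisible_reduction(self):
        with pytest.raises(ConfigurationError, match="divisible"):
            SelfAttention(BlockConfig(6, 6, attention_key_reduction=4), rng=_rng())

    def test_zeroed_output_projection_returns_input_bit_exactly(self):
        sam = SelfAttention(BlockConfig(8, 8), rng=_rng())
        sam.out_conv.weight.data[:] = 0.0
        sam.out_conv.bias.data[:] = 0.0
        x = _rng(4).random((1, 8, 4, 4)).astype(np.float32)
        out = sam(Tensor(x))
        np.testing.assert_array_equal(out.data, x)

    def test_attention_rows_sum_to_one(self):
        for seed, (h, w) in [(0, (2, 2)), (1, (3, 4)), (2, (4, 4))]:
            sam = SelfAttention(BlockConfig(8, 8), rng=_rng(seed))
            att = sam.attention_tensors(_rng(seed + 10).random((8, h, w)))
            assert att.weights.shape == (h * w, h * w)
            np.testing.assert_allclose(att.weights.sum(axis=1), 1.0, atol=1e-5)
            assert np.all(att.weights >= 0.0) and np.all(att.weights <= 1.0)

    @pytest.mark.parametrize("spatial", [(2, 2), (3, 3), (4, 4)])
    def test_matches_brute_force_position_pair_oracle(self, spatial):
        h, w = spatial
        sam = SelfAttention(BlockConfig(8, 8), rng=_rng(7))
        x = _rng(8).random((1, 8, h, w))
        out = sam(Tensor(x)).data[0]

        # independent double loop over all query/key position pairs
        def conv1x1(weight, bias, img):
            c_out = weight.shape[0]
            res = np.zeros((c_out, h, w))
            for i in range(h):
                for j in range(w):
                    res[:, i, j] = weight[:, :, 0, 0] @ img[:, i, j] + bias
            return res

        q = conv1x1(sam.q_conv.weight.data, sam.q_conv.bias.data, x[0])
        k = conv1x1(sam.k_conv.weight.data, sam.k_conv.bias.data, x[0])
        v = conv1x1(sam.v_conv.weight.data, sam.v_conv.bias.data, x[0])
        positions = [(i, j) for i in range(h) for j in range(w)]
        attended = np.zeros((8, h, w))
        for qi, qj in positions:
            logits = np.array([q[:, qi, qj] @ k[:, ki, kj] for ki, kj in positions])
            weights = np.exp(logits - logits.max())
            weights /= weights.sum()
            acc = sum(wgt * v[:, ki, kj]
                      for wgt, (ki, kj) in zip(weights, positions))
            attended[:, qi, qj] = acc
        expected = x[0] + conv1x1(sam.out_conv.weight.data,
                                  sam.out_conv.bias.data, attended)
        np.testing.assert_allclose(out, expected, atol=1e-5)


class TestResidualBlock:
    def test_identity_shortcut_when_channels_match(self):
        blk = ResidualBlock(16, 16, rng=_rng())
        assert not blk.has_projection
        out = blk(Tensor(_rng(1).random((1, 16, 16, 16))))
        assert out.shape == (1, 16, 16, 16)

    def test_projected_shortcut_when_channels_differ(self):
        blk = ResidualBlock(16, 32, rng=_rng())
        assert blk.has_projection
        out = blk(Tensor(_rng(2).random((1, 16, 16, 16))))
        assert out.shape == (1, 32, 16, 16)

    def test_zeroed_main_path_reduces_to_rectification(self):
        blk = ResidualBlock(8, 8, rng=_rng())
        _zero_convs(blk)
        _identity_norms(blk)
        x = _rng(3).normal(size=(2, 8, 6, 6))
        out = blk(Tensor(x))
        np.testing.assert_allclose(out.data, np.maximum(x, 0.0), atol=1e-7)


class TestChannelAttention:
    def test_gates_strictly_inside_unit_interval_and_shape_preserved(self):
        ca = ChannelAttention(16, reduction=4, rng=_rng())
        x = Tensor(_rng(1).random((2, 16, 8, 8)))
        gate = ca.gate(x).data
        assert np.all(gate > 0.0) and np.all(gate < 1.0)
        assert ca(x).shape == (2, 16, 8, 8)

    def test_zeroed_gate_path_halves_input(self):
        ca = ChannelAttention(8, reduction=4, rng=_rng())
        _zero_convs(ca)
        x = _rng(2).random((1, 8, 4, 4)).astype(np.float32)
        np.testing.assert_allclose(ca(Tensor(x)).data, 0.5 * x, atol=1e-7)

    def test_hand_computed_gates_for_constant_channels(self):
        ca = ChannelAttention(2, reduction=1, rng=_rng())
        # hand-set weights: squeeze = identity, excite = identity, biases 0
        ca.squeeze.weight.data = np.eye(2).reshape(2, 2, 1, 1).astype(np.float32)
        ca.squeeze.bias.data[:] = 0.0
        ca.excite.weight.data = np.eye(2).reshape(2, 2, 1, 1).astype(np.float32)
        ca.excite.bias.data[:] = 0.0
        c = 0.8
        x = np.zeros((1, 2, 4, 4))
        x[0, 1] = c
        gate = ca.gate(Tensor(x)).data[0, :, 0, 0]
        # channel 0 pools to 0 -> logistic(0) = 0.5; channel 1 pools to c
        assert gate[0] == pytest.approx(0.5, abs=1e-7)
        assert gate[1] == pytest.approx(1 / (1 + np.exp(-c)), abs=1e-6)

    def test_rejects_non_dividing_reduction(self):
        with pytest.raises(ConfigurationError, match="reduction"):
            ChannelAttention(6, reduction=4, rng=_rng())


class TestSpatialAttention:
    def test_shape_preserved_and_gates_in_unit_interval(self):
        sa = SpatialAttention(7, rng=_rng())
        x = Tensor(_rng(1).random((2, 8, 8, 8)))
        gate = sa.gate(x).data
        assert gate.shape == (2, 1, 8, 8)
        assert np.all(gate > 0.0) and np.all(gate < 1.0)
        assert sa(x).shape == (2, 8, 8, 8)

    def test_zeroed_kernel_halves_input(self):
        sa = SpatialAttention(7, rng=_rng())
        _zero_convs(sa)
        x = _rng(2).random((1, 4, 6, 6)).astype(np.float32)
        np.testing.assert_allclose(sa(Tensor(x)).data, 0.5 * x, atol=1e-7)

    def test_single_channel_gate_is_logistic_of_scaled_input(self):
        sa = SpatialAttention(1, rng=_rng())
        w_mean, w_max = 0.7, 0.3
        sa.conv.weight.data = np.array([[[[w_mean]], [[w_max]]]], dtype=np.float32)
        sa.conv.bias.data[:] = 0.0
        x = _rng(3).random((1, 1, 3, 3))
        gate = sa.gate(Tensor(x)).data[0, 0]
        expected = 1.0 / (1.0 + np.exp(-(w_mean + w_max) * x[0, 0]))
        np.testing.assert_allclose(gate, expected, atol=1e-6)

    def test_rejects_even_kernel(self):
        with pytest.raises(ConfigurationError, match="odd"):
            SpatialAttention(4, rng=_rng())


class TestCSABlock:
    def test_equals_sequential_composition(self):
        csa = CSABlock(8, reduction=4, spatial_kernel=7, rng=_rng(5))
        x = Tensor(_rng(6).random((2, 8, 8, 8)))
        fused = csa(x).data
        manual = csa.spatial(csa.channel(x)).data
        np.testing.assert_array_equal(fused, manual)

    def test_both_paths_zeroed_quarter_input(self):
        csa = CSABlock(8, reduction=4, rng=_rng())
        _zero_convs(csa)
        x = _rng(7).random((1, 8, 4, 4)).astype(np.float32)
        np.testing.assert_allclose(csa(Tensor(x)).data, 0.25 * x, atol=1e-7)


@pytest.mark.parametrize("factory", [
    lambda rng: DCPBlock(BlockConfig(4, 8), rng=rng),
    lambda rng: SelfAttention(BlockConfig(8, 8), rng=rng),
    lambda rng: ResidualBlock(4, 8, rng=rng),
    lambda rng: CSABlock(8, reduction=4, rng=rng),
])
def test_every_block_parameter_receives_gradient(factory):
    rng = _rng(11)
    blk = factory(rng)
    cin = 4 if isinstance(blk, (DCPBlock, ResidualBlock)) else 8
    x = Tensor(rng.random((2, cin, 8, 8)))
    out = blk(x)
    target = rng.integers(0, 2, out.size).astype(float)
    loss = total_loss(target, out.sigmoid().reshape(-1))
    blk.zero_grad()
    loss.backward()
    for name, p in blk.named_parameters():
        assert p.grad is not None and np.abs(p.grad).sum() > 0, name
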