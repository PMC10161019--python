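import numpy as np
import pytest

from hepavess.nn import Adam, Param
from hepavess.resdense_unet import (
    ConvUnit,
    DenseBlock,
    NetworkConfig,
    PlainBlock,
    ResDenseBlock,
    ResidualBlock,
    build_unet,
    load_model,
    save_model,
)
from hepavess.trainer import soft_dice_grad, soft_dice_loss


def _zero_convs(obj):
    """Zero every conv weight/bias reachable through params()."""
    for p in obj.params():
        p.data[...] = 0.0 if "conv" in p.name else p.data


class TestConvUnit:
    def test_shape_contract_and_nonnegativity(self, rng):
        unit = ConvUnit(3, 7, rng)
        x = rng.normal(size=(2, 12, 12, 3)).astype(np.float32)
        y = unit.forward(x, train=True)
        assert y.shape == (2, 12, 12, 7)
        assert y.min() >= 0.0  # ReLU output

    def test_two_conv_units_per_block(self, rng):
        block = ResDenseBlock(4, 8, rng)
        assert isinstance(block.u1, ConvUnit) and isinstance(block.u2, ConvUnit)


class TestResDenseBlock:
    def test_output_channels_are_width_plus_input(self, rng):
        block = ResDenseBlock(32, 32, rng)
        x = rng.normal(size=(1, 8, 8, 32)).astype(np.float32)
        y = block.forward(x, train=True)
        assert y.shape == (1, 8, 8, 64)  # doubled when width == c_in

    def test_identity_path_survives_zeroed_convs(self, rng):
        block = ResDenseBlock(5, 9, rng)
        _zero_convs(block)
        x = rng.normal(size=(2, 6, 6, 5)).astype(np.float32)
        y = block.forward(x, train=False)
        np.testing.assert_array_equal(y[..., 9:], x)

    def test_gradient_reaches_input_through_identity_path(self, rng):
        block = ResDenseBlock(4, 6, rng)
        _zero_convs(block)
        x = rng.normal(size=(1, 4, 4, 4)).astype(np.float32)
        y = block.forward(x, train=False)
        dx = block.backward(np.ones_like(y))
        assert np.abs(dx).max() > 0.0

    def test_shape_differs_from_summation_residual(self, rng):
        x = rng.normal(size=(1, 8, 8, 16)).astype(np.float32)
        concat_out = ResDenseBlock(16, 16, rng).forward(x, train=True)
        sum_out = ResidualBlock(16, 16, rng).forward(x, train=True)
        assert concat_out.shape[-1] == 32 and sum_out.shape[-1] == 16


@pytest.mark.parametrize("cls,expected_c", [
    (ResDenseBlock, 10 + 4),
    (ResidualBlock, 10),
    (DenseBlock, 2 * 10 + 4),
    (PlainBlock, 10),
])
def test_block_variants_shape_contracts(cls, expected_c, rng):
    block = cls(4, 10, rng)
    x = rng.normal(size=(2, 8, 8, 4)).astype(np.float32)
    assert block.forward(x, train=True).shape == (2, 8, 8, expected_c)


class TestNetworkConfig:
    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig(levels=5, input_size=100)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(levels=1)

    def test_unknown_block_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(block="transformer")


class TestUNet:
    def test_forward_shape_and_probability_range(self, rng):
        net = build_unet(NetworkConfig(levels=3, base_channels=4, input_size=32))
        x = rng.normal(size=(2, 1, 32, 32)).astype(np.float32)
        y = net.forward(x)
        assert y.shape == (2, 1, 32, 32)
        assert 0.0 < y.min() and y.max() < 1.0
        assert np.all(np.isfinite(y))

    def test_forward_on_smaller_divisible_input(self, rng):
        net = build_unet(NetworkConfig(levels=3, base_channels=4, input_size=64))
        y = net.forward(rng.normal(size=(1, 1, 32, 32)).astype(np.float32))
        assert y.shape == (1, 1, 32, 32)

    def test_indivisible_runtime_input_rejected(self, rng):
        net = build_unet(NetworkConfig(levels=3, base_channels=4, input_size=32))
        with pytest.raises(ValueError, match="divisible"):
            net.forward(rng.normal(size=(1, 1, 30, 30)).astype(np.float32))

    def test_parameter_count_increases_with_width(self):
        n8 = build_unet(NetworkConfig(levels=3, base_channels=8, input_size=32))
        n16 = build_unet(NetworkConfig(levels=3, base_channels=16, input_size=32))
        assert n16.n_parameters() > n8.n_parameters()

    def test_inference_is_deterministic(self, rng):
        net = build_unet(NetworkConfig(levels=2, base_channels=4, input_size=16))
        x = rng.normal(size=(3, 1, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), net.forward(x))

    def test_seeded_init_is_reproducible(self, rng):
        a = build_unet(NetworkConfig(levels=2, base_channels=4, input_size=16), seed=5)
        b = build_unet(NetworkConfig(levels=2, base_channels=4, input_size=16), seed=5)
        x = rng.normal(size=(1, 1, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(a.forward(x), b.forward(x))

    def test_gradients_match_finite_differences(self, rng):
        net = build_unet(NetworkConfig(levels=2, base_channels=4, input_size=8))
        x = rng.normal(size=(2, 1, 8, 8)).astype(np.float32)
        t = (rng.random((2, 1, 8, 8)) > 0.7).astype(np.float32)
        pred = net.forward(x, train=True)
        for p in net.parameters():
            p.zero_grad()
        net.backward(soft_dice_grad(pred, t))
        eps = 1e-3
        check_rng = np.random.default_rng(0)
        for p in net.parameters()[::4]:
            flat = p.data.ravel()
            idx = int(check_rng.integers(flat.size))
            old = flat[idx]
            flat[idx] = old + eps
            lp = soft_dice_loss(net.forward(x, train=True), t)
            flat[idx] = old - eps
            lm = soft_dice_loss(net.forward(x, train=True), t)
            flat[idx] = old
            fd = (lp - lm) / (2 * eps)
            an = p.grad.ravel()[idx]
            # float32 forward passes limit finite-difference accuracy
            assert an == pytest.approx(fd, abs=2e-3 + 0.05 * abs(fd))

    def test_checkpoint_roundtrip_preserves_outputs(self, rng, tmp_path):
        net = build_unet(NetworkConfig(levels=2, base_channels=4, input_size=16), seed=1)
        x = rng.normal(size=(2, 1, 16, 16)).astype(np.float32)
        before = net.forward(x)
        save_model(net, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        assert back.config == net.config
        np.testing.assert_array_equal(back.forward(x), before)

    def test_summary_mentions_every_level(self):
        net = build_unet(NetworkConfig(levels=3, base_channels=4, input_size=32))
        s = net.summary()
        assert "enc L0" in s and "enc L1" in s and "bottleneck" in s and "dec L0" in s


class TestOptimizer:
    def test_adam_reduces_a_quadratic(self, rng):
        p = Param(np.array([5.0, -3.0], dtype=np.float32))
        opt = Adam([p], lr=0.1)
        for _ in range(200):
            opt.zero_grad()
            p.grad[...] = 2 * p.data
            opt.step()
        assert np.abs(p.data).max() < 0.1
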