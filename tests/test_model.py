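"""Network architecture contracts: SE gating, shapes, parameter counts, gradients."""

import numpy as np
import pytest

from octa.model import (
    ConfigurationError,
    ModelConfig,
    SEBlockSpec,
    UNet2D,
    load_checkpoint,
    save_checkpoint,
    se_block_forward,
    se_extra_parameter_count,
    unet_forward,
)
from octa.nn.layers import SEBlock

SMALL = dict(n_channels_in=2, depth=2, base_features=8, se_reduction=4)


class TestSEBlock:
    def test_output_is_channelwise_scalar_gating(self, rng):
        x = rng.standard_normal((4, 6, 5))
        spec = SEBlockSpec(channels=4, reduction=2)
        w = {
            "w1": rng.standard_normal((2, 4)),
            "b1": rng.standard_normal(2),
            "w2": rng.standard_normal((4, 2)),
            "b2": rng.standard_normal(4),
        }
        y = se_block_forward(x, spec, w)
        assert y.shape == x.shape
        gains = y / x
        for c in range(4):
            g = gains[c].ravel()
            np.testing.assert_allclose(g, g[0], rtol=1e-10)
            assert 0.0 < g[0] < 1.0

    def test_saturated_bias_gives_identity(self, rng):
        x = rng.standard_normal((4, 3, 3))
        w = {
            "w1": np.zeros((2, 4)),
            "b1": np.zeros(2),
            "w2": np.zeros((4, 2)),
            "b2": np.full(4, 50.0),  # sigmoid(50) ~ 1
        }
        y = se_block_forward(x, SEBlockSpec(4, 2), w)
        np.testing.assert_allclose(y, x, rtol=1e-10)

    def test_hand_computed_bottleneck(self):
        """C=4, r=2 worked example: constant-per-channel input, hand-set weights."""
        x = np.stack([np.full((2, 2), v) for v in [1.0, 2.0, -1.0, 0.5]])
        w1 = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, -1.0, 0.0]])
        b1 = np.array([0.0, -0.5])
        w2 = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [-1.0, 0.0]])
        b2 = np.zeros(4)
        # squeeze = [1, 2, -1, 0.5]; z1 = [1, 2.5]; relu -> [1, 2.5]
        # z2 = [1, 2.5, 3.5, -1]; gates = sigmoid(z2)
        gates = 1 / (1 + np.exp(-np.array([1.0, 2.5, 3.5, -1.0])))
        y = se_block_forward(x, SEBlockSpec(4, 2), {"w1": w1, "b1": b1, "w2": w2, "b2": b2})
        np.testing.assert_allclose(y, x * gates[:, None, None], rtol=1e-12)

    def test_indivisible_reduction_rejected(self):
        with pytest.raises((ConfigurationError, ValueError)):
            SEBlockSpec(channels=6, reduction=4)
        with pytest.raises(ValueError):
            SEBlock(channels=6, reduction=4)

    def test_gates_strictly_inside_unit_interval(self, rng):
        blk = SEBlock(channels=8, reduction=4, rng=rng)
        g = blk.gates(rng.standard_normal((3, 8, 4, 4)) * 10)
        assert (g > 0).all() and (g < 1).all()


class TestUNetForward:
    def test_shape_contract(self, rng):
        cfg = ModelConfig(**SMALL)
        out = unet_forward(rng.random((2, 32, 32)), cfg, UNet2D(cfg, seed=0))
        assert out.shape == (1, 32, 32)

    def test_indivisible_size_rejected_without_padding(self, rng):
        cfg = ModelConfig(**SMALL)
        with pytest.raises(ConfigurationError):
            UNet2D(cfg, seed=0)(rng.random((1, 2, 30, 30)))

    def test_pad_and_crop_mode(self, rng):
        cfg = ModelConfig(**SMALL, pad_inputs=True)
        out = UNet2D(cfg, seed=0)(rng.random((1, 2, 30, 27)), train=False)
        assert out.shape == (1, 1, 30, 27)

    def test_se_parameter_overhead_closed_form(self):
        plain = UNet2D(ModelConfig(**SMALL, se_enabled=False), seed=0)
        se = UNet2D(ModelConfig(**SMALL, se_enabled=True), seed=0)
        cfg = ModelConfig(**SMALL, se_enabled=True)
        assert se.n_parameters() - plain.n_parameters() == se_extra_parameter_count(cfg)

    def test_deterministic_given_weights(self, rng):
        cfg = ModelConfig(**SMALL)
        net = UNet2D(cfg, seed=3)
        x = rng.random((1, 2, 16, 16))
        a = net(x, train=False)
        b = net(x, train=False)
        assert (a == b).all()

    def test_no_dead_input_channels(self, rng):
        """Zeroing an input channel must change the output (smoke)."""
        cfg = ModelConfig(n_channels_in=3, depth=2, base_features=8)
        net = UNet2D(cfg, seed=1)
        x = rng.random((1, 3, 16, 16))
        base = net(x, train=False)
        for k in range(3):
            xz = x.copy()
            xz[:, k] = 0.0
            assert not np.allclose(net(xz, train=False), base)

    def test_channel_mismatch_rejected(self, rng):
        net = UNet2D(ModelConfig(**SMALL), seed=0)
        with pytest.raises(ConfigurationError):
            net(rng.random((1, 5, 16, 16)))


class TestGradients:
    @pytest.mark.parametrize(
        "se_enabled,norm", [(False, "instance"), (True, "instance"), (True, "batch")]
    )
    def test_backward_matches_central_differences(self, rng, se_enabled, norm):
        """Analytic parameter gradients agree with numerical differentiation."""
        cfg = ModelConfig(
            n_channels_in=2, depth=2, base_features=4,
            se_enabled=se_enabled, se_reduction=2, norm=norm,
        )
        net = UNet2D(cfg, seed=0)
        x = rng.random((2, 2, 8, 8))
        y = rng.random((2, 1, 8, 8))
        out = net(x, train=True)
        resid = out - y
        net.zero_grad()
        net.backward(2.0 * resid / resid.size)
        params = net.params()
        for pi in range(0, len(params), 5):
            p = params[pi]
            idx = p.value.size // 2
            eps = 1e-6
            orig = p.value.flat[idx]
            p.value.flat[idx] = orig + eps
            lp = np.mean((net(x, train=True) - y) ** 2)
            p.value.flat[idx] = orig - eps
            lm = np.mean((net(x, train=True) - y) ** 2)
            p.value.flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = p.grad.flat[idx]
            assert ana == pytest.approx(num, rel=1e-4, abs=1e-9)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, rng, tmp_path):
        cfg = ModelConfig(**SMALL, se_enabled=True)
        net = UNet2D(cfg, seed=5)
        x = rng.random((1, 2, 16, 16))
        # move BN running stats off their init values
        net(rng.random((4, 2, 16, 16)), train=True)
        before = net(x, train=False)
        path = tmp_path / "model.npz"
        save_checkpoint(path, net, {"seed": 5})
        loaded, prov = load_checkpoint(path)
        assert prov == {"seed": 5}
        np.testing.assert_array_equal(loaded(x, train=False), before)
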