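"""Autodiff engine, ST-SC module, model contracts, and the dice loss."""

import numpy as np
import pytest

from ivdquant.network import (STSC, Adam, ConfigError, NetConfig, Tensor,
                              build_bianquenet, default_channel_weights,
                              load_checkpoint, one_hot, save_checkpoint,
                              weighted_dice_loss)
from ivdquant.network.autodiff import (adaptive_avg_pool2d, concat, conv2d,
                                       conv_transpose2d, resize_nearest,
                                       softmax)


def _numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x.data)
    it = np.nditer(x.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x.data[i] += eps
        fp = f().item()
        x.data[i] -= 2 * eps
        fm = f().item()
        x.data[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestAutodiff:
    @pytest.mark.parametrize("op", ["conv", "deconv", "pool", "resize",
                                    "softmax"])
    def test_gradients_match_finite_differences(self, op, rng):
        if op == "conv":
            x = Tensor(rng.normal(size=(1, 2, 6, 7)), requires_grad=True)
            w = Tensor(rng.normal(size=(3, 2, 3, 3)), requires_grad=True)
            f = lambda: (conv2d(x, w, stride=2, padding=1) ** 2.0).sum()
            params = [x, w]
        elif op == "deconv":
            x = Tensor(rng.normal(size=(1, 2, 4, 4)), requires_grad=True)
            w = Tensor(rng.normal(size=(2, 3, 2, 2)), requires_grad=True)
            f = lambda: (conv_transpose2d(x, w, stride=2) ** 2.0).sum()
            params = [x, w]
        elif op == "pool":
            x = Tensor(rng.normal(size=(1, 2, 5, 7)), requires_grad=True)
            f = lambda: (adaptive_avg_pool2d(x, 3) ** 2.0).sum()
            params = [x]
        elif op == "resize":
            x = Tensor(rng.normal(size=(1, 2, 3, 4)), requires_grad=True)
            f = lambda: (resize_nearest(x, 7, 5) ** 2.0).sum()
            params = [x]
        else:
            x = Tensor(rng.normal(size=(2, 6)), requires_grad=True)
            f = lambda: ((softmax(x, axis=-1) - 0.3) ** 2.0).sum()
            params = [x]
        loss = f()
        loss.backward()
        for p in params:
            num = _numeric_grad(f, p)
            np.testing.assert_allclose(p.grad, num, atol=1e-6)


class TestSTSC:
    def test_channel_reduction_default_eighth(self, rng):
        mod = STSC(np.random.default_rng(0), c_in=64, window=2)
        x = Tensor(rng.normal(size=(1, 64, 8, 8)))
        y = mod(x)
        assert y.shape == (1, 8, 8, 8)  # 64/8 channels

    def test_degenerate_weights_finite(self):
        mod = STSC(np.random.default_rng(0), c_in=16, window=2)
        for p in mod.parameters():
            p.data[:] = 0.0
        x = Tensor(np.random.default_rng(1).normal(size=(1, 16, 4, 4)))
        y = mod(x)
        assert np.isfinite(y.data).all()

    def test_shifted_vs_unshifted_differ_on_nonconstant_input(self):
        from ivdquant.network.swin import SwinBlock
        rng = np.random.default_rng(0)
        b0 = SwinBlock(rng, dim=8, heads=2, window=2, shift=0)
        b1 = SwinBlock(np.random.default_rng(0), dim=8, heads=2, window=2,
                       shift=1)
        const = Tensor(np.ones((1, 4, 4, 8)))
        rnd = Tensor(np.random.default_rng(2).normal(size=(1, 4, 4, 8)))
        np.testing.assert_allclose(b0(const).data, b1(const).data, atol=1e-9)
        assert not np.allclose(b0(rnd).data, b1(rnd).data)

    def test_indivisible_window_rejected(self):
        mod = STSC(np.random.default_rng(0), c_in=16, window=3)
        with pytest.raises(ValueError, match="window"):
            mod(Tensor(np.ones((1, 16, 4, 4))))


class TestModelContracts:
    def test_input_not_divisible_by_16_rejected(self):
        with pytest.raises(ConfigError):
            NetConfig(input_size=(60, 64))

    @pytest.mark.parametrize("hw", [(64, 64), (16, 48)])
    def test_output_shape_and_softmax(self, hw, rng):
        net = build_bianquenet(NetConfig(input_size=hw, seed=1))
        out = net(rng.normal(size=hw) ** 2)
        assert out.shape == (1, 14, *hw)
        np.testing.assert_allclose(out.data.sum(axis=1), 1.0, atol=1e-5)

    def test_gradient_norm_finite(self, rng):
        net = build_bianquenet(NetConfig(input_size=(16, 16), seed=2))
        target = one_hot(rng.integers(0, 14, size=(16, 16)))
        loss = weighted_dice_loss(net(rng.random((16, 16))), target)
        loss.backward()
        norms = [np.linalg.norm(p.grad) for p in net.parameters()
                 if p.grad is not None]
        assert norms and np.isfinite(norms).all()

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        net = build_bianquenet(NetConfig(input_size=(16, 16), seed=3))
        img = rng.random((16, 16))
        ref = net(img).data
        path = tmp_path / "w.npz"
        save_checkpoint(net, path)
        other = build_bianquenet(NetConfig(input_size=(16, 16), seed=99))
        load_checkpoint(other, path)
        np.testing.assert_allclose(other(img).data, ref, atol=1e-12)

    def test_full_preset_constructs(self):
        net = build_bianquenet(NetConfig.full(input_size=(512, 512)))
        n = sum(p.data.size for p in net.parameters())
        assert n > 4e7  # resnet101-scale backbone
        assert net.backbone.out_channels == 2048


class TestWeightedDiceLoss:
    def test_default_weights(self):
        xi = default_channel_weights()
        assert (xi[1:6] == 0.9).all()
        assert (xi[6:11] == 0.8).all()
        assert xi[0] == 1.0 and (xi[11:] == 1.0).all()

    def test_perfect_prediction_zero_loss(self, rng):
        labels = rng.integers(0, 14, size=(8, 8))
        t = one_hot(labels)
        assert weighted_dice_loss(t, t).item() == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_one_hot_loss(self, rng):
        labels = np.arange(14).repeat(14).reshape(14, 14)
        pred = one_hot((labels + 1) % 14)
        truth = one_hot(labels)
        expect = (5 * 0.9 + 5 * 0.8 + 4 * 1.0) / 14
        assert weighted_dice_loss(pred, truth).item() == pytest.approx(
            expect, abs=1e-6)

    def test_loss_bounded_by_mean_weight(self, rng):
        for _ in range(10):
            p = rng.random((1, 14, 6, 6))
            p /= p.sum(axis=1, keepdims=True)
            t = one_hot(rng.integers(0, 14, size=(6, 6)))
            val = weighted_dice_loss(p, t).item()
            xi = default_channel_weights()
            assert 0.0 <= val <= xi.mean() + 1e-12

    def test_unit_weights_match_soft_dice_mean(self, rng):
        p = rng.random((1, 5, 6, 6))
        p /= p.sum(axis=1, keepdims=True)
        t = one_hot(rng.integers(0, 5, size=(6, 6)), n_classes=5)
        val = weighted_dice_loss(p, t, xi=np.ones(5), eps=0.0).item()
        dices = []
        for c in range(5):
            tp = (p[0, c] * t[0, c]).sum()
            fn = ((1 - p[0, c]) * t[0, c]).sum()
            fp = (p[0, c] * (1 - t[0, c])).sum()
            dices.append(2 * tp / (2 * tp + fn + fp))
        assert val == pytest.approx(1 - np.mean(dices), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_dice_loss(np.ones((1, 3, 4, 4)), np.ones((1, 3, 5, 5)))

    def test_short_training_decreases_loss(self, rng):
        # a brief optimisation on a small scene must make progress
        net = build_bianquenet(NetConfig(input_size=(16, 16), seed=5))
        labels = np.zeros((16, 16), dtype=int)
        labels[4:12, 4:12] = 1
        t = one_hot(labels)
        img = (labels == 1).astype(float)
        opt = Adam(net.parameters(), lr=1e-2)
        first = None
        for _ in range(15):
            opt.zero_grad()
            loss = weighted_dice_loss(net(img), t)
            loss.backward()
            opt.step()
            first = first if first is not None else loss.item()
        assert loss.item() < first
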