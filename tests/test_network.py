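"""Architecture contracts: shapes, sharing, isolation, serialization."""

import numpy as np
import pytest

from mammodensity import nn
from mammodensity.losses import focal_tversky_loss
from mammodensity.network import (MDRBlock, NetworkConfig, build_model,
                                  forward, load_checkpoint, save_checkpoint)

TINY = NetworkConfig(input_side=32, depth=2, base_width=4)


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(TINY, seed=1)


def _batch(rng, n=2, side=32):
    return rng.random((n, 1, side, side)).astype(np.float32)


class TestConfig:
    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig(input_side=100, depth=3)

    def test_dilations_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            NetworkConfig(bottleneck_dilations=(3, 1))

    def test_two_class_heads_enforced(self):
        with pytest.raises(ValueError):
            NetworkConfig(classes_per_head=1)


class TestForward:
    def test_output_shapes_and_softmax(self, tiny_model, rng):
        out = tiny_model.forward_tensors(nn.Tensor(_batch(rng)))
        for head in ("breast", "dense"):
            assert out[head].shape == (2, 2, 32, 32)
            sums = out[head].data.sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-5)
            assert out[head].data.min() >= 0.0

    def test_eval_determinism(self, tiny_model, rng):
        x = _batch(rng)
        m1 = forward(tiny_model, x[:, 0])
        m2 = forward(tiny_model, x[:, 0])
        np.testing.assert_array_equal(m1[0].breast, m2[0].breast)
        np.testing.assert_array_equal(m1[0].dense, m2[0].dense)

    def test_zero_logits_give_half_probabilities(self, rng):
        model = build_model(TINY, seed=0)
        for head in ("breast", "dense"):
            dec = model.decoders[head]
            dec.head.weight.data[...] = 0.0
            dec.head.bias.data[...] = 0.0
        out = model.forward_tensors(nn.Tensor(_batch(rng)))
        np.testing.assert_allclose(out["breast"].data, 0.5, atol=1e-7)
        np.testing.assert_allclose(out["dense"].data, 0.5, atol=1e-7)

    def test_wrong_input_side_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError, match="expected"):
            forward(tiny_model, rng.random((16, 16)))


class TestParameters:
    def test_doubling_width_increases_parameter_count(self):
        small = build_model(NetworkConfig(input_side=32, depth=2, base_width=4))
        big = build_model(NetworkConfig(input_side=32, depth=2, base_width=8))
        assert big.parameter_count() > small.parameter_count()

    def test_build_seed_determinism(self):
        a = build_model(TINY, seed=7)
        b = build_model(TINY, seed=7)
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_gradient_routing(self, rng):
        """Breast-head loss reaches encoder but never the dense decoder."""
        model = build_model(TINY, seed=3)
        x = _batch(rng)
        t = (rng.random((2, 32, 32)) > 0.5).astype(np.float32)
        oh = np.stack([1 - t, t], axis=1)
        out = model.forward_tensors(nn.Tensor(x))
        focal_tversky_loss(out["breast"], oh).backward()
        assert all(p.grad is not None for p in model.encoder_parameters())
        assert all(p.grad is None for p in model.decoder_parameters("dense"))
        assert any(p.grad is not None for p in model.decoder_parameters("breast"))

    def test_decoder_parameter_independence(self, rng):
        """Zeroing the dense decoder leaves breast probabilities unchanged."""
        model = build_model(TINY, seed=4)
        x = _batch(rng)
        before = model.forward_tensors(nn.Tensor(x))["breast"].data.copy()
        for p in model.decoder_parameters("dense"):
            p.data[...] = 0.0
        after = model.forward_tensors(nn.Tensor(x))["breast"].data
        np.testing.assert_array_equal(before, after)


class TestMDRBlock:
    def test_residual_identity_with_zero_branches(self, rng):
        block = MDRBlock(4, 4, (1, 3), "instance", np.random.default_rng(0))
        for name, p in block.named_parameters():
            if name.endswith((".weight", ".bias")):
                p.data[...] = 0.0
        x = rng.random((1, 4, 16, 16)).astype(np.float32)
        out = block(nn.Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-6)

    @pytest.mark.parametrize("dilations", [(1,), (1, 3), (1, 3, 5)])
    def test_spatial_size_preserved(self, rng, dilations):
        block = MDRBlock(3, 6, dilations, "group", np.random.default_rng(1))
        x = rng.random((1, 3, 20, 20)).astype(np.float32)
        assert block(nn.Tensor(x)).shape == (1, 6, 20, 20)

    @pytest.mark.parametrize("rate", [1, 2, 3, 5])
    def test_dilated_receptive_field_from_impulse(self, rate):
        """A 3x3 kernel at dilation r has impulse support 2r+1 per axis."""
        w = nn.Tensor(np.ones((1, 1, 3, 3)))
        delta = np.zeros((1, 1, 25, 25))
        delta[0, 0, 12, 12] = 1.0
        out = nn.conv2d(nn.Tensor(delta), w, dilation=rate).data[0, 0]
        ys, xs = np.nonzero(out)
        assert ys.max() - ys.min() == 2 * rate
        assert xs.max() - xs.min() == 2 * rate


class TestBottleneck:
    def test_branch_union_support(self):
        """Merged impulse response covers the union of branch supports."""
        from mammodensity.network import Bottleneck
        rngs = np.random.default_rng(0)
        bott = Bottleneck(1, 2, (1, 3, 5), "instance", rngs)
        for name, p in bott.named_parameters():
            if name.endswith(".weight"):
                p.data[...] = 1.0   # all-pass weights
            elif name.endswith((".bias", ".beta")):
                p.data[...] = 0.0
            elif name.endswith(".gamma"):
                p.data[...] = 1.0
        delta = np.zeros((1, 1, 31, 31))
        delta[0, 0, 15, 15] = 1.0
        out = bott(nn.Tensor(delta)).data[0, 0]
        ys, xs = np.nonzero(np.abs(out) > 1e-9)
        assert ys.max() - ys.min() == 10  # widest branch: dilation 5 -> 11 wide
        assert xs.max() - xs.min() == 10

    def test_single_rate_degenerate_config(self, rng):
        model = build_model(NetworkConfig(input_side=32, depth=2, base_width=4,
                                          bottleneck_dilations=(1,)), seed=0)
        out = model.forward_tensors(nn.Tensor(_batch(rng)))
        assert out["breast"].shape == (2, 2, 32, 32)


@pytest.mark.parametrize("norm", ["batch", "instance", "group", "wsgroup"])
def test_norm_layer_variants_build_and_run(rng, norm):
    model = build_model(NetworkConfig(input_side=32, depth=2, base_width=4,
                                      norm_layer=norm), seed=0)
    out = model.forward_tensors(nn.Tensor(_batch(rng, n=2)))
    assert np.all(np.isfinite(out["dense"].data))


def test_checkpoint_round_trip(tmp_path, tiny_model, rng):
    x = _batch(rng)
    before = tiny_model.forward_tensors(nn.Tensor(x))["dense"].data.copy()
    path = save_checkpoint(tiny_model, tmp_path / "m.npz")
    restored = load_checkpoint(path)
    after = restored.forward_tensors(nn.Tensor(x))["dense"].data
    np.testing.assert_array_equal(before, after)
    assert restored.config == tiny_model.config
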