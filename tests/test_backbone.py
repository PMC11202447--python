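"""Residual 3D U-Net: parameter counts, forward contract, gradients."""

import numpy as np
import pytest

from mamlseg.backbone import (BackboneConfig, build_backbone, count_parameters,
                              forward, get_engine, load_checkpoint, prelu,
                              save_checkpoint)


def enumerate_parameters(cfg: BackboneConfig) -> int:
    """Independent per-layer enumeration of the architecture's parameter count.

    Walks the construction rules directly (closed-form per layer) without
    touching the layer tree: each conv unit is k^3*cin*cout weights + cout
    biases, followed by an affine norm (2*cout) and a single-slope PReLU (1)
    unless it is the network's final convolution; residual shortcuts are
    strided 3x3x3 convs, unstrided 1x1x1 projections, or the identity.
    """

    def conv(cin, cout, k):
        return k ** 3 * cin * cout + cout

    def res_unit(cin, cout, stride, subunits, last_conv_only=False):
        n, c = 0, cin
        for i in range(subunits):
            n += conv(c, cout, 3)
            c = cout
            if not (last_conv_only and i == subunits - 1):
                n += 2 * cout + 1  # norm affine + PReLU slope
        if stride != 1 or cin != cout:
            n += conv(cin, cout, 3 if stride != 1 else 1)
        return n

    def up_layer(upc, outc, top):
        n = conv(upc, outc, 3) + 2 * outc + 1  # transpose conv + norm + act
        n += res_unit(outc, outc, 1, 1, last_conv_only=top)
        return n

    def block(cin, cout, channels, strides, top):
        c, s = channels[0], strides[0]
        if len(channels) > 2:
            sub = block(c, c, channels[1:], strides[1:], False)
            upc = c * 2
        else:
            sub = res_unit(c, channels[1], 1, cfg.num_res_units)
            upc = c + channels[1]
        return (res_unit(cin, c, s, cfg.num_res_units) + sub
                + up_layer(upc, cout, top))

    return block(cfg.in_channels, cfg.out_channels, cfg.channels, cfg.strides, True)


class TestParameterCount:
    def test_default_config_reproduces_published_count(self):
        state = build_backbone(BackboneConfig(), rng_seed=0)
        assert count_parameters(state) == 4_808_917

    def test_tiny_config_matches_hand_enumeration(self):
        # channels (4,8), strides (2,), 1 residual subunit, hand-summed:
        # down 112+8+1+112, bottom 872+16+1+40, up 650+4+1, refine 110 = 1927
        cfg = BackboneConfig(channels=(4, 8), strides=(2,), num_res_units=1)
        assert count_parameters(build_backbone(cfg, 0)) == 1927

    @pytest.mark.parametrize("cfg", [
        BackboneConfig(),
        BackboneConfig(channels=(4, 8), strides=(2,), num_res_units=1),
        BackboneConfig(channels=(8, 16, 32), strides=(2, 2), num_res_units=2),
        BackboneConfig(channels=(2, 3, 5, 7), strides=(2, 2, 2), num_res_units=3),
        BackboneConfig(in_channels=2, out_channels=2, channels=(6, 12), strides=(2,)),
    ])
    def test_count_matches_independent_enumeration(self, cfg):
        assert count_parameters(build_backbone(cfg, 0)) == enumerate_parameters(cfg)

    def test_count_invariant_under_seed(self):
        cfg = BackboneConfig(channels=(4, 8), strides=(2,))
        assert count_parameters(build_backbone(cfg, 0)) == \
            count_parameters(build_backbone(cfg, 123))

    def test_mismatched_channels_strides_rejected(self):
        with pytest.raises(ValueError, match="strides"):
            BackboneConfig(channels=(8, 16, 32), strides=(2,))


class TestInitialization:
    def test_same_seed_bitwise_identical(self, tiny_backbone_cfg):
        a = build_backbone(tiny_backbone_cfg, 42)
        b = build_backbone(tiny_backbone_cfg, 42)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_different_seed_differs(self, tiny_backbone_cfg):
        a = build_backbone(tiny_backbone_cfg, 0)
        b = build_backbone(tiny_backbone_cfg, 1)
        assert any((a.params[k] != b.params[k]).any()
                   for k in a.params if a.params[k].size > 2)


class TestForward:
    def test_output_shape_matches_input(self, tiny_backbone_cfg, rng):
        state = build_backbone(tiny_backbone_cfg, 0)
        x = rng.normal(size=(1, 1, 16, 16, 16))
        y = forward(state, x)
        assert y.shape == (1, 2, 16, 16, 16)

    def test_indivisible_extent_names_axis(self, tiny_backbone_cfg, rng):
        state = build_backbone(tiny_backbone_cfg, 0)
        with pytest.raises(ValueError, match="axis H"):
            forward(state, rng.normal(size=(1, 1, 16, 15, 16)))

    def test_eval_mode_deterministic(self, rng):
        cfg = BackboneConfig(channels=(4, 8), strides=(2,), dropout=0.5)
        state = build_backbone(cfg, 0)
        x = rng.normal(size=(1, 1, 8, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(forward(state, x), forward(state, x))

    def test_train_mode_dropout_varies(self, rng):
        cfg = BackboneConfig(channels=(4, 8), strides=(2,), dropout=0.5)
        state = build_backbone(cfg, 0)
        x = rng.normal(size=(1, 1, 8, 8, 8)).astype(np.float32)
        y1 = forward(state, x, train_mode=True, rng=np.random.default_rng(0))
        y2 = forward(state, x, train_mode=True, rng=np.random.default_rng(1))
        assert (y1 != y2).any()

    def test_equal_params_equal_outputs(self, tiny_backbone_cfg, rng):
        a = build_backbone(tiny_backbone_cfg, 7)
        b = build_backbone(tiny_backbone_cfg, 7)
        x = rng.normal(size=(1, 1, 8, 8, 8))
        np.testing.assert_array_equal(forward(a, x), forward(b, x))


class TestPRelu:
    @pytest.mark.parametrize("y,slope,expected", [
        (3.0, 0.9, 3.0),       # positive branch: identity
        (-2.0, 0.25, -0.5),    # negative branch: slope * y
        (0.0, 0.7, 0.0),       # continuity at zero
    ])
    def test_pointwise_values(self, y, slope, expected):
        assert prelu(y, slope) == pytest.approx(expected)

    def test_slope_one_is_identity(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(prelu(x, 1.0), x)


class TestBackward:
    def test_full_network_gradient_matches_finite_differences(self, tiny_backbone_cfg, rng):
        """Reverse-mode gradients of a scalar functional of the logits agree
        with central finite differences for every layer type in the net."""
        state = build_backbone(tiny_backbone_cfg, 1)
        eng = get_engine(tiny_backbone_cfg)
        x = rng.normal(size=(1, 1, 8, 8, 8))
        R = rng.normal(size=(1, 2, 8, 8, 8))

        def loss(params):
            return float((eng.forward(params, x) * R).sum())

        eng.forward(state.params, x)
        grads = eng.backward(R)
        for k, v in state.params.items():
            for _ in range(2):
                idx = tuple(rng.integers(0, s) for s in v.shape)
                h = 1e-6 * (1 + abs(v[idx]))
                p = {kk: vv.copy() for kk, vv in state.params.items()}
                p[k][idx] += h
                lp = loss(p)
                p[k][idx] -= 2 * h
                lm = loss(p)
                fd = (lp - lm) / (2 * h)
                assert abs(fd - grads[k][idx]) <= 1e-4 + 1e-4 * (abs(fd) + abs(grads[k][idx])), k


class TestCheckpoint:
    def test_roundtrip(self, tiny_backbone_cfg, tmp_path):
        state = build_backbone(tiny_backbone_cfg, 3)
        save_checkpoint(state, tmp_path / "ck.npz")
        back = load_checkpoint(tmp_path / "ck.npz")
        assert back.config == tiny_backbone_cfg
        assert list(back.params) == list(state.params)
        for k in state.params:
            np.testing.assert_array_equal(back.params[k], state.params[k])

    def test_config_mismatch_rejected(self, tiny_backbone_cfg, tmp_path):
        state = build_backbone(tiny_backbone_cfg, 3)
        save_checkpoint(state, tmp_path / "ck.npz")
        other = BackboneConfig(channels=(8, 16), strides=(2,))
        with pytest.raises(ValueError, match="does not.*match|match the requested"):
            load_checkpoint(tmp_path / "ck.npz", expect_config=other)
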