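"""Difference convolutions, FCA attention, group norm, shared head, decoding."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from peonyqc.blocks import (
    DIFFERENCE_KINDS,
    FCAParams,
    HeadParams,
    KernelBank,
    conv2d,
    deconv_forward,
    dfl_decode,
    fca_apply,
    fca_weights,
    gap,
    group_norm,
    head_param_count,
    load_head_weights,
    lsd_head_forward,
    merge_kernels,
    nms,
    save_head_weights,
    transform_kernel,
)
from peonyqc.synthetic import random_feature_map

_AD_PERM = np.array([3, 0, 1, 6, 4, 2, 7, 8, 5])


def _conv_same(x2d, k2d):
    """Independent same-padding cross-correlation oracle (scipy)."""
    return correlate2d(x2d, k2d, mode="same", boundary="fill")


def _difference_form(kind, x2d, w):
    """Direct evaluation of each branch's difference definition."""
    if kind == "vanilla":
        return _conv_same(x2d, w)
    if kind == "center":
        return _conv_same(x2d, w) - w.sum() * x2d
    if kind == "horizontal":
        return _conv_same(x2d, w) - _conv_same(x2d, w[:, ::-1])
    if kind == "vertical":
        return _conv_same(x2d, w) - _conv_same(x2d, w[::-1, :])
    if kind == "adaptive":
        return _conv_same(x2d, w) - _conv_same(x2d, w.flatten()[_AD_PERM].reshape(3, 3))
    raise AssertionError(kind)


class TestTransformKernel:
    def test_vanilla_is_identity(self, rng):
        w = rng.standard_normal((3, 3))
        assert np.array_equal(transform_kernel("vanilla", w), w)

    def test_center_difference_on_ones(self):
        out = transform_kernel("center", np.ones((3, 3)))
        expected = np.ones((3, 3))
        expected[1, 1] = 1.0 - 9.0
        assert np.array_equal(out, expected)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            transform_kernel("sideways", np.ones((3, 3)))

    @pytest.mark.parametrize("kind", DIFFERENCE_KINDS)
    def test_transformed_kernel_equals_difference_form(self, kind, rng):
        w = rng.standard_normal((3, 3))
        x = rng.standard_normal((16, 16))
        via_kernel = _conv_same(x, transform_kernel(kind, w))
        direct = _difference_form(kind, x, w)
        scale = np.abs(direct).max() + 1e-12
        assert np.abs(via_kernel - direct).max() / scale < 1e-6


class TestMergeKernels:
    def test_five_zero_kernels_merge_to_zero(self):
        bank = KernelBank({k: np.zeros((2, 2, 3, 3)) for k in DIFFERENCE_KINDS})
        assert not merge_kernels(bank).any()

    def test_single_vanilla_kernel_survives(self, rng):
        w = rng.standard_normal((2, 2, 3, 3))
        weights = {k: np.zeros((2, 2, 3, 3)) for k in DIFFERENCE_KINDS}
        weights["vanilla"] = w
        assert np.allclose(merge_kernels(KernelBank(weights)), w)

    def test_shape_mismatch_rejected(self):
        weights = {k: np.zeros((2, 2, 3, 3)) for k in DIFFERENCE_KINDS}
        weights["center"] = np.zeros((2, 2, 5, 5))
        with pytest.raises(ValueError):
            KernelBank(weights)

    def test_merged_convolution_equals_branch_sum(self):
        # the reparameterization claim, against the scipy oracle
        bank = KernelBank.random(0, 2, 4, 3, scale=1.0)
        x = random_feature_map(1, 1, 4, 16, 16)
        merged = merge_kernels(bank)
        via_merged = conv2d(x, merged)
        t = bank.transformed()
        branch_sum = np.zeros_like(via_merged)
        for kind in DIFFERENCE_KINDS:
            for o in range(2):
                for c in range(4):
                    branch_sum[0, o] += _conv_same(x[0, c], t[kind][o, c])
        scale = np.abs(branch_sum).max()
        assert np.abs(via_merged - branch_sum).max() / scale < 1e-5


class TestDeconvForward:
    def test_zero_input_zero_output(self):
        bank = KernelBank.random(3, 2, 2)
        x = np.zeros((1, 2, 8, 8))
        assert not deconv_forward(x, bank, "parallel").any()
        assert not deconv_forward(x, bank, "merged").any()

    def test_modes_agree(self):
        bank = KernelBank.random(5, 3, 3)
        x = random_feature_map(6, 2, 3, 12, 12)
        a = deconv_forward(x, bank, "merged")
        b = deconv_forward(x, bank, "parallel")
        assert np.abs(a - b).max() < 1e-5 * max(np.abs(a).max(), 1.0)

    def test_linearity_in_kernel_weights(self):
        bank = KernelBank.random(7, 2, 2)
        doubled = KernelBank({k: 2 * v for k, v in bank.weights.items()})
        x = random_feature_map(8, 1, 2, 10, 10)
        assert np.allclose(deconv_forward(x, doubled), 2 * deconv_forward(x, bank))

    def test_spatial_size_preserved(self):
        bank = KernelBank.random(9, 4, 3)
        x = random_feature_map(10, 2, 3, 11, 17)
        assert deconv_forward(x, bank).shape == (2, 4, 11, 17)


class TestGap:
    def test_constant_channel(self):
        x = np.full((1, 3, 4, 4), 7.0)
        assert np.allclose(gap(x), 7.0)

    def test_small_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 2, 2)
        assert gap(x)[0, 0] == pytest.approx(2.5)

    def test_matches_loop_oracle(self):
        x = random_feature_map(11, 2, 3, 5, 7)
        expected = np.empty((2, 3))
        for n in range(2):
            for c in range(3):
                acc = 0.0
                for i in range(5):
                    for j in range(7):
                        acc += x[n, c, i, j]
                expected[n, c] = acc / 35
        assert np.abs(gap(x) - expected).max() < 1e-9


class TestFCA:
    def test_identical_channels_give_equal_weights(self):
        x = np.tile(random_feature_map(12, 2, 1, 6, 6), (1, 8, 1, 1))
        p = FCAParams(b=np.array([0.2, 0.6, 0.2]), d=np.full(8, 1.3), theta=0.4)
        w = fca_weights(x, p).w
        assert np.allclose(w, w[:, :1])

    def test_weights_strictly_in_unit_interval(self):
        for seed in range(5):
            x = random_feature_map(seed, 2, 16, 4, 4) * 10
            p = FCAParams.random(seed + 100, 16)
            w = fca_weights(x, p).w
            assert np.all(w > 0) and np.all(w < 1)

    def test_theta_limit_reduces_to_global_branch(self):
        x = random_feature_map(13, 1, 8, 5, 5)
        p = FCAParams.random(14, 8)
        big = FCAParams(b=p.b, d=p.d, theta=30.0)
        cw = fca_weights(x, big)
        limit = 1 / (1 + np.exp(-(1 / (1 + np.exp(-cw.Uwgc)))))
        assert np.abs(cw.w - limit).max() < 1e-6

    def test_balanced_theta_is_exact_midpoint(self):
        x = random_feature_map(15, 1, 8, 5, 5)
        p = FCAParams.random(16, 8)
        mid = FCAParams(b=p.b, d=p.d, theta=0.0)  # sigma(0) = 0.5
        cw = fca_weights(x, mid)
        sg = 1 / (1 + np.exp(-cw.Uwgc))
        sl = 1 / (1 + np.exp(-cw.Uwlc))
        expected = 1 / (1 + np.exp(-(0.5 * sg + 0.5 * sl)))
        assert np.allclose(cw.w, expected)

    def test_channel_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fca_weights(random_feature_map(0, 1, 4, 3, 3), FCAParams.random(0, 8))

    def test_apply_scales_channels(self):
        x = random_feature_map(17, 1, 4, 6, 6) + 3.0
        w = np.array([[0.5, 1.0, 0.25, 0.75]])
        out = fca_apply(x, w)
        assert out.shape == x.shape
        ratio = out / x
        for c in range(4):
            assert np.allclose(ratio[0, c], w[0, c])

    def test_apply_zero_input_zero_output(self):
        out = fca_apply(np.zeros((1, 4, 3, 3)), np.full((1, 4), 0.5))
        assert not out.any()


class TestGroupNorm:
    def test_constant_input_maps_to_zero(self):
        out = group_norm(np.full((2, 8, 3, 3), 4.2), groups=4)
        assert np.abs(out).max() < 1e-3

    def test_per_group_moments(self):
        x = random_feature_map(18, 2, 8, 6, 6) * 3 + 1
        out = group_norm(x, groups=4).reshape(2, 4, 2, 6, 6)
        mu = out.mean(axis=(2, 3, 4))
        var = out.var(axis=(2, 3, 4))
        assert np.abs(mu).max() < 1e-6
        assert np.abs(var - 1).max() < 1e-4

    def test_single_group_is_layer_norm(self):
        x = random_feature_map(19, 1, 6, 4, 4)
        out = group_norm(x, groups=1)
        flat = x.reshape(1, -1)
        expected = (flat - flat.mean()) / np.sqrt(flat.var() + 1e-5)
        assert np.allclose(out.reshape(1, -1), expected)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError):
            group_norm(np.zeros((1, 6, 2, 2)), groups=4)


class TestLsdHead:
    @pytest.fixture()
    def head(self):
        return HeadParams.init(0, in_channels=(8, 8, 16), hidden=8,
                               nc=3, reg_max=4, gn_groups=2)

    def test_output_shapes_match_inputs(self, head):
        levels = [
            random_feature_map(20, 2, 8, 16, 16),
            random_feature_map(21, 2, 8, 8, 8),
            random_feature_map(22, 2, 16, 4, 4),
        ]
        out = lsd_head_forward(levels, head)
        for x, c, r in zip(levels, out.cls_logits, out.reg_logits):
            assert c.shape == (2, 3, *x.shape[2:])
            assert r.shape == (2, 16, *x.shape[2:])

    def test_weight_sharing_swaps_outputs(self, head):
        # levels 0 and 1 share channels and spatial dims and the head weights
        # are identical objects, so swapping inputs swaps outputs exactly
        # (up to the per-level scale, which is 1 at init)
        a = random_feature_map(23, 1, 8, 8, 8)
        b = random_feature_map(24, 1, 8, 8, 8)
        c = random_feature_map(25, 1, 16, 4, 4)
        head.reduce_w[1] = head.reduce_w[0]
        head.reduce_b[1] = head.reduce_b[0]
        o1 = lsd_head_forward([a, b, c], head)
        o2 = lsd_head_forward([b, a, c], head)
        assert np.array_equal(o1.cls_logits[0], o2.cls_logits[1])
        assert np.array_equal(o1.reg_logits[1], o2.reg_logits[0])

    def test_zero_scale_zeroes_regression_only(self, head):
        levels = [
            random_feature_map(26, 1, 8, 8, 8),
            random_feature_map(27, 1, 8, 4, 4),
            random_feature_map(28, 1, 16, 2, 2),
        ]
        ref = lsd_head_forward(levels, head)
        head.level_scales[1] = 0.0
        out = lsd_head_forward(levels, head)
        assert not out.reg_logits[1].any()
        assert np.array_equal(out.cls_logits[1], ref.cls_logits[1])

    def test_wrong_level_count_rejected(self, head):
        with pytest.raises(ValueError):
            lsd_head_forward([random_feature_map(0, 1, 8, 8, 8)], head)

    def test_shared_head_has_fewer_parameters(self, head):
        assert head_param_count(head, shared=True) < head_param_count(head, shared=False)

    def test_weight_archive_roundtrip(self, head, tmp_path):
        path = tmp_path / "head.npz"
        save_head_weights(head, path)
        loaded = load_head_weights(path)
        levels = [
            random_feature_map(29, 1, 8, 8, 8),
            random_feature_map(30, 1, 8, 4, 4),
            random_feature_map(31, 1, 16, 2, 2),
        ]
        a = lsd_head_forward(levels, head)
        b = lsd_head_forward(levels, loaded)
        for x, y in zip(a.cls_logits + a.reg_logits, b.cls_logits + b.reg_logits):
            assert np.array_equal(x, y)


class TestDflDecode:
    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dfl_decode(np.zeros((1, 16, 1, 1)), reg_max=5, stride=8)

    def test_one_hot_left_distance(self):
        logits = np.full((1, 16, 1, 1), -20.0)
        logits[0, 0 * 4 + 1] = 20.0  # left distance = bin 1 -> x1 = (0.5 - 1) * 8
        boxes = dfl_decode(logits, reg_max=4, stride=8)
        assert boxes[0, 0, 0, 0] == pytest.approx((0.5 - 1.0) * 8.0, abs=1e-6)

    def test_point_mass_side_distance(self):
        reg_max = 16
        logits = np.full((1, 4 * reg_max, 1, 1), -30.0)
        logits[0, 2 * reg_max + 5] = 30.0  # right side, bin 5
        boxes = dfl_decode(logits, reg_max=reg_max, stride=8)
        x2 = boxes[0, 0, 0, 2]
        assert x2 - 0.5 * 8 == pytest.approx(40.0, abs=1e-4)  # 5 bins * stride 8

    def test_uniform_distribution_gives_mean_bin(self):
        reg_max = 16
        boxes = dfl_decode(np.zeros((1, 64, 2, 2)), reg_max=reg_max, stride=4)
        x1 = boxes[0, 0, 0, 0]
        assert 0.5 * 4 - x1 == pytest.approx(7.5 * 4)  # mean of 0..15

    def test_monotone_in_higher_bins(self):
        reg_max = 8
        rng = np.random.default_rng(3)
        logits = rng.standard_normal((1, 32, 1, 1))
        base = dfl_decode(logits, reg_max, stride=1)[0, 0, 0, 2]
        for bump in np.linspace(0.5, 5, 8):
            boosted = logits.copy()
            boosted[0, 2 * reg_max + reg_max - 1] += bump  # raise top bin of right side
            out = dfl_decode(boosted, reg_max, stride=1)[0, 0, 0, 2]
            assert out >= base
            base = out

    def test_box_ordering_after_clamp(self):
        rng = np.random.default_rng(4)
        boxes = dfl_decode(rng.standard_normal((1, 64, 4, 4)), 16, 8, img_size=(32, 32))
        assert np.all(boxes[..., 2] >= boxes[..., 0])
        assert np.all(boxes[..., 3] >= boxes[..., 1])


def test_nms_suppresses_overlapping_boxes():
    boxes = np.array([
        [0, 0, 10, 10],
        [1, 1, 11, 11],   # IoU with first ~0.68 -> suppressed
        [20, 20, 30, 30],
    ], dtype=float)
    keep = nms(boxes, np.array([0.9, 0.8, 0.7]), iou_thr=0.45)
    assert list(keep) == [0, 2]
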