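"""Grayscale, blur, Canny edge extraction and contour geometry."""

import numpy as np
import pytest

from peonyqc.edges import (
    EdgeParams,
    contour_geometry,
    edge_map,
    find_contours,
    gaussian_blur,
    min_area_rect,
    to_grayscale,
)


class TestGrayscale:
    def test_gray_input_is_fixed_point(self):
        img = np.full((5, 5, 3), 93, dtype=np.uint8)
        assert np.all(to_grayscale(img) == 93)

    def test_white_maps_to_255(self):
        assert to_grayscale(np.full((2, 2, 3), 255, dtype=np.uint8)).max() == 255

    def test_pure_red_maps_to_76(self):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[..., 0] = 255
        assert to_grayscale(img)[0, 0] == 76  # round(0.299 * 255)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4), dtype=np.uint8))


class TestGaussianBlur:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 130.0)
        assert gaussian_blur(img) == pytest.approx(img)

    def test_impulse_center_equals_kernel_center_weight(self):
        img = np.zeros((11, 11))
        img[5, 5] = 1.0
        p = EdgeParams(blur_kernel=3, blur_sigma=1.0)
        out = gaussian_blur(img, p)
        k = np.exp(-0.5 * np.array([-1.0, 0.0, 1.0]) ** 2)
        k /= k.sum()
        assert out[5, 5] == pytest.approx(k[1] ** 2)

    def test_total_intensity_preserved(self, rng):
        img = rng.uniform(0, 255, (40, 55))
        out = gaussian_blur(img, EdgeParams(blur_kernel=7, blur_sigma=1.5))
        assert out.sum() == pytest.approx(img.sum(), rel=1e-6)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            EdgeParams(blur_kernel=4)


class TestEdgeMap:
    def test_constant_image_gives_empty_mask(self):
        assert not edge_map(np.full((30, 30), 99.0)).any()

    def test_step_edge_thins_to_single_column(self):
        img = np.zeros((20, 40))
        img[:, 20:] = 120.0
        mask = edge_map(img, EdgeParams(t_low=20, t_high=50))
        cols = np.nonzero(mask[10])[0]
        assert len(cols) == 1  # NMS thins the plateau to one pixel
        assert abs(cols[0] - 19.5) <= 1.0
        # every row has exactly that one edge pixel
        assert np.all(mask.sum(axis=1) == 1)

    def test_disk_edge_lies_on_the_circle(self):
        h = w = 140
        rr, cc = np.mgrid[0:h, 0:w]
        dist = np.hypot(rr - 70, cc - 70)
        img = np.where(dist <= 50, 200.0, 20.0)
        img = gaussian_blur(img)
        mask = edge_map(img)
        r, c = np.nonzero(mask)
        d = np.hypot(r - 70, c - 70)
        assert len(d) > 0
        assert np.all(np.abs(d - 50) <= 1.5)
        # the ring closes: every 6-degree sector contains edge pixels
        ang = np.degrees(np.arctan2(r - 70.0, c - 70.0)) % 360
        assert len(np.unique((ang // 6).astype(int))) == 60

    def test_invariant_to_constant_intensity_shift(self):
        img = np.zeros((20, 40))
        img[:, 20:] = 120.0
        assert np.array_equal(edge_map(img), edge_map(img + 77.0))

    def test_inverted_threshold_order_rejected(self):
        with pytest.raises(ValueError):
            EdgeParams(t_low=150, t_high=50)

    def test_agrees_with_reference_canny_on_a_disk(self):
        # independent cross-check: edge sets from an established Canny lie
        # within 2 px of ours on a smooth high-contrast disk
        from skimage import feature

        h = w = 120
        rr, cc = np.mgrid[0:h, 0:w]
        img = np.where(np.hypot(rr - 60, cc - 60) <= 40, 200.0, 20.0)
        ours = edge_map(gaussian_blur(img))
        ref = feature.canny(img, sigma=1.0)
        ro, co = np.nonzero(ours)
        rr2, cc2 = np.nonzero(ref)
        for r, c in zip(ro[::7], co[::7]):
            assert np.min(np.hypot(rr2 - r, cc2 - c)) <= 2.0


class TestFindContours:
    def test_empty_mask_gives_empty_list(self):
        assert find_contours(np.zeros((10, 10), dtype=bool)) == []

    def test_rectangle_outline_traced_with_correct_bbox(self):
        mask = np.zeros((80, 120), dtype=bool)
        mask[10, 10:110] = mask[69, 10:110] = True
        mask[10:70, 10] = mask[10:70, 109] = True
        contours = find_contours(mask)
        assert len(contours) == 1
        _, (bw, bh), _ = contour_geometry(contours[0])
        assert bw == pytest.approx(100, abs=1)
        assert bh == pytest.approx(60, abs=1)

    def test_two_disjoint_disks_give_two_contours(self):
        rr, cc = np.mgrid[0:80, 0:160]
        mask = (np.hypot(rr - 40, cc - 40) <= 20) | (np.hypot(rr - 40, cc - 120) <= 15)
        contours = find_contours(mask)
        assert len(contours) == 2
        # ordered by descending area
        a0 = contour_geometry(contours[0])[0]
        a1 = contour_geometry(contours[1])[0]
        assert a0 > a1


def _rect_points(w, h, angle_deg, n=400):
    t = np.linspace(0, 1, n // 4, endpoint=False)
    edges = [
        np.stack([np.full_like(t, -h / 2), -w / 2 + w * t], axis=1),
        np.stack([-h / 2 + h * t, np.full_like(t, w / 2)], axis=1),
        np.stack([np.full_like(t, h / 2), w / 2 - w * t], axis=1),
        np.stack([h / 2 - h * t, np.full_like(t, -w / 2)], axis=1),
    ]
    pts = np.concatenate(edges)
    th = np.radians(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return pts @ rot.T + 200.0


class TestContourGeometry:
    def test_unit_square(self):
        sq = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]])
        area, bbox, _ = contour_geometry(sq)
        assert area == pytest.approx(1.0)
        assert bbox == pytest.approx((1.0, 1.0))

    def test_rotated_rectangle_min_rect_vs_bbox(self):
        pts = _rect_points(40, 20, 30)
        area, (bw, bh), (long_px, short_px, _) = contour_geometry(pts)
        assert long_px == pytest.approx(40, abs=1)
        assert short_px == pytest.approx(20, abs=1)
        assert bw > 40 and bh > 20  # axis-aligned box overestimates

    @pytest.mark.parametrize("angle", [0, 13, 45, 77, 121, 160])
    def test_min_rect_rotation_invariant(self, angle):
        long_px, short_px, _ = min_area_rect(_rect_points(40, 20, angle))
        assert long_px == pytest.approx(40, abs=1)
        assert short_px == pytest.approx(20, abs=1)

    def test_min_rect_contains_the_area(self, rng):
        for _ in range(10):
            pts = rng.uniform(0, 100, (30, 2))
            hullish = pts[np.argsort(np.arctan2(*(pts - pts.mean(0)).T))]
            area, _, (long_px, short_px, _) = contour_geometry(hullish)
            assert long_px * short_px >= area - 1e-9

    def test_degenerate_contour_rejected(self):
        with pytest.raises(ValueError):
            contour_geometry(np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValueError):
            contour_geometry(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))
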