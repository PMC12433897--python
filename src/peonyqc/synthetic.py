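"""Deterministic synthetic scenes and tensors with exact ground truth.

No public image corpus of white-peony decoction slices exists, so the
measurement pipeline is exercised on rendered stand-in scenes that emulate
the acquisition setup: a uniform dark (or green) backplate photographed from
a fixed distance, bright quasi-elliptical slices 10-30 mm across, and one
rectangular calibration card of known physical size (26 x 38 mm).  The
renderer knows the exact pixels-per-mm scale, so every scene ships with a
ground-truth table of physical dimensions.

Shapes are drawn with a soft 1-px anti-aliasing ramp so sub-pixel
measurement error behaves like a real photograph rather than a staircase
raster, and sensor noise is additive Gaussian, clipped to [0, 255].  The
card is rendered at an intensity distinct from the slices, so the pipeline
must identify it by aspect ratio — the mechanism under test — not by
brightness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "EllipseSpec",
    "SceneSpec",
    "CARD_SIZE_MM",
    "render_scene",
    "random_scene",
    "random_feature_map",
    "write_scene",
]

#: Physical size of the reference card, mm (short side, long side).
CARD_SIZE_MM = (26.0, 38.0)

_TRUTH_COLUMNS = ["object_id", "long_mm", "short_mm", "area_mm2", "card_flag"]


@dataclass(frozen=True)
class EllipseSpec:
    """One elliptical slice: center in mm, full axis lengths in mm, rotation."""

    center_mm: tuple[float, float]  # (x, y) = (col, row) in mm
    long_axis_mm: float
    short_axis_mm: float
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (self.long_axis_mm >= self.short_axis_mm > 0):
            raise ValueError("need long_axis_mm >= short_axis_mm > 0")
        if not (5.0 <= self.short_axis_mm and self.long_axis_mm <= 40.0):
            raise ValueError("axes must lie within 5-40 mm")

    @property
    def area_mm2(self) -> float:
        return math.pi * (self.long_axis_mm / 2) * (self.short_axis_mm / 2)


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a rendered measurement scene.

    ppm is the true pixels-per-mm scale; background/foreground/card levels
    are 8-bit intensities (foreground - background >= 60 guarantees edges
    detectable by the default thresholds); noise_sigma is the Gaussian
    sensor-noise standard deviation in intensity units.
    """

    ppm: float
    slices: tuple[EllipseSpec, ...] = ()
    card_size_mm: tuple[float, float] = CARD_SIZE_MM
    card_center_mm: tuple[float, float] | None = None  # default: image center
    card_angle_deg: float = 0.0
    background_level: int = 20
    foreground_level: int = 200
    card_level: int = 150
    noise_sigma: float = 3.0
    seed: int = 0
    image_size_px: tuple[int, int] = (640, 640)  # (H, W)

    def __post_init__(self) -> None:
        if self.ppm <= 0:
            raise ValueError("ppm must be positive")
        if min(self.foreground_level, self.card_level) - self.background_level < 60:
            raise ValueError(
                "foreground/card levels must exceed background by >= 60"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def resolved_card_center_mm(self) -> tuple[float, float]:
        if self.card_center_mm is not None:
            return self.card_center_mm
        h, w = self.image_size_px
        return (w / (2 * self.ppm), h / (2 * self.ppm))


def _rect_coverage(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    size_px: tuple[float, float],
    angle_deg: float,
) -> np.ndarray:
    """Anti-aliased coverage of a rotated rectangle (signed-distance ramp)."""
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    x = cols - center_px[0]
    y = rows - center_px[1]
    th = math.radians(angle_deg)
    xr = x * math.cos(th) + y * math.sin(th)
    yr = -x * math.sin(th) + y * math.cos(th)
    dx = np.abs(xr) - size_px[0] / 2
    dy = np.abs(yr) - size_px[1] / 2
    outside = np.hypot(np.maximum(dx, 0), np.maximum(dy, 0))
    inside = np.minimum(np.maximum(dx, dy), 0)
    dist = outside + inside
    return np.clip(0.5 - dist, 0.0, 1.0)


def _ellipse_coverage(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    semi_axes_px: tuple[float, float],
    angle_deg: float,
) -> np.ndarray:
    """Anti-aliased coverage of a rotated ellipse.

    The implicit value (x/a)^2 + (y/b)^2 - 1 is converted to an approximate
    signed distance by first-order normalisation with its gradient norm,
    which is accurate near the boundary where the 1-px ramp lives.
    """
    h, w = shape
    a, b = semi_axes_px
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    x = cols - center_px[0]
    y = rows - center_px[1]
    th = math.radians(angle_deg)
    xr = x * math.cos(th) + y * math.sin(th)
    yr = -x * math.sin(th) + y * math.cos(th)
    f = (xr / a) ** 2 + (yr / b) ** 2 - 1.0
    grad = 2.0 * np.hypot(xr / a**2, yr / b**2)
    dist = f / np.maximum(grad, 1e-12)
    return np.clip(0.5 - dist, 0.0, 1.0)


def _shape_bounds_px(spec: SceneSpec) -> list[tuple[str, float, float, float, float]]:
    """Axis-aligned (xmin, xmax, ymin, ymax) bounds in px for every shape."""
    bounds = []
    cw, ch = spec.card_size_mm
    cx, cy = spec.resolved_card_center_mm()
    th = math.radians(spec.card_angle_deg)
    hx = (abs(cw * math.cos(th)) + abs(ch * math.sin(th))) / 2 * spec.ppm
    hy = (abs(cw * math.sin(th)) + abs(ch * math.cos(th))) / 2 * spec.ppm
    bounds.append(("card", cx * spec.ppm - hx, cx * spec.ppm + hx,
                   cy * spec.ppm - hy, cy * spec.ppm + hy))
    for i, e in enumerate(spec.slices):
        a = e.long_axis_mm / 2 * spec.ppm
        b = e.short_axis_mm / 2 * spec.ppm
        th = math.radians(e.angle_deg)
        hx = math.hypot(a * math.cos(th), b * math.sin(th))
        hy = math.hypot(a * math.sin(th), b * math.cos(th))
        x, y = e.center_mm[0] * spec.ppm, e.center_mm[1] * spec.ppm
        bounds.append((f"slice_{i}", x - hx, x + hx, y - hy, y + hy))
    return bounds


def _validate_layout(spec: SceneSpec) -> None:
    h, w = spec.image_size_px
    margin = 3.0  # px clearance so rendered edges close inside the frame
    bounds = _shape_bounds_px(spec)
    for name, x0, x1, y0, y1 in bounds:
        if x0 < margin or y0 < margin or x1 > w - margin or y1 > h - margin:
            raise ValueError(f"shape {name!r} extends outside the image")
    # pairwise separation via circumscribed circles (conservative but exact
    # for the layouts random_scene produces, which keep a 2-mm circle gap)
    circles: list[tuple[str, float, float, float]] = []
    cw, ch = spec.card_size_mm
    ccx, ccy = spec.resolved_card_center_mm()
    circles.append(("card", ccx * spec.ppm, ccy * spec.ppm,
                    math.hypot(cw, ch) / 2 * spec.ppm))
    for i, e in enumerate(spec.slices):
        circles.append((f"slice_{i}", e.center_mm[0] * spec.ppm,
                        e.center_mm[1] * spec.ppm, e.long_axis_mm / 2 * spec.ppm))
    for i in range(len(circles)):
        for j in range(i + 1, len(circles)):
            na, xa, ya, ra = circles[i]
            nb, xb, yb, rb = circles[j]
            if math.hypot(xa - xb, ya - yb) < ra + rb:
                raise ValueError(f"shape {na!r} overlaps shape {nb!r}")


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a scene to an RGB uint8 image plus its ground-truth table.

    The truth table has columns object_id, long_mm, short_mm, area_mm2,
    card_flag (one row per rendered shape, card first) and additionally
    carries center_x_px / center_y_px columns so measured contours can be
    matched back to the shape that produced them.  Rendering is bit-identical
    for identical specs (the noise stream is seeded by ``spec.seed``).
    """
    _validate_layout(spec)
    h, w = spec.image_size_px
    img = np.full((h, w), float(spec.background_level))

    rows = []
    cw, ch = spec.card_size_mm
    ccx, ccy = spec.resolved_card_center_mm()
    cov = _rect_coverage(
        (h, w),
        (ccx * spec.ppm, ccy * spec.ppm),
        (cw * spec.ppm, ch * spec.ppm),
        spec.card_angle_deg,
    )
    img = img * (1 - cov) + spec.card_level * cov
    rows.append(
        dict(object_id=0, long_mm=max(cw, ch), short_mm=min(cw, ch),
             area_mm2=cw * ch, card_flag=True,
             center_x_px=ccx * spec.ppm, center_y_px=ccy * spec.ppm)
    )
    for i, e in enumerate(spec.slices, start=1):
        cov = _ellipse_coverage(
            (h, w),
            (e.center_mm[0] * spec.ppm, e.center_mm[1] * spec.ppm),
            (e.long_axis_mm / 2 * spec.ppm, e.short_axis_mm / 2 * spec.ppm),
            e.angle_deg,
        )
        img = img * (1 - cov) + spec.foreground_level * cov
        rows.append(
            dict(object_id=i, long_mm=e.long_axis_mm, short_mm=e.short_axis_mm,
                 area_mm2=e.area_mm2, card_flag=False,
                 center_x_px=e.center_mm[0] * spec.ppm,
                 center_y_px=e.center_mm[1] * spec.ppm)
        )

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    rgb = np.repeat(img[:, :, None], 3, axis=2)
    truth = pd.DataFrame(rows)
    return rgb, truth


def random_scene(
    seed: int,
    n_slices: int | None = None,
    ppm_range: tuple[float, float] = (10.0, 14.0),
    axis_range_mm: tuple[float, float] = (10.0, 30.0),
    noise_sigma: float = 3.0,
    image_size_px: tuple[int, int] = (1280, 1600),
    max_tries: int = 4000,
) -> SceneSpec:
    """Draw a valid random SceneSpec: 3-6 non-overlapping ellipses plus card.

    Placement is rejection-sampled on bounding circles so rendered shapes
    never merge; everything is a pure function of ``seed``.
    """
    rng = np.random.default_rng(seed)
    if n_slices is None:
        n_slices = int(rng.integers(3, 7))
    ppm = float(rng.uniform(*ppm_range))
    h, w = image_size_px
    w_mm, h_mm = w / ppm, h / ppm

    placed: list[tuple[float, float, float]] = []  # (x, y, radius_mm)
    card_r = math.hypot(*CARD_SIZE_MM) / 2
    gap = 2.0  # mm clearance between bounding circles

    def try_place(radius_mm: float) -> tuple[float, float] | None:
        for _ in range(max_tries):
            x = rng.uniform(radius_mm + 1.5, w_mm - radius_mm - 1.5)
            y = rng.uniform(radius_mm + 1.5, h_mm - radius_mm - 1.5)
            if all(math.hypot(x - px, y - py) > radius_mm + pr + gap
                   for px, py, pr in placed):
                return x, y
        return None

    card_xy = try_place(card_r)
    if card_xy is None:
        raise RuntimeError("could not place the reference card")
    placed.append((*card_xy, card_r))
    card_angle = float(rng.uniform(0, 180))

    slices = []
    for _ in range(n_slices):
        for _ in range(max_tries):
            long_ax = float(rng.uniform(*axis_range_mm))
            short_ax = float(rng.uniform(axis_range_mm[0], long_ax))
            xy = try_place(long_ax / 2)
            if xy is not None:
                placed.append((*xy, long_ax / 2))
                slices.append(
                    EllipseSpec(center_mm=xy, long_axis_mm=long_ax,
                                short_axis_mm=short_ax,
                                angle_deg=float(rng.uniform(0, 180)))
                )
                break
        else:
            raise RuntimeError("could not place a slice without overlap")

    return SceneSpec(
        ppm=ppm,
        slices=tuple(slices),
        card_center_mm=card_xy,
        card_angle_deg=card_angle,
        noise_sigma=noise_sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
        image_size_px=image_size_px,
    )


def random_feature_map(
    seed: int,
    n: int,
    c: int,
    h: int,
    w: int,
    distribution: str = "normal",
    value: float = 0.0,
) -> np.ndarray:
    """Seeded random N x C x H x W tensor for exercising the neural blocks.

    distribution: "normal" (standard normal), "uniform" (on [0, 1)), or
    "constant" (every element equal to ``value``).
    """
    for name, d in zip("nchw", (n, c, h, w)):
        if d <= 0:
            raise ValueError(f"dimension {name} must be positive, got {d}")
    rng = np.random.default_rng(seed)
    shape = (n, c, h, w)
    if distribution == "normal":
        return rng.standard_normal(shape)
    if distribution == "uniform":
        return rng.random(shape)
    if distribution == "constant":
        return np.full(shape, float(value))
    raise ValueError(f"unknown distribution {distribution!r}")


def write_scene(spec: SceneSpec, out_dir: str | Path, stem: str = "scene") -> tuple[Path, Path]:
    """Render a scene and write ``<stem>.png`` plus ``<stem>_truth.csv``.

    The CSV has the header object_id,long_mm,short_mm,area_mm2,card_flag.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img, truth = render_scene(spec)
    png = out / f"{stem}.png"
    csv = out / f"{stem}_truth.csv"
    Image.fromarray(img).save(png)
    truth[_TRUTH_COLUMNS].to_csv(csv, index=False)
    return png, csv
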