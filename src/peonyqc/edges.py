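"""Low-level image operations: grayscale, Gaussian denoising, Canny edges, contours.

The measurement pipeline reduces an RGB photograph of herbal slices to closed
object contours in four steps: luminance conversion, Gaussian blur, gradient
edge extraction (Sobel magnitude, directional non-maximum suppression,
dual-threshold hysteresis), and contour tracing of the closed regions the
edges bound.  All coordinates are (row, col), 0-based, with pixel centers at
integer coordinates; bounding-box width runs along columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure as skmeasure

__all__ = [
    "EdgeParams",
    "to_grayscale",
    "gaussian_blur",
    "edge_map",
    "find_contours",
    "contour_geometry",
    "shoelace_area",
    "min_area_rect",
]

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class EdgeParams:
    """Edge-extraction parameters.

    T_low / T_high are hysteresis thresholds on the Sobel gradient magnitude
    of an 8-bit image (weak edges >= T_low survive only when connected to a
    strong edge >= T_high).  blur_kernel is the odd side length of the
    Gaussian window, blur_sigma its standard deviation in pixels.
    """

    t_low: float = 50.0
    t_high: float = 150.0
    blur_kernel: int = 5
    blur_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.t_low <= self.t_high):
            raise ValueError(
                f"thresholds must satisfy 0 < T_low <= T_high, got "
                f"({self.t_low}, {self.t_high})"
            )
        if self.blur_kernel < 1 or self.blur_kernel % 2 == 0:
            raise ValueError(f"blur_kernel must be odd >= 1, got {self.blur_kernel}")
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be positive")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an H x W x 3 RGB image to 8-bit luminance.

    Uses 0.299 R + 0.587 G + 0.114 B, rounded to the nearest integer.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB array, got shape {image.shape}")
    gray = image.astype(np.float64) @ _LUMA
    return np.rint(gray).astype(np.uint8)


def _gaussian_kernel_1d(size: int, sigma: float) -> np.ndarray:
    x = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_blur(img: np.ndarray, params: EdgeParams = EdgeParams()) -> np.ndarray:
    """Separable Gaussian blur with reflective (symmetric) borders.

    The kernel is normalised to sum to one, so constant images are fixed
    points and the total intensity is preserved under symmetric padding.
    Returns float64 to avoid quantisation before gradient computation.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    k = _gaussian_kernel_1d(params.blur_kernel, params.blur_sigma)
    out = ndimage.correlate1d(img, k, axis=0, mode="reflect")
    out = ndimage.correlate1d(out, k, axis=1, mode="reflect")
    return out


def _sobel_gradients(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # scipy's sobel = [-1,0,1] derivative x [1,2,1] smoothing, reflect border
    gr = ndimage.sobel(img, axis=0, mode="reflect")  # d/d(row)
    gc = ndimage.sobel(img, axis=1, mode="reflect")  # d/d(col)
    return gr, gc


def _nms(mag: np.ndarray, gr: np.ndarray, gc: np.ndarray) -> np.ndarray:
    """Directional non-maximum suppression with one-sided tie-break.

    The gradient direction is quantised to 4 axes; a pixel survives when its
    magnitude strictly exceeds the previous neighbour along the gradient and
    is >= the next one, so a plateau of equal magnitudes (e.g. an ideal step
    edge) thins to a single-pixel line instead of vanishing or doubling.
    """
    h, w = mag.shape
    angle = np.mod(np.arctan2(gr, gc), np.pi)  # [0, pi)
    sector = np.floor((angle + np.pi / 8) / (np.pi / 4)).astype(int) % 4
    # sector 0: horizontal gradient (vertical edge) -> compare along cols
    offsets = {
        0: (0, 1),
        1: (1, 1),
        2: (1, 0),
        3: (1, -1),
    }
    padded = np.pad(mag, 1, mode="constant")
    keep = np.zeros_like(mag, dtype=bool)
    rows, cols = np.indices(mag.shape)
    for s, (dr, dc) in offsets.items():
        sel = sector == s
        r = rows[sel] + 1
        c = cols[sel] + 1
        m = padded[r, c]
        prev = padded[r - dr, c - dc]
        nxt = padded[r + dr, c + dc]
        keep[rows[sel], cols[sel]] = (m > prev) & (m >= nxt)
    return keep


def edge_map(img: np.ndarray, params: EdgeParams = EdgeParams()) -> np.ndarray:
    """Canny-style binary edge mask of a (pre-blurred) grayscale image.

    Sobel gradient magnitude, directional non-maximum suppression, then
    dual-threshold hysteresis: pixels with magnitude >= T_high are edges,
    pixels >= T_low survive only when 8-connected to a strong edge.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    gr, gc = _sobel_gradients(img)
    mag = np.hypot(gr, gc)
    thin = _nms(mag, gr, gc)
    weak = thin & (mag >= params.t_low)
    strong = thin & (mag >= params.t_high)
    if not strong.any():
        return np.zeros_like(weak)
    labels, _ = ndimage.label(weak, structure=np.ones((3, 3), dtype=int))
    keep_ids = np.unique(labels[strong])
    keep_ids = keep_ids[keep_ids > 0]
    mask = np.isin(labels, keep_ids)
    return mask


def find_contours(mask: np.ndarray) -> list[np.ndarray]:
    """Outer contours of the closed regions bounded by an edge mask.

    Raw thin edge rings can carry 1-px gaps, so the mask is morphologically
    closed (3x3, 1 iteration), holes are filled, and the outer boundary of
    each filled component is traced at sub-pixel precision.  Contours are
    returned as closed (N, 2) float arrays of (row, col) points, ordered by
    descending enclosed area.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("expected a 2-D binary mask")
    if not mask.any():
        return []
    closed = ndimage.binary_closing(mask, structure=np.ones((3, 3), dtype=bool))
    filled = ndimage.binary_fill_holes(closed)
    contours = skmeasure.find_contours(filled.astype(np.float64), 0.5)
    contours = [c for c in contours if len(c) >= 3]
    contours.sort(key=lambda c: abs(shoelace_area(c)), reverse=True)
    return contours


def shoelace_area(contour: np.ndarray) -> float:
    """Signed polygon area of a closed (row, col) contour (shoelace formula)."""
    pts = np.asarray(contour, dtype=np.float64)
    r, c = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(c * np.roll(r, -1) - np.roll(c, -1) * r))


def min_area_rect(points: np.ndarray) -> tuple[float, float, float]:
    """Minimum-area rotated rectangle of a point set (rotating calipers).

    Returns (long_px, short_px, angle_deg) with long >= short; the angle is
    the direction of the long side, in degrees, measured from the +col axis.
    """
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    try:
        hull = ConvexHull(pts)
        hp = pts[hull.vertices]
    except QhullError as exc:  # collinear / degenerate input
        raise ValueError("degenerate contour: points are collinear") from exc
    edges = np.roll(hp, -1, axis=0) - hp
    norms = np.linalg.norm(edges, axis=1)
    dirs = edges[norms > 0] / norms[norms > 0, None]
    best = None
    for d in dirs:
        perp = np.array([-d[1], d[0]])
        u = hp @ d
        v = hp @ perp
        w = u.max() - u.min()
        h = v.max() - v.min()
        area = w * h
        if best is None or area < best[0]:
            best = (area, w, h, d)
    _, w, h, d = best
    if w >= h:
        long_px, short_px = w, h
        axis = d
    else:
        long_px, short_px = h, w
        axis = np.array([-d[1], d[0]])
    # axis components are (row, col); angle from +col axis
    angle = float(np.degrees(np.arctan2(axis[0], axis[1])) % 180.0)
    return float(long_px), float(short_px), angle


def contour_geometry(
    contour: np.ndarray,
) -> tuple[float, tuple[float, float], tuple[float, float, float]]:
    """Geometry of a closed contour.

    Returns (area_px, (bbox_w, bbox_h), (long_px, short_px, angle_deg)):
    unsigned shoelace area, axis-aligned bounding-box extents (width along
    columns), and the minimum-area rotated rectangle.
    """
    pts = np.asarray(contour, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("contour must be an (N, 2) array with N >= 3")
    area = abs(shoelace_area(pts))
    bbox = (
        float(pts[:, 1].max() - pts[:, 1].min()),
        float(pts[:, 0].max() - pts[:, 0].min()),
    )
    return area, bbox, min_area_rect(pts)
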