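"""Card-calibrated measurement: pixels-per-mm, slice dimensions, error reports.

The measurement core converts contours to physical dimensions by locating a
rectangular reference card of known size (default 26 x 38 mm) among the
detected contours via its aspect ratio, deriving the pixels-per-mm scale
PPM = W_pixels / W_mm from its 26-mm side, and dividing every other
contour's minimum-area-rectangle sides by that scale.  Agreement with a
caliper measurement is scored as

    Error% = |Pred - Actual| / Actual * 100,    Acc% = 100 - Error%.

Long/short diameters come from the minimum-area rotated rectangle rather
than the axis-aligned bounding box: the axis-aligned extents overestimate
rotated slices and are not rotation invariant.  The axis-aligned values are
still carried on each measurement for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .edges import contour_geometry

__all__ = [
    "CalibrationError",
    "CalibrationResult",
    "SliceMeasurement",
    "ErrorReport",
    "find_reference",
    "compute_ppm",
    "measure_slice",
    "measure_contours",
    "error_accuracy",
    "summarize_errors",
    "round_half_up",
    "percent_reduction",
    "point_gain",
    "write_report",
]

#: Card physical size in mm (short side used for calibration, long side as check).
CARD_W_MM = 26.0
CARD_H_MM = 38.0


class CalibrationError(RuntimeError):
    """Raised when no usable reference card can be found or validated."""


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CalibrationResult:
    """Pixel-to-mm calibration derived from the reference card."""

    ppm: float  # pixels per mm
    card_contour: np.ndarray
    card_px: tuple[float, float]  # (short side px ~ 26 mm, long side px ~ 38 mm)
    ratio_warning: bool = False  # long/short cross-check disagreed > 3 %


@dataclass(frozen=True)
class SliceMeasurement:
    """Physical dimensions of one slice contour after calibration."""

    object_id: int
    long_mm: float
    short_mm: float
    area_mm2: float
    contour: np.ndarray
    bbox_long_mm: float  # axis-aligned extents, for fidelity comparison
    bbox_short_mm: float
    centroid_px: tuple[float, float]  # (x=col, y=row)


@dataclass(frozen=True)
class ErrorReport:
    """Predicted-vs-actual agreement for one dimension of one object."""

    pred: float
    actual: float
    error_pct: float
    acc_pct: float


def find_reference(
    contours: list[np.ndarray],
    expected_ratio: float = CARD_H_MM / CARD_W_MM,
    tol: float = 0.10,
) -> np.ndarray:
    """Pick the reference-card contour by min-rect aspect ratio.

    Returns the contour whose long/short side ratio is within ``tol``
    (relative) of ``expected_ratio``; among several matches the one with the
    largest enclosed area wins.  Raises CalibrationError naming the closest
    ratio seen when nothing matches.
    """
    if not contours:
        raise CalibrationError("no contours to search for a reference card")
    best = None
    closest = None
    for c in contours:
        area, _, (long_px, short_px, _) = contour_geometry(c)
        if short_px <= 0:
            continue
        ratio = long_px / short_px
        rel = abs(ratio - expected_ratio) / expected_ratio
        if closest is None or rel < closest[0]:
            closest = (rel, ratio)
        if rel <= tol and (best is None or area > best[0]):
            best = (area, c)
    if best is None:
        seen = f"{closest[1]:.3f}" if closest else "none"
        raise CalibrationError(
            f"no contour with aspect ratio within {tol:.0%} of "
            f"{expected_ratio:.4f}; closest ratio seen: {seen}"
        )
    return best[1]


def compute_ppm(card: np.ndarray, wmm: float = CARD_W_MM, hmm: float = CARD_H_MM) -> CalibrationResult:
    """Pixels-per-mm from the card contour: PPM = short side px / 26 mm.

    The 38-mm side provides a consistency cross-check; disagreement beyond
    3 % is reported as a warning on the result (the aspect-ratio gate in
    find_reference is the hard failure).
    """
    _, _, (long_px, short_px, _) = contour_geometry(card)
    if short_px <= 0:
        raise CalibrationError("degenerate card contour")
    ppm = short_px / wmm
    ppm_long = long_px / hmm
    mismatch = abs(ppm_long - ppm) / ppm
    warned = False
    if mismatch > 0.03:
        warned = True
        warnings.warn(
            f"card side cross-check disagrees by {mismatch:.1%} "
            f"(26-mm side gives {ppm:.3f} px/mm, 38-mm side {ppm_long:.3f})",
            stacklevel=2,
        )
    return CalibrationResult(
        ppm=float(ppm),
        card_contour=np.asarray(card),
        card_px=(float(short_px), float(long_px)),
        ratio_warning=warned,
    )


def measure_slice(
    contour: np.ndarray,
    cal: CalibrationResult,
    object_id: int,
    min_area_px: float = 400.0,
) -> SliceMeasurement | None:
    """Physical dimensions of one slice contour; None when below min area.

    long_mm / short_mm are the min-area rectangle sides divided by ppm;
    area_mm2 is the shoelace pixel area divided by ppm^2.  Contours smaller
    than ``min_area_px`` square pixels are specks and are filtered out.
    """
    area_px, (bw, bh), (long_px, short_px, _) = contour_geometry(contour)
    if area_px < min_area_px:
        return None
    pts = np.asarray(contour, dtype=np.float64)
    return SliceMeasurement(
        object_id=object_id,
        long_mm=long_px / cal.ppm,
        short_mm=short_px / cal.ppm,
        area_mm2=area_px / cal.ppm**2,
        contour=pts,
        bbox_long_mm=max(bw, bh) / cal.ppm,
        bbox_short_mm=min(bw, bh) / cal.ppm,
        centroid_px=(float(pts[:, 1].mean()), float(pts[:, 0].mean())),
    )


def measure_contours(
    contours: list[np.ndarray],
    expected_ratio: float = CARD_H_MM / CARD_W_MM,
    tol: float = 0.10,
    wmm: float = CARD_W_MM,
    hmm: float = CARD_H_MM,
    min_area_px: float = 400.0,
) -> tuple[CalibrationResult, list[SliceMeasurement], int]:
    """Calibrate on the card and measure every other contour.

    Convenience wrapper chaining find_reference -> compute_ppm ->
    measure_slice.  Returns (calibration, measurements, n_filtered); the card
    itself is excluded from the measurements.
    """
    card = find_reference(contours, expected_ratio=expected_ratio, tol=tol)
    cal = compute_ppm(card, wmm=wmm, hmm=hmm)
    out: list[SliceMeasurement] = []
    n_filtered = 0
    next_id = 1
    for c in contours:
        if c is card:
            continue
        m = measure_slice(c, cal, next_id, min_area_px=min_area_px)
        if m is None:
            n_filtered += 1
            continue
        out.append(m)
        next_id += 1
    return cal, out, n_filtered


def error_accuracy(pred: float, actual: float) -> ErrorReport:
    """Relative error and accuracy of a prediction, in percent.

    Error% = |pred - actual| / actual * 100 and Acc% = 100 - Error%, both
    reported at one decimal (ties rounded up, matching printed tables).
    acc_pct + error_pct == 100 holds exactly.
    """
    if actual <= 0:
        raise ValueError(f"actual must be positive, got {actual}")
    error = abs(pred - actual) / actual * 100.0
    error = round_half_up(error, 1)
    return ErrorReport(pred=pred, actual=actual, error_pct=error,
                       acc_pct=round(100.0 - error, 1))


def summarize_errors(reports: list[ErrorReport]) -> dict[str, float]:
    """Arithmetic mean and max of the error percentages of a report list."""
    if not reports:
        raise ValueError("no reports to summarize")
    errs = np.array([r.error_pct for r in reports], dtype=np.float64)
    return {
        "mean_error_pct": float(errs.mean()),
        "max_error_pct": float(errs.max()),
        "mean_acc_pct": float(100.0 - errs.mean()),
        "n": int(len(errs)),
    }


def percent_reduction(before: float, after: float) -> float:
    """Reduction from ``before`` to ``after`` as a percentage of ``before``."""
    if before <= 0:
        raise ValueError("before must be positive")
    return (before - after) / before * 100.0


def point_gain(before: float, after: float) -> float:
    """Absolute gain in percentage points (after - before)."""
    return after - before


def write_report(
    measurements: list[SliceMeasurement],
    out_dir: str | Path,
    stem: str = "report",
) -> tuple[Path, Path]:
    """Write the measurement report as TXT and CSV twins.

    TXT: one tab-separated line per object, ``id  long_mm  short_mm
    area_mm2`` at one decimal.  CSV: same values with a header.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    txt = out / f"{stem}.txt"
    csv = out / f"{stem}.csv"
    rows = [
        (m.object_id, round_half_up(m.long_mm, 1), round_half_up(m.short_mm, 1),
         round_half_up(m.area_mm2, 1))
        for m in measurements
    ]
    with open(txt, "w") as fh:
        for r in rows:
            fh.write("\t".join(f"{v:.1f}" if isinstance(v, float) else str(v) for v in r) + "\n")
    pd.DataFrame(rows, columns=["object_id", "long_mm", "short_mm", "area_mm2"]).to_csv(
        csv, index=False, float_format="%.1f"
    )
    return txt, csv
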