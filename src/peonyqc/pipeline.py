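"""End-to-end pipeline: image in, two annotated result images + report out.

Mirrors the deployed inspection flow: the measurement branch runs grayscale
-> blur -> edges -> contours -> card calibration -> per-slice physical
dimensions; the optional detection branch runs the shared detection head on
an image-pyramid featurization and emits NMS-filtered boxes.  Outputs are a
measurement overlay PNG, a defect/detection overlay PNG, a tab-separated
``report.txt`` (one line per object: id, long mm, short mm, area mm2) and a
CSV twin, plus a detections CSV when weights are supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from . import blocks
from .edges import EdgeParams, edge_map, find_contours, gaussian_blur, to_grayscale
from .measure import (
    CARD_H_MM,
    CARD_W_MM,
    CalibrationResult,
    SliceMeasurement,
    measure_contours,
    round_half_up,
    write_report,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "image_pyramid_features"]

log = logging.getLogger("peonyqc")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the measurement/detection pipeline."""

    card_mm: tuple[float, float] = (CARD_W_MM, CARD_H_MM)
    edge_params: EdgeParams = field(default_factory=EdgeParams)
    min_area_px: float = 400.0
    ratio_tol: float = 0.10
    iou_thr: float = 0.45
    score_thr: float = 0.25
    weights: str | Path | None = None  # head weight archive; None = measurement only


@dataclass(frozen=True)
class PipelineResult:
    calibration: CalibrationResult
    measurements: list[SliceMeasurement]
    n_filtered: int
    detections: pd.DataFrame | None
    outputs: dict[str, Path]


def image_pyramid_features(
    gray: np.ndarray, in_channels: tuple[int, ...], strides: tuple[int, ...]
) -> list[np.ndarray]:
    """Fixed (non-learned) pyramid featurization of a grayscale image.

    Average-pools the normalized intensity by each level's stride and tiles
    it across the level's channel count — enough structure for the detection
    head to run end-to-end on raw images when no trained backbone features
    are given.
    """
    g = np.asarray(gray, dtype=np.float64) / 255.0
    feats = []
    for c, s in zip(in_channels, strides):
        h, w = g.shape[0] // s, g.shape[1] // s
        pooled = g[: h * s, : w * s].reshape(h, s, w, s).mean(axis=(1, 3))
        feats.append(np.tile(pooled[None, None], (1, c, 1, 1)))
    return feats


def _draw_measurements(
    image: np.ndarray, result_measurements: list[SliceMeasurement], card: np.ndarray
) -> Image.Image:
    im = Image.fromarray(image).convert("RGB")
    draw = ImageDraw.Draw(im)
    pts = [(float(p[1]), float(p[0])) for p in card[:: max(1, len(card) // 400)]]
    draw.polygon(pts, outline=(0, 160, 255))
    for m in result_measurements:
        pts = [(float(p[1]), float(p[0]))
               for p in m.contour[:: max(1, len(m.contour) // 400)]]
        draw.polygon(pts, outline=(255, 80, 0))
        label = (f"#{m.object_id} {round_half_up(m.long_mm, 1):.1f}x"
                 f"{round_half_up(m.short_mm, 1):.1f}mm "
                 f"{round_half_up(m.area_mm2, 1):.1f}mm2")
        draw.text((m.centroid_px[0] - 40, m.centroid_px[1]), label, fill=(255, 255, 0))
    return im


def _draw_detections(image: np.ndarray, det: pd.DataFrame) -> Image.Image:
    im = Image.fromarray(image).convert("RGB")
    draw = ImageDraw.Draw(im)
    for _, r in det.iterrows():
        draw.rectangle([r.x1, r.y1, r.x2, r.y2], outline=(255, 0, 80))
        draw.text((r.x1, max(0.0, r.y1 - 12)),
                  f"c{int(r.class_id)} {r.score:.2f}", fill=(255, 0, 80))
    return im


def _detect(gray: np.ndarray, cfg: PipelineConfig) -> pd.DataFrame:
    params = blocks.load_head_weights(cfg.weights)
    in_channels = tuple(w.shape[1] for w in params.reduce_w)
    feats = image_pyramid_features(gray, in_channels, params.strides)
    out = blocks.lsd_head_forward(feats, params)
    rows = []
    for lvl, (cls_l, reg_l, stride) in enumerate(
        zip(out.cls_logits, out.reg_logits, out.strides)
    ):
        boxes = blocks.dfl_decode(reg_l, out.reg_max, stride, img_size=gray.shape)
        scores = 1.0 / (1.0 + np.exp(-cls_l))  # (1, nc, H, W)
        best_c = scores[0].argmax(axis=0)
        best_s = scores[0].max(axis=0)
        keep = best_s >= cfg.score_thr
        for (i, j) in zip(*np.nonzero(keep)):
            x1, y1, x2, y2 = boxes[0, i, j]
            rows.append((0, int(best_c[i, j]), float(best_s[i, j]),
                         float(x1), float(y1), float(x2), float(y2)))
    det = pd.DataFrame(
        rows, columns=["image_id", "class_id", "score", "x1", "y1", "x2", "y2"]
    )
    if len(det):
        keep = blocks.nms(det[["x1", "y1", "x2", "y2"]].to_numpy(),
                          det["score"].to_numpy(), cfg.iou_thr)
        det = det.iloc[keep].reset_index(drop=True)
    log.info("detection: %d boxes after NMS", len(det))
    return det


def run_pipeline(
    image_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run measurement (and, with weights, detection) on one image.

    Raises CalibrationError when no reference card is found and OSError when
    the image cannot be read.  Re-running on the same inputs is
    deterministic, so the report files are byte-identical across runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image = np.asarray(Image.open(image_path).convert("RGB"))
    log.info("loaded %s: %dx%d", image_path, image.shape[1], image.shape[0])

    gray = to_grayscale(image)
    blurred = gaussian_blur(gray, config.edge_params)
    edges = edge_map(blurred, config.edge_params)
    contours = find_contours(edges)
    log.info("found %d contours", len(contours))
    wmm, hmm = min(config.card_mm), max(config.card_mm)
    cal, measurements, n_filtered = measure_contours(
        contours,
        expected_ratio=hmm / wmm,
        tol=config.ratio_tol,
        wmm=wmm,
        hmm=hmm,
        min_area_px=config.min_area_px,
    )
    log.info(
        "calibration: ppm=%.3f px/mm (card %.1f x %.1f px); "
        "%d slices measured, %d sub-minimum contours filtered",
        cal.ppm, cal.card_px[0], cal.card_px[1], len(measurements), n_filtered,
    )

    txt, csv = write_report(measurements, out)
    outputs = {"report_txt": txt, "report_csv": csv}

    m_png = out / "measurement_overlay.png"
    _draw_measurements(image, measurements, cal.card_contour).save(m_png)
    outputs["measurement_overlay"] = m_png

    detections = None
    if config.weights is not None:
        detections = _detect(gray, config)
        det_csv = out / "detections.csv"
        detections.to_csv(det_csv, index=False)
        d_png = out / "defect_overlay.png"
        _draw_detections(image, detections).save(d_png)
        outputs.update(detections_csv=det_csv, defect_overlay=d_png)

    return PipelineResult(
        calibration=cal,
        measurements=measurements,
        n_filtered=n_filtered,
        detections=detections,
        outputs=outputs,
    )
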