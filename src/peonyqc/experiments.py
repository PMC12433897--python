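"""Repeatable validation experiments: parameter recovery and reparam sweeps.

These drive the package's own components end-to-end under controlled,
seeded conditions and return summary statistics; the test suite and the
results-reproduction script both call them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import KernelBank, deconv_forward
from .edges import EdgeParams, edge_map, find_contours, gaussian_blur, to_grayscale
from .measure import SliceMeasurement, measure_contours
from .synthetic import random_feature_map, random_scene, render_scene

__all__ = ["match_to_truth", "recover_scene", "parameter_recovery", "reparameterization_sweep"]


def match_to_truth(
    measurements: list[SliceMeasurement], truth: pd.DataFrame
) -> pd.DataFrame:
    """Pair measured slices with ground-truth rows by nearest shape center.

    ``truth`` is the table from :func:`peonyqc.synthetic.render_scene`
    (carries center_x_px / center_y_px).  The card row is excluded.  Returns
    one row per truth slice with measured and true dimensions plus their
    relative errors in percent; unmatched truth rows get NaN measurements.
    """
    slices = truth[~truth["card_flag"]].reset_index(drop=True)
    rows = []
    used: set[int] = set()
    for _, t in slices.iterrows():
        best, best_d = None, np.inf
        for k, m in enumerate(measurements):
            if k in used:
                continue
            d = np.hypot(m.centroid_px[0] - t.center_x_px,
                         m.centroid_px[1] - t.center_y_px)
            if d < best_d:
                best, best_d = k, d
        # a match must land inside the shape; half the short axis is a safe radius
        if best is not None and best_d < t.long_mm:  # px/mm >= 1 in all scenes
            m = measurements[best]
            used.add(best)
            rows.append(dict(
                object_id=int(t.object_id),
                long_true=t.long_mm, short_true=t.short_mm, area_true=t.area_mm2,
                long_meas=m.long_mm, short_meas=m.short_mm, area_meas=m.area_mm2,
            ))
        else:
            rows.append(dict(
                object_id=int(t.object_id),
                long_true=t.long_mm, short_true=t.short_mm, area_true=t.area_mm2,
                long_meas=np.nan, short_meas=np.nan, area_meas=np.nan,
            ))
    df = pd.DataFrame(rows)
    for dim in ("long", "short", "area"):
        df[f"{dim}_err_pct"] = (df[f"{dim}_meas"] - df[f"{dim}_true"]).abs() / df[f"{dim}_true"] * 100
    return df


@dataclass(frozen=True)
class SceneRecovery:
    seed: int
    ppm_true: float
    ppm_recovered: float
    ppm_err_pct: float
    n_slices: int
    n_matched: int
    per_slice: pd.DataFrame


def recover_scene(seed: int, noise_sigma: float = 3.0,
                  edge_params: EdgeParams = EdgeParams()) -> SceneRecovery:
    """Render one seeded random scene and run the full measurement pipeline."""
    spec = random_scene(seed, noise_sigma=noise_sigma)
    img, truth = render_scene(spec)
    gray = to_grayscale(img)
    edges = edge_map(gaussian_blur(gray, edge_params), edge_params)
    cal, measurements, _ = measure_contours(find_contours(edges))
    per_slice = match_to_truth(measurements, truth)
    return SceneRecovery(
        seed=seed,
        ppm_true=spec.ppm,
        ppm_recovered=cal.ppm,
        ppm_err_pct=abs(cal.ppm - spec.ppm) / spec.ppm * 100,
        n_slices=len(spec.slices),
        n_matched=int(per_slice["long_meas"].notna().sum()),
        per_slice=per_slice,
    )


def parameter_recovery(
    n_scenes: int = 20, base_seed: int = 0, noise_sigma: float = 3.0
) -> dict[str, float]:
    """Measurement accuracy over seeded random scenes.

    Returns max ppm error, mean absolute diameter error (long and short
    pooled) and mean absolute area error, all in percent, plus counts.
    """
    recs = [recover_scene(base_seed + i, noise_sigma=noise_sigma)
            for i in range(n_scenes)]
    per = pd.concat([r.per_slice for r in recs], ignore_index=True)
    diam = pd.concat([per["long_err_pct"], per["short_err_pct"]], ignore_index=True)
    return {
        "n_scenes": float(n_scenes),
        "n_slices": float(len(per)),
        "n_matched": float(sum(r.n_matched for r in recs)),
        "ppm_max_err_pct": max(r.ppm_err_pct for r in recs),
        "ppm_mean_err_pct": float(np.mean([r.ppm_err_pct for r in recs])),
        "diameter_mean_abs_err_pct": float(diam.mean()),
        "area_mean_abs_err_pct": float(per["area_err_pct"].mean()),
    }


def reparameterization_sweep(n_configs: int = 50, base_seed: int = 0) -> float:
    """Max relative merged-vs-parallel discrepancy over seeded DEConv configs.

    For each configuration a random kernel bank and input are drawn and the
    output of the single merged kernel is compared against the sum of the
    five parallel difference-convolution branches; returns the worst
    relative error (max |diff| / max |merged output|).
    """
    rng = np.random.default_rng(base_seed)
    worst = 0.0
    for _ in range(n_configs):
        c_in = int(rng.integers(1, 7))
        c_out = int(rng.integers(1, 7))
        h = int(rng.integers(6, 20))
        w = int(rng.integers(6, 20))
        bank = KernelBank.random(int(rng.integers(2**31 - 1)), c_out, c_in, 3, scale=1.0)
        x = random_feature_map(int(rng.integers(2**31 - 1)), 1, c_in, h, w)
        merged = deconv_forward(x, bank, mode="merged")
        parallel = deconv_forward(x, bank, mode="parallel")
        denom = max(np.abs(merged).max(), 1e-12)
        worst = max(worst, float(np.abs(merged - parallel).max() / denom))
    return worst
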