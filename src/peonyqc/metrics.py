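"""Detection evaluation: IoU, greedy matching, precision/recall, AP and mAP.

Conventions: predictions are matched to ground truths per image and class in
descending score order (ties broken by insertion order); each ground truth
can absorb at most one prediction; a match requires IoU >= the threshold
(default 0.5).  Precision = TP/(TP+FP) and recall = TP/(TP+FN) with 0/0
defined as 0.  AP is the all-point-interpolated area under the
precision-recall curve, mAP the unweighted mean of the per-class APs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BoxRecord",
    "DetectionMetrics",
    "iou",
    "match_detections",
    "precision_recall",
    "average_precision",
    "mean_ap",
    "evaluate_detections",
]


@dataclass(frozen=True)
class BoxRecord:
    """One box: ground truth (score ignored) or scored prediction."""

    image_id: int
    class_id: int
    box: tuple[float, float, float, float]  # (x1, y1, x2, y2)
    score: float = 1.0

    def __post_init__(self) -> None:
        x1, y1, x2, y2 = self.box
        if x2 < x1 or y2 < y1:
            raise ValueError(f"invalid box {self.box}: need x2 >= x1 and y2 >= y1")


@dataclass(frozen=True)
class DetectionMetrics:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    ap_per_class: dict[int, float]
    map: float


def iou(a, b) -> float:
    """Intersection-over-union of two (x1, y1, x2, y2) boxes, in [0, 1]."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union if union > 0 else 0.0


def _group(records: list[BoxRecord]) -> dict[tuple[int, int], list[BoxRecord]]:
    out: dict[tuple[int, int], list[BoxRecord]] = {}
    for r in records:
        out.setdefault((r.image_id, r.class_id), []).append(r)
    return out


def _match_group(
    preds: list[BoxRecord], gts: list[BoxRecord], iou_thr: float
) -> list[bool]:
    """Greedy score-descending matching; returns a TP flag per prediction
    (in score order).  IoU ties go to the lowest ground-truth index."""
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].score, i))
    taken = [False] * len(gts)
    flags = []
    for i in order:
        best_j, best_iou = -1, iou_thr
        for j, g in enumerate(gts):
            if taken[j]:
                continue
            v = iou(preds[i].box, g.box)
            if v > best_iou or (v == best_iou and best_j == -1 and v >= iou_thr > 0 and v > 0):
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_thr:
            taken[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    return flags


def match_detections(
    preds: list[BoxRecord], gts: list[BoxRecord], iou_thr: float = 0.5
) -> tuple[int, int, int]:
    """TP/FP/FN counts over all images and classes.

    Predictions are matched greedily in descending score order within each
    (image, class) group; every ground truth is matched at most once.
    Unmatched predictions count as FP, unmatched ground truths as FN.
    """
    pg, gg = _group(preds), _group(gts)
    tp = fp = 0
    for key, p in pg.items():
        flags = _match_group(p, gg.get(key, []), iou_thr)
        tp += sum(flags)
        fp += len(flags) - sum(flags)
    fn = sum(len(g) for g in gg.values()) - tp
    return tp, fp, fn


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN); 0/0 is defined as 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return precision, recall


def average_precision(
    preds: list[BoxRecord], gts: list[BoxRecord], iou_thr: float = 0.5
) -> float:
    """All-point-interpolated AP at the given IoU threshold (single class set).

    Predictions from all images are ranked globally by score; the
    precision envelope is integrated over recall.
    """
    n_gt = len(gts)
    if n_gt == 0:
        warnings.warn("no ground truths: AP undefined, returning 0", stacklevel=2)
        return 0.0
    pg, gg = _group(preds), _group(gts)
    scored: list[tuple[float, int, bool]] = []  # (score, insertion order, tp)
    order = 0
    for key, p in pg.items():
        flags = _match_group(p, gg.get(key, []), iou_thr)
        ranked = sorted(range(len(p)), key=lambda i: (-p[i].score, i))
        for i, flag in zip(ranked, flags):
            scored.append((p[i].score, order, flag))
            order += 1
    if not scored:
        return 0.0
    scored.sort(key=lambda t: (-t[0], t[1]))
    tps = np.cumsum([t[2] for t in scored])
    fps = np.cumsum([not t[2] for t in scored])
    recall = tps / n_gt
    precision = tps / (tps + fps)
    mrec = np.concatenate([[0.0], recall, [1.0]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]  # precision envelope
    idx = np.nonzero(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def mean_ap(ap_per_class: dict[int, float] | list[float]) -> float:
    """Unweighted mean of per-class average precisions."""
    vals = list(ap_per_class.values()) if isinstance(ap_per_class, dict) else list(ap_per_class)
    if not vals:
        return 0.0
    return float(np.mean(vals))


def evaluate_detections(
    preds: list[BoxRecord], gts: list[BoxRecord], iou_thr: float = 0.5
) -> DetectionMetrics:
    """Full evaluation: counts, precision/recall, per-class AP and mAP.

    Classes with no ground truth are excluded from mAP with a warning.
    """
    tp, fp, fn = match_detections(preds, gts, iou_thr)
    precision, recall = precision_recall(tp, fp, fn)
    classes = sorted({g.class_id for g in gts})
    pred_only = sorted({p.class_id for p in preds} - set(classes))
    if pred_only:
        warnings.warn(
            f"classes {pred_only} have predictions but no ground truth; "
            "excluded from mAP", stacklevel=2,
        )
    ap = {
        c: average_precision(
            [p for p in preds if p.class_id == c],
            [g for g in gts if g.class_id == c],
            iou_thr,
        )
        for c in classes
    }
    return DetectionMetrics(
        tp=tp, fp=fp, fn=fn, precision=precision, recall=recall,
        ap_per_class=ap, map=mean_ap(ap),
    )
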