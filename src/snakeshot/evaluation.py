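"""COCO-style detection and segmentation metrics: AP, AP50, AP75.

Matching is score-greedy per image and class: detections, in descending
score order, each claim the unclaimed ground truth of highest IoU provided
it reaches the threshold.  Average precision is the 101-point interpolated
area under the precision-recall staircase, averaged over the IoU thresholds
0.50:0.05:0.95 and over categories; AP50/AP75 fix the threshold at 0.5/0.75.
Values are reported on the 0-100 scale.  Box mode compares boxes, mask mode
rasterizes the contours and compares masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .geometry import BoundingBox

__all__ = [
    "Detection",
    "MatchResult",
    "EvalResult",
    "iou_thresholds",
    "match_detections",
    "average_precision",
    "evaluate_run",
    "format_table",
]


@dataclass
class Detection:
    """One predicted instance: box, class, confidence, optional contour."""

    box: BoundingBox
    category_id: int
    score: float
    image_id: int = -1
    contour: np.ndarray | None = None  # (n, 2) polygon for mask-mode evaluation


@dataclass
class MatchResult:
    """Per-detection TP/FP flags at one IoU threshold plus unmatched-GT count."""

    tp: np.ndarray
    n_unmatched_gt: int


@dataclass
class EvalResult:
    ap: float
    ap50: float
    ap75: float
    mode: str
    per_class: dict = field(default_factory=dict)  # category_id -> AP (0-100)


def iou_thresholds() -> np.ndarray:
    return np.arange(0.50, 0.96, 0.05)


def _pairwise_iou(dets, gts, mode, raster_shape):
    """IoU matrix between detections and ground-truth annotations."""
    m = np.zeros((len(dets), len(gts)))
    if mode == "box":
        for i, d in enumerate(dets):
            for j, g in enumerate(gts):
                m[i, j] = geometry.box_iou(d.box, geometry.coco_to_box(g["bbox"]))
        return m
    h, w = raster_shape
    dmasks = [geometry.contour_to_mask(d.contour, h, w) for d in dets]
    gmasks = [geometry.contour_to_mask(geometry.coco_to_contour(g["segmentation"][0]), h, w)
              for g in gts]
    for i, dm in enumerate(dmasks):
        for j, gm in enumerate(gmasks):
            m[i, j] = geometry.mask_iou(dm, gm)
    return m


def match_detections(dets, gts, iou_threshold: float, mode: str = "box",
                     raster_shape=None, iou_matrix=None) -> MatchResult:
    """Greedy score-order matching of detections to ground truth.

    ``dets`` must already be sorted by descending score (contract error
    otherwise); each ground truth is claimed at most once.
    """
    scores = [d.score for d in dets]
    if any(a < b for a, b in zip(scores, scores[1:])):
        raise ValueError("detections must be sorted by descending score")
    if mode not in ("box", "mask"):
        raise ValueError(f"unknown mode {mode!r}")
    if iou_matrix is None:
        iou_matrix = _pairwise_iou(dets, gts, mode, raster_shape)
    claimed = np.zeros(len(gts), dtype=bool)
    tp = np.zeros(len(dets), dtype=bool)
    for i in range(len(dets)):
        best_j, best_iou = -1, iou_threshold
        for j in range(len(gts)):
            if not claimed[j] and iou_matrix[i, j] >= best_iou:
                best_j, best_iou = j, iou_matrix[i, j]
        if best_j >= 0:
            claimed[best_j] = True
            tp[i] = True
    return MatchResult(tp=tp, n_unmatched_gt=int((~claimed).sum()))


def average_precision(tp_flags: np.ndarray, n_gt: int) -> float:
    """101-point interpolated AP from score-ordered TP/FP flags.

    ``tp_flags`` concatenates all detections of one class across images,
    sorted by descending score.  Returns a value in [0, 1]; 0 when there is
    no ground truth.
    """
    if n_gt < 0:
        raise ValueError("n_gt must be non-negative")
    if n_gt == 0 or len(tp_flags) == 0:
        return 0.0
    tp = np.asarray(tp_flags, dtype=float)
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope: best precision at any recall >= r
    for i in range(len(precision) - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    points = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, points, side="left")
    interp = np.where(idx < len(precision), precision[np.minimum(idx, len(precision) - 1)], 0.0)
    return float(interp.mean())


def evaluate_run(predictions, dataset, mode: str = "box") -> EvalResult:
    """Evaluate a list of :class:`Detection` against a dataset's val annotations.

    Classes absent from the ground truth are skipped (COCO convention);
    unknown category ids in the predictions raise.
    """
    known = {c["id"] for c in dataset.categories}
    for d in predictions:
        if d.category_id not in known:
            raise ValueError(f"unknown category id {d.category_id}")
    val_ids = dataset.image_ids("val")
    thresholds = iou_thresholds()
    per_class_ap: dict[int, float] = {}
    ap50s, ap75s = [], []
    for cat in sorted(known):
        n_gt = 0
        # gather (score, tp-at-each-threshold) across images, then global sort
        all_scores: list[float] = []
        all_tp = [[] for _ in thresholds]
        for image_id in val_ids:
            gts = [g for g in dataset.annotations_for(image_id) if g["category_id"] == cat]
            n_gt += len(gts)
            dets = sorted(
                (d for d in predictions if d.image_id == image_id and d.category_id == cat),
                key=lambda d: -d.score)
            if not dets:
                continue
            im = dataset.image_by_id(image_id)
            iou = _pairwise_iou(dets, gts, mode, (im["height"], im["width"]))
            for t, thr in enumerate(thresholds):
                res = match_detections(dets, gts, thr, mode=mode, iou_matrix=iou)
                all_tp[t].extend(res.tp.tolist())
            all_scores.extend(d.score for d in dets)
        if n_gt == 0:
            continue
        order = np.argsort(-np.asarray(all_scores), kind="stable")
        aps = [average_precision(np.asarray(flags)[order], n_gt) for flags in all_tp]
        per_class_ap[cat] = 100.0 * float(np.mean(aps))
        ap50s.append(100.0 * aps[0])
        ap75s.append(100.0 * aps[5])
    if not per_class_ap:
        return EvalResult(ap=0.0, ap50=0.0, ap75=0.0, mode=mode)
    return EvalResult(
        ap=float(np.mean(list(per_class_ap.values()))),
        ap50=float(np.mean(ap50s)),
        ap75=float(np.mean(ap75s)),
        mode=mode,
        per_class=per_class_ap,
    )


def format_table(rows: list[tuple[str, EvalResult]]) -> str:
    """Plain-text Method / AP / AP50 / AP75 table."""
    lines = [f"{'Method':<28}{'AP':>8}{'AP50':>8}{'AP75':>8}"]
    for name, r in rows:
        lines.append(f"{name:<28}{r.ap:>8.1f}{r.ap50:>8.1f}{r.ap75:>8.1f}")
    return "\n".join(lines)
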