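"""Learning-based contour deformation (deep snake) on cyclic contour graphs.

A detector box is first collapsed to the diamond through its edge midpoints;
a snake block reads features along the diamond (resampled to 40 vertices for
context) and regresses offsets from the four midpoints to the object's
extreme points.  The extreme points define an octagon inscribed in the box;
a second snake block then deforms the octagon — resampled to N = 128
vertices — toward the object boundary, and is applied iteratively (3 rounds)
so that vertices far from the boundary can travel in several short hops.

Because a contour is a cycle graph, per-vertex features are mixed with
*circular* convolution: the kernel support wraps around modulo the vertex
count, so the contour has no artificial endpoints.  Each vertex carries an
appearance feature (bilinearly sampled from a strided convolutional feature
grid) concatenated with its coordinates relative to the contour centroid.

Each deformation round has its own block weights, and contours are detached
between iterations: every round is supervised independently against the
ground-truth polygon, so later rounds learn progressively finer refinements.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np

from . import geometry
from .config import SnakeConfig, TrainConfig
from .geometry import BoundingBox, ExtremePointSet
from .nn import (
    Adam,
    Tensor,
    bilinear_sample,
    concat,
    conv2d,
    cyclic_unfold,
    linear,
    max_over_rows,
    relu,
    smooth_l1,
    take_rows,
)

__all__ = [
    "FeatureGrid",
    "init_snake_params",
    "extract_features",
    "vertex_features",
    "circular_conv",
    "snake_block",
    "predict_extreme_points",
    "deform_iteratively",
    "snake_training_loss",
    "train_snake",
    "evaluate_snake",
    "save_params",
    "load_params",
]


@dataclass
class FeatureGrid:
    """Image features (C, H', W') at a fixed spatial stride."""

    values: Tensor
    stride: int


def _he(rng, shape, fan_in):
    return rng.standard_normal(shape) * np.sqrt(2.0 / max(fan_in, 1))


def init_snake_params(cfg: SnakeConfig, seed: int = 0) -> dict:
    """Initialize feature extractor plus the two snake blocks.

    Offset heads start at zero, so an untrained model is the identity on its
    input contour.
    """
    rng = np.random.default_rng(seed)
    fc = cfg.feature_channels
    p: dict[str, Tensor] = {}
    # feature extractor: stride-4 grid
    p["fe.c1.w"] = Tensor(_he(rng, (16, 3, 3, 3), 27), requires_grad=True)
    p["fe.c1.b"] = Tensor(np.zeros(16), requires_grad=True)
    p["fe.c2.w"] = Tensor(_he(rng, (fc, 16, 3, 3), 144), requires_grad=True)
    p["fe.c2.b"] = Tensor(np.zeros(fc), requires_grad=True)
    p["fe.c3.w"] = Tensor(_he(rng, (fc, fc, 3, 3), 9 * fc), requires_grad=True)
    p["fe.c3.b"] = Tensor(np.zeros(fc), requires_grad=True)
    d_in = fc + 2
    s = cfg.state_channels
    k = cfg.kernel_size
    # extreme-point block plus one deformation block per iteration: the last
    # round can then specialize in small refinements instead of re-applying
    # the same coarse step
    for blk in ["ex"] + [f"df{i}" for i in range(cfg.iterations)]:
        p[f"{blk}.cc1.w"] = Tensor(_he(rng, (k * d_in, s), k * d_in), requires_grad=True)
        p[f"{blk}.cc1.b"] = Tensor(np.zeros(s), requires_grad=True)
        p[f"{blk}.cc2.w"] = Tensor(_he(rng, (k * s, s), k * s), requires_grad=True)
        p[f"{blk}.cc2.b"] = Tensor(np.zeros(s), requires_grad=True)
        p[f"{blk}.fc1.w"] = Tensor(_he(rng, (2 * s, s), 2 * s), requires_grad=True)
        p[f"{blk}.fc1.b"] = Tensor(np.zeros(s), requires_grad=True)
        p[f"{blk}.out.w"] = Tensor(np.zeros((s, 2)), requires_grad=True)
        p[f"{blk}.out.b"] = Tensor(np.zeros(2), requires_grad=True)
    return p


def extract_features(params: dict, image: np.ndarray, cfg: SnakeConfig) -> FeatureGrid:
    """Run the small strided feature extractor on an (H, W, 3) image in [0, 1]."""
    x = Tensor(np.ascontiguousarray(image.transpose(2, 0, 1), dtype=np.float64))
    x = relu(conv2d(x, params["fe.c1.w"], params["fe.c1.b"], stride=2, pad=1))
    x = relu(conv2d(x, params["fe.c2.w"], params["fe.c2.b"], stride=2, pad=1))
    x = relu(conv2d(x, params["fe.c3.w"], params["fe.c3.b"], stride=1, pad=1))
    return FeatureGrid(values=x, stride=cfg.stride)


def vertex_features(grid: FeatureGrid, contour: np.ndarray) -> Tensor:
    """Per-vertex features: sampled appearance ++ centroid-relative coordinates.

    Appearance is bilinearly interpolated from the feature grid at each
    vertex; relative coordinates are normalized by the contour's half-extent,
    making the shape channel scale-free.  Rows align with contour vertices.
    """
    pts = np.asarray(contour, dtype=float)
    fpts = pts / grid.stride - 0.5  # image coords -> feature-cell coords
    app = bilinear_sample(grid.values, fpts)
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    half_extent = max(rel.max(initial=0.0), -rel.min(initial=0.0), 1e-6)
    rel = rel / half_extent
    return concat([app, Tensor(rel)], axis=1)


def circular_conv(features, kernel, bias=None) -> Tensor:
    """Circular convolution on the contour cycle graph.

    ``out[i] = Σ_j kernel[j] · features[(i + j − (k−1)/2) mod n]`` with the
    index wrapping modulo the vertex count.  ``kernel`` may be a (k, d, d')
    array/tensor or its (k*d, d') flattening.
    """
    if not isinstance(features, Tensor):
        features = Tensor(features)
    kdata = kernel.data if isinstance(kernel, Tensor) else np.asarray(kernel, dtype=float)
    if kdata.ndim == 3:
        k = kdata.shape[0]
        kernel = kernel.reshape(kdata.shape[0] * kdata.shape[1], kdata.shape[2]) \
            if isinstance(kernel, Tensor) else Tensor(kdata.reshape(k * kdata.shape[1], -1))
    else:
        if not isinstance(kernel, Tensor):
            kernel = Tensor(kdata)
        d = features.data.shape[1]
        k = kdata.shape[0] // d
        if k * d != kdata.shape[0]:
            raise ValueError("flattened kernel rows must be k * d")
    if k % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {k}")
    if features.data.shape[0] < k:
        raise ValueError("contour has fewer vertices than kernel taps")
    out = cyclic_unfold(features, k) @ kernel
    if bias is not None:
        out = out + (bias if isinstance(bias, Tensor) else Tensor(bias))
    return out


def snake_block(params: dict, prefix: str, vf: Tensor) -> Tensor:
    """Circular-conv stack + global max feature + per-vertex 2-D offset head."""
    x = relu(circular_conv(vf, params[f"{prefix}.cc1.w"], params[f"{prefix}.cc1.b"]))
    x = relu(circular_conv(x, params[f"{prefix}.cc2.w"], params[f"{prefix}.cc2.b"]))
    g = max_over_rows(x)  # (1, s): shift-invariant whole-contour descriptor
    ones = Tensor(np.ones((x.data.shape[0], 1)))
    fused = concat([x, ones @ g], axis=1)
    h = relu(linear(fused, params[f"{prefix}.fc1.w"], params[f"{prefix}.fc1.b"]))
    return linear(h, params[f"{prefix}.out.w"], params[f"{prefix}.out.b"])


def _midpoint_indices(n_diamond: int) -> np.ndarray:
    # diamond edges have equal length, so resampling keeps the original four
    # vertices at quarter positions
    return np.arange(4) * (n_diamond // 4)


def _extreme_offsets(box: BoundingBox, grid: FeatureGrid, params: dict,
                     cfg: SnakeConfig) -> tuple[np.ndarray, Tensor]:
    diamond = geometry.box_to_diamond(box)
    dense = geometry.resample_contour(diamond, cfg.n_diamond)
    vf = vertex_features(grid, dense)
    offsets = snake_block(params, "ex", vf)
    idx = _midpoint_indices(cfg.n_diamond)
    pred = Tensor(dense[idx]) + take_rows(offsets, idx)
    return dense[idx], pred  # midpoints (top,right,bottom,left), predicted extremes


def predict_extreme_points(box: BoundingBox, grid: FeatureGrid, params: dict,
                           cfg: SnakeConfig) -> ExtremePointSet:
    """Predict the object's four extreme points from the diamond contour.

    The diamond is resampled to ``cfg.n_diamond`` vertices for context;
    offsets are read at the four original midpoint vertices.  Predictions are
    clamped into the box so the set's ordering invariants always hold (the
    octagon construction projects onto box edges anyway).
    """
    if not isinstance(box, BoundingBox):
        box = BoundingBox.from_array(box)
    c, h, w = grid.values.data.shape
    if box.x1 / grid.stride > w or box.y1 / grid.stride > h or box.x0 < 0 or box.y0 < 0:
        raise geometry.InvalidGeometryError("box lies outside the feature grid")
    _, pred = _extreme_offsets(box, grid, params, cfg)
    return _clamp_extremes(pred.data, box)


def _clamp_extremes(pts: np.ndarray, box: BoundingBox) -> ExtremePointSet:
    pts = np.asarray(pts, dtype=float).copy()
    pts[:, 0] = np.clip(pts[:, 0], box.x0, box.x1)
    pts[:, 1] = np.clip(pts[:, 1], box.y0, box.y1)
    return ExtremePointSet(top=tuple(pts[0]), rightmost=tuple(pts[1]),
                           bottom=tuple(pts[2]), leftmost=tuple(pts[3]))


def _deform_tensors(octagon: np.ndarray, grid: FeatureGrid, params: dict,
                    cfg: SnakeConfig) -> list[Tensor]:
    """One Tensor contour per iteration; inputs detached between iterations."""
    ct = geometry.resample_contour(octagon, cfg.n_contour)
    preds = []
    for i in range(cfg.iterations):
        vf = vertex_features(grid, ct)
        off = snake_block(params, f"df{i}", vf)
        pred = Tensor(ct) + off
        preds.append(pred)
        ct = pred.data
    return preds


def deform_iteratively(octagon: np.ndarray, grid: FeatureGrid, params: dict,
                       cfg: SnakeConfig, return_all: bool = False):
    """Iteratively shrink-wrap the octagon onto the object boundary.

    Returns the final ``cfg.n_contour``-vertex contour, or all per-iteration
    contours when ``return_all`` is set.
    """
    preds = _deform_tensors(np.asarray(octagon, dtype=float), grid, params, cfg)
    contours = [p.data.copy() for p in preds]
    return contours if return_all else contours[-1]


def _align_target(gt_resampled: np.ndarray, pred_vertices: np.ndarray) -> np.ndarray:
    """Roll the ground truth so its start vertex pairs with the nearest prediction."""
    j = int(np.argmin(np.linalg.norm(pred_vertices - gt_resampled[0], axis=1)))
    return np.roll(gt_resampled, j, axis=0)


def snake_training_loss(pred_extremes: Tensor, pred_contours: list[Tensor],
                        gt_polygon: np.ndarray, cfg: SnakeConfig) -> Tensor:
    """Smooth-L1 on extreme points plus per-vertex smooth-L1 summed over iterations.

    The ground-truth polygon is resampled to ``cfg.n_contour`` vertices in
    clockwise order; correspondence rolls its start vertex onto the nearest
    predicted vertex, then follows index order.
    """
    gt = geometry.ensure_clockwise(np.asarray(gt_polygon, dtype=float))
    gt_ext = geometry.extreme_points_of(gt).as_array()
    loss = smooth_l1(pred_extremes, gt_ext)
    gt_res = geometry.resample_contour(gt, cfg.n_contour)
    target = None
    for i, pred in enumerate(pred_contours):
        if pred.data.shape[0] != cfg.n_contour:
            raise ValueError("predicted contour vertex count != cfg.n_contour")
        if target is None:
            # correspondence fixed once, from the first round: later rounds
            # then refine toward a stable target instead of chasing a
            # re-aligned one
            target = _align_target(gt_res, pred.data)
        term = smooth_l1(pred, target)
        # the last round produces the output contour: double weight so the
        # final refinement is trained to land, not overshoot
        loss = loss + (term * 2.0 if i == len(pred_contours) - 1 else term)
    return loss


def _instance_records(dataset, split: str, min_side: float = 6.0):
    """(image_id, gt polygon, gt box) for annotations big enough to learn from."""
    out = []
    for image_id in dataset.image_ids(split):
        for ann in dataset.annotations_for(image_id):
            x, y, w, h = ann["bbox"]
            if w < min_side or h < min_side:
                continue
            poly = geometry.coco_to_contour(ann["segmentation"][0])
            out.append((image_id, poly, BoundingBox(x, y, x + w, y + h)))
    return out


def _jitter_box(box: BoundingBox, rng, frac: float, bounds) -> BoundingBox:
    """Randomly shift/scale a box (train-time noise emulating detector error)."""
    w, h = box.width, box.height
    dx, dy = rng.normal(0.0, frac * w), rng.normal(0.0, frac * h)
    sw, sh = np.exp(rng.normal(0.0, frac)), np.exp(rng.normal(0.0, frac))
    cx, cy = 0.5 * (box.x0 + box.x1) + dx, 0.5 * (box.y0 + box.y1) + dy
    x0 = np.clip(cx - 0.5 * sw * w, 0, bounds[0] - 2)
    y0 = np.clip(cy - 0.5 * sh * h, 0, bounds[1] - 2)
    x1 = np.clip(cx + 0.5 * sw * w, x0 + 2, bounds[0])
    y1 = np.clip(cy + 0.5 * sh * h, y0 + 2, bounds[1])
    return BoundingBox(float(x0), float(y0), float(x1), float(y1))


def segment_instance(box: BoundingBox, grid: FeatureGrid, params: dict,
                     cfg: SnakeConfig, return_all: bool = False):
    """Full contour pipeline for one box: diamond → extremes → octagon → deform."""
    extremes = predict_extreme_points(box, grid, params, cfg)
    octagon = geometry.build_octagon(extremes, box, tol=None)
    return deform_iteratively(octagon, grid, params, cfg, return_all=return_all)


def train_snake(dataset, cfg: SnakeConfig, train_cfg: TrainConfig, seed: int = 0,
                progress=None):
    """Train extractor + snake blocks on ground-truth boxes (oracle-detector mode).

    Adam at ``train_cfg.lr_snake`` with the configured weight decay;
    gradients are accumulated over ``train_cfg.batch_size`` images per step.
    Returns ``(params, history)`` where history rows are
    ``(epoch, mean_total_loss)``.
    """
    records = _instance_records(dataset, "train")
    if not records:
        raise ValueError("training split contains no usable annotated instances")
    params = init_snake_params(cfg, seed=seed)
    opt = Adam(params, lr=train_cfg.lr_snake, weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(seed + 1)
    by_image: dict[int, list] = {}
    for rec in records:
        by_image.setdefault(rec[0], []).append(rec)
    image_ids = sorted(by_image)
    history = []
    for epoch in range(train_cfg.epochs_snake):
        order = rng.permutation(len(image_ids))
        total, count = 0.0, 0
        opt.zero_grad()
        pending = 0
        # learning-rate step-down for the last third of training
        opt.lr = train_cfg.lr_snake * (0.1 if epoch >= 2 * train_cfg.epochs_snake // 3 else 1.0)
        for pos in order:
            image_id = image_ids[pos]
            im = dataset.image_by_id(image_id)
            grid = extract_features(params, im["pixels"], cfg)
            losses = []
            for _, poly, gt_box in by_image[image_id]:
                box = _jitter_box(gt_box, rng, 0.05, (im["width"], im["height"]))
                _, pred_ext = _extreme_offsets(box, grid, params, cfg)
                ext = _clamp_extremes(pred_ext.data, box)
                octagon = geometry.build_octagon(ext, box, tol=None)
                preds = _deform_tensors(octagon, grid, params, cfg)
                losses.append(snake_training_loss(pred_ext, preds, poly, cfg))
            if not losses:
                continue
            loss = losses[0]
            for extra in losses[1:]:
                loss = loss + extra
            loss = loss * (1.0 / len(losses))
            loss.backward()
            total += float(loss.data)
            count += 1
            pending += 1
            if pending >= train_cfg.batch_size:
                opt.step()
                opt.zero_grad()
                pending = 0
        if pending:
            opt.step()
            opt.zero_grad()
        history.append((epoch, total / max(count, 1)))
        if progress is not None:
            progress(epoch, history[-1][1])
    return params, history


def evaluate_snake(params: dict, dataset, cfg: SnakeConfig, split: str = "val"):
    """Oracle-box evaluation: mask IoU of deformed contours against ground truth.

    Returns mean/median IoU of the final contour and per-iteration IoU lists,
    so convergence across the deformation rounds can be inspected.
    """
    per_iter: list[list[float]] = [[] for _ in range(cfg.iterations)]
    for image_id in dataset.image_ids(split):
        im = dataset.image_by_id(image_id)
        anns = [a for a in dataset.annotations_for(image_id)
                if a["bbox"][2] >= 6 and a["bbox"][3] >= 6]
        if not anns:
            continue
        grid = extract_features(params, im["pixels"], cfg)
        for ann in anns:
            x, y, w, h = ann["bbox"]
            box = BoundingBox(x, y, x + w, y + h)
            contours = segment_instance(box, grid, params, cfg, return_all=True)
            gt_mask = geometry.contour_to_mask(
                geometry.coco_to_contour(ann["segmentation"][0]),
                im["height"], im["width"])
            for it, ct in enumerate(contours):
                pred_mask = geometry.contour_to_mask(ct, im["height"], im["width"])
                per_iter[it].append(geometry.mask_iou(pred_mask, gt_mask))
    final = per_iter[-1]
    return {
        "mean_iou": float(np.mean(final)) if final else 0.0,
        "median_iou": float(np.median(final)) if final else 0.0,
        "per_iteration_median": [float(np.median(v)) if v else 0.0 for v in per_iter],
        "per_iteration_mean": [float(np.mean(v)) if v else 0.0 for v in per_iter],
        "n_instances": len(final),
    }


def save_params(params: dict, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump({k: v.data for k, v in params.items()}, fh)


def load_params(path) -> dict:
    with open(path, "rb") as fh:
        raw = pickle.load(fh)
    return {k: Tensor(v, requires_grad=True) for k, v in raw.items()}
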