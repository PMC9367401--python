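"""Few-shot object detector: backbone → RPN → ROI pooling → FC → box predictor.

Desk-scale analogue of a two-stage detector trained with the two-stage
few-shot strategy:

* **base training** — abundant images of the *base* classes train every
  parameter (backbone, RPN, FC feature layers, box classifier, box
  regressor) with SGD at the base learning rate;
* **fine-tuning** — the feature extractor (backbone + RPN + FC) is frozen
  bitwise; the box predictor gets freshly initialized rows for the *novel*
  classes and only the predictor is updated, at the fine-tuning learning
  rate, on a small balanced n-shot subset covering base and novel classes.

Because the extractor is frozen, fine-tuning caches each subset image's ROI
features once and trains the two linear heads on that fixed design matrix,
which is what makes whole n-shot grids tractable on one CPU.

The backbone is a small strided convolutional network (3 conv layers,
stride 8) with a single-scale RPN over 9 anchors (3 scales x 3 aspect
ratios) — structurally faithful to the backbone/RPN/FC-vs-predictor split
while remaining CPU-trainable.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np

from .config import TrainConfig
from .data import SyntheticDataset, DatasetManifest
from .evaluation import Detection
from .geometry import BoundingBox
from .nn import (
    SGD,
    Tensor,
    bilinear_sample,
    concat,
    conv2d,
    linear,
    relu,
    smooth_l1,
    softmax_cross_entropy,
    take_rows,
    transpose2d,
)

__all__ = [
    "ClassSplit",
    "DetectorModel",
    "split_base_novel",
    "build_nshot_subset",
    "filter_to_classes",
    "init_detector",
    "base_train",
    "fine_tune",
    "detect",
    "oracle_detections",
    "extractor_checksums",
    "save_model",
    "load_model",
]

_STRIDE = 8
_FC_DIM = 128
_ROI_GRID = 4
_BACKBONE_CH = 48


@dataclass(frozen=True)
class ClassSplit:
    """Disjoint base/novel category-id partition."""

    base_classes: tuple
    novel_classes: tuple

    def __post_init__(self) -> None:
        if set(self.base_classes) & set(self.novel_classes):
            raise ValueError("base and novel classes overlap")


def split_base_novel(categories, ratio=(3, 1), seed: int = 0) -> ClassSplit:
    """Randomly partition category ids into base and novel at the given ratio.

    Novel gets ``floor(n * novel_part / (base_part + novel_part))`` classes
    (at least one), the remainder is base; 12 categories at 3:1 give 9 base
    and 3 novel.  Deterministic in ``seed``.
    """
    cats = sorted(int(c) for c in categories)
    if len(cats) < 2:
        raise ValueError("need at least 2 categories to split")
    rb, rn = ratio
    n_novel = max(1, int(len(cats) * rn / (rb + rn)))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(cats))
    novel = tuple(sorted(cats[i] for i in perm[:n_novel]))
    base = tuple(sorted(cats[i] for i in perm[n_novel:]))
    return ClassSplit(base_classes=base, novel_classes=novel)


def _subset(dataset: SyntheticDataset, image_ids) -> SyntheticDataset:
    ids = set(image_ids)
    return SyntheticDataset(
        images=[im for im in dataset.images if im["id"] in ids],
        annotations=[a for a in dataset.annotations if a["image_id"] in ids],
        categories=dataset.categories,
        manifest=DatasetManifest(rows={}, split_ratio=dataset.manifest.split_ratio),
    )


def filter_to_classes(dataset: SyntheticDataset, class_ids, split: str | None = "train") -> SyntheticDataset:
    """Images (of one split) whose annotations all belong to ``class_ids``."""
    keep = set(class_ids)
    ids = []
    for im in dataset.images:
        if split is not None and im["split"] != split:
            continue
        anns = dataset.annotations_for(im["id"])
        if anns and all(a["category_id"] in keep for a in anns):
            ids.append(im["id"])
    return _subset(dataset, ids)


def build_nshot_subset(dataset: SyntheticDataset, split: ClassSplit, n: int,
                       seed: int = 0) -> SyntheticDataset:
    """Balanced fine-tuning subset: exactly n training images per class.

    Images are drawn without replacement from the training split, per class
    over base ∪ novel; a class with fewer than n images raises a data error
    naming it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    used: set[int] = set()
    name_of = {c["id"]: c["name"] for c in dataset.categories}
    for cat in list(split.base_classes) + list(split.novel_classes):
        pool = sorted(
            im["id"] for im in dataset.images
            if im["split"] == "train" and im["id"] not in used
            and any(a["category_id"] == cat for a in dataset.annotations_for(im["id"]))
        )
        if len(pool) < n:
            raise ValueError(
                f"class {name_of.get(cat, cat)!r} has only {len(pool)} training images, "
                f"need {n} for {n}-shot")
        pick = rng.choice(len(pool), size=n, replace=False)
        for i in sorted(pick):
            chosen.append(pool[i])
            used.add(pool[i])
    return _subset(dataset, chosen)


# --- anchors and box arithmetic -------------------------------------------------

def _anchor_shapes() -> np.ndarray:
    shapes = []
    for scale in (16.0, 32.0, 64.0):
        for ratio in (0.5, 1.0, 2.0):
            shapes.append([scale * np.sqrt(ratio), scale / np.sqrt(ratio)])
    return np.asarray(shapes)


def _anchor_boxes(fh: int, fw: int) -> np.ndarray:
    """(fh*fw*A, 4) corner-form anchors, row-major cells, anchor-minor."""
    shapes = _anchor_shapes()
    cy, cx = np.mgrid[0:fh, 0:fw].astype(float)
    cx = (cx.ravel() + 0.5) * _STRIDE
    cy = (cy.ravel() + 0.5) * _STRIDE
    boxes = np.empty((fh * fw, len(shapes), 4))
    for a, (w, h) in enumerate(shapes):
        boxes[:, a, 0] = cx - w / 2
        boxes[:, a, 1] = cy - h / 2
        boxes[:, a, 2] = cx + w / 2
        boxes[:, a, 3] = cy + h / 2
    return boxes.reshape(-1, 4)


def _encode_deltas(src: np.ndarray, gt: np.ndarray) -> np.ndarray:
    sw, sh = src[:, 2] - src[:, 0], src[:, 3] - src[:, 1]
    gw, gh = gt[:, 2] - gt[:, 0], gt[:, 3] - gt[:, 1]
    return np.stack([
        ((gt[:, 0] + gt[:, 2]) - (src[:, 0] + src[:, 2])) / (2 * sw),
        ((gt[:, 1] + gt[:, 3]) - (src[:, 1] + src[:, 3])) / (2 * sh),
        np.log(gw / sw),
        np.log(gh / sh),
    ], axis=1)


def _apply_deltas(src: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    sw, sh = src[:, 2] - src[:, 0], src[:, 3] - src[:, 1]
    cx = (src[:, 0] + src[:, 2]) / 2 + deltas[:, 0] * sw
    cy = (src[:, 1] + src[:, 3]) / 2 + deltas[:, 1] * sh
    w = sw * np.exp(np.clip(deltas[:, 2], -4, 4))
    h = sh * np.exp(np.clip(deltas[:, 3], -4, 4))
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def _iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    ix0 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy0 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix1 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix1 - ix0, 0, None) * np.clip(iy1 - iy0, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> list[int]:
    """Greedy non-maximum suppression; ties broken by score then input index."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    keep: list[int] = []
    suppressed = np.zeros(len(scores), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(int(i))
        ious = _iou_matrix(boxes[i : i + 1], boxes)[0]
        suppressed |= ious > iou_threshold
        suppressed[i] = True
    return keep


# --- model ----------------------------------------------------------------------

@dataclass
class DetectorModel:
    extractor: dict            # backbone + RPN + FC weights (frozen at fine-tuning)
    predictor: dict            # box classifier (per-class rows) + box regressor
    classes: list = field(default_factory=list)  # category id per classifier row (after background)
    base_trained: bool = False

    def n_rows(self) -> int:
        return self.predictor["cls.w"].data.shape[1]


def init_detector(n_classes: int, seed: int = 0) -> DetectorModel:
    """Fresh detector with classifier rows for ``n_classes`` plus background."""
    rng = np.random.default_rng(seed)

    def he_conv(*shape):  # (C_out, C_in, kh, kw): fan-in over the receptive field
        fan_in = int(np.prod(shape[1:]))
        return Tensor(rng.standard_normal(shape) * np.sqrt(2.0 / fan_in),
                      requires_grad=True)

    def he_lin(d_in, d_out, gain=1.0):  # (d_in, d_out) row-major dense weights
        return Tensor(rng.standard_normal((d_in, d_out)) * gain * np.sqrt(2.0 / d_in),
                      requires_grad=True)

    def zeros(*shape):
        return Tensor(np.zeros(shape), requires_grad=True)

    ext = {
        "bb.c1.w": he_conv(16, 3, 3, 3), "bb.c1.b": zeros(16),
        "bb.c2.w": he_conv(32, 16, 3, 3), "bb.c2.b": zeros(32),
        "bb.c3.w": he_conv(_BACKBONE_CH, 32, 3, 3), "bb.c3.b": zeros(_BACKBONE_CH),
        "rpn.conv.w": he_conv(64, _BACKBONE_CH, 3, 3), "rpn.conv.b": zeros(64),
        "rpn.obj.w": he_lin(64, 9, gain=0.1), "rpn.obj.b": zeros(9),
        "rpn.reg.w": he_lin(64, 36, gain=0.1), "rpn.reg.b": zeros(36),
        "fc.w": he_lin(_BACKBONE_CH * _ROI_GRID * _ROI_GRID, _FC_DIM), "fc.b": zeros(_FC_DIM),
    }
    pred = {
        "cls.w": Tensor(rng.standard_normal((_FC_DIM, n_classes + 1)) * 0.01, requires_grad=True),
        "cls.b": zeros(n_classes + 1),
        "reg.w": Tensor(rng.standard_normal((_FC_DIM, 4)) * 0.01, requires_grad=True),
        "reg.b": zeros(4),
    }
    return DetectorModel(extractor=ext, predictor=pred)


def _backbone(ext: dict, image: np.ndarray) -> Tensor:
    x = Tensor(np.ascontiguousarray(image.transpose(2, 0, 1), dtype=np.float64))
    x = relu(conv2d(x, ext["bb.c1.w"], ext["bb.c1.b"], stride=2, pad=1))
    x = relu(conv2d(x, ext["bb.c2.w"], ext["bb.c2.b"], stride=2, pad=1))
    x = relu(conv2d(x, ext["bb.c3.w"], ext["bb.c3.b"], stride=2, pad=1))
    return x  # (C, H/8, W/8)


def _rpn_heads(ext: dict, feat: Tensor):
    h = relu(conv2d(feat, ext["rpn.conv.w"], ext["rpn.conv.b"], stride=1, pad=1))
    c, fh, fw = h.data.shape
    cols = transpose2d(h.reshape(c, fh * fw))          # (L, 64), row-major cells
    obj = linear(cols, ext["rpn.obj.w"], ext["rpn.obj.b"])    # (L, 9)
    reg = linear(cols, ext["rpn.reg.w"], ext["rpn.reg.b"])    # (L, 36)
    return obj, reg, (fh, fw)


def _roi_features(ext: dict, feat: Tensor, boxes: np.ndarray) -> Tensor:
    """ROI pooling: 4x4 bilinear grid per box on the backbone map, then FC."""
    n = len(boxes)
    g = _ROI_GRID
    fx = (np.arange(g) + 0.5) / g
    pts = np.empty((n * g * g, 2))
    for i, (x0, y0, x1, y1) in enumerate(boxes):
        xs = x0 + fx * (x1 - x0)
        ys = y0 + fx * (y1 - y0)
        gx, gy = np.meshgrid(xs, ys)
        pts[i * g * g : (i + 1) * g * g, 0] = gx.ravel() / _STRIDE - 0.5
        pts[i * g * g : (i + 1) * g * g, 1] = gy.ravel() / _STRIDE - 0.5
    sampled = bilinear_sample(feat, pts)               # (n*g*g, C)
    flat = sampled.reshape(n, g * g * feat.data.shape[0])
    return relu(linear(flat, ext["fc.w"], ext["fc.b"]))


def _proposals(obj_data: np.ndarray, reg_data: np.ndarray, shape, image_size,
               pre_nms: int = 200, post_nms: int = 24) -> np.ndarray:
    fh, fw = shape
    anchors = _anchor_boxes(fh, fw)
    scores = obj_data.reshape(-1)          # (L*9,), cell-major
    deltas = reg_data.reshape(-1, 4)
    order = np.argsort(-scores, kind="stable")[:pre_nms]
    boxes = _apply_deltas(anchors[order], deltas[order])
    w, h = image_size
    boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, w)
    boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, h)
    ok = (boxes[:, 2] - boxes[:, 0] > 2) & (boxes[:, 3] - boxes[:, 1] > 2)
    boxes, sc = boxes[ok], scores[order][ok]
    keep = nms(boxes, sc, 0.7)[:post_nms]
    return boxes[keep]


def _binary_ce(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Logistic loss built from the 2-way softmax: label 1 = object."""
    zeros = Tensor(np.zeros_like(logits.data))
    two = concat([zeros, logits], axis=1)
    return softmax_cross_entropy(two, labels)


def _rpn_loss(obj: Tensor, reg: Tensor, shape, gt_boxes: np.ndarray, rng) -> Tensor:
    fh, fw = shape
    anchors = _anchor_boxes(fh, fw)
    if len(gt_boxes) == 0:
        sel = rng.choice(len(anchors), 16, replace=False)
        return _binary_ce(take_rows(obj.reshape(fh * fw * 9, 1), sel),
                          np.zeros(16, dtype=int))
    iou = _iou_matrix(anchors, gt_boxes)
    best = iou.max(axis=1)
    pos = best >= 0.5
    pos[np.argmax(iou, axis=0)] = True     # best anchor per gt is always positive
    neg = best < 0.3
    neg &= ~pos
    pos_idx = np.flatnonzero(pos)
    neg_idx = np.flatnonzero(neg)
    if len(pos_idx) > 16:
        pos_idx = pos_idx[rng.choice(len(pos_idx), 16, replace=False)]
    n_neg = min(len(neg_idx), max(16, len(pos_idx)))
    neg_idx = neg_idx[rng.choice(len(neg_idx), n_neg, replace=False)]
    sel = np.concatenate([pos_idx, neg_idx])
    labels = np.concatenate([np.ones(len(pos_idx), int), np.zeros(len(neg_idx), int)])
    obj_flat = obj.reshape(fh * fw * 9, 1)
    loss = _binary_ce(take_rows(obj_flat, sel), labels)
    if len(pos_idx):
        match = np.argmax(iou[pos_idx], axis=1)
        targets = _encode_deltas(anchors[pos_idx], gt_boxes[match])
        reg_flat = reg.reshape(fh * fw * 36)
        idx = (pos_idx // 9)[:, None] * 36 + (pos_idx % 9)[:, None] * 4 + np.arange(4)
        pred = take_rows(reg_flat, idx.ravel()).reshape(len(pos_idx), 4)
        loss = loss + smooth_l1(pred, targets, beta=1.0 / 9.0)
    return loss


def _roi_targets(proposals: np.ndarray, gt_boxes: np.ndarray, gt_labels: np.ndarray,
                 row_of: dict, rng, max_fg: int = 8, max_bg: int = 8):
    iou = _iou_matrix(proposals, gt_boxes)
    best = iou.max(axis=1)
    match = iou.argmax(axis=1)
    fg = np.flatnonzero(best >= 0.5)
    bg = np.flatnonzero(best < 0.5)
    if len(fg) > max_fg:
        fg = fg[rng.choice(len(fg), max_fg, replace=False)]
    if len(bg) > max_bg:
        bg = bg[rng.choice(len(bg), max_bg, replace=False)]
    sel = np.concatenate([fg, bg])
    labels = np.zeros(len(sel), dtype=int)
    labels[: len(fg)] = [row_of[int(gt_labels[m])] for m in match[fg]]
    deltas = _encode_deltas(proposals[fg], gt_boxes[match[fg]]) if len(fg) else np.zeros((0, 4))
    return sel, labels, deltas, len(fg)


def _gt_arrays(dataset: SyntheticDataset, image_id: int):
    anns = dataset.annotations_for(image_id)
    boxes = np.array([[a["bbox"][0], a["bbox"][1],
                       a["bbox"][0] + a["bbox"][2], a["bbox"][1] + a["bbox"][3]]
                      for a in anns]) if anns else np.zeros((0, 4))
    labels = np.array([a["category_id"] for a in anns], dtype=int)
    return boxes, labels


def _jittered(gt_boxes: np.ndarray, rng, image_size, n: int = 2) -> np.ndarray:
    """Noisy copies of gt boxes so the ROI head sees near-miss positives."""
    out = []
    w, h = image_size
    for _ in range(n):
        bw = gt_boxes[:, 2] - gt_boxes[:, 0]
        bh = gt_boxes[:, 3] - gt_boxes[:, 1]
        noise = rng.normal(0, 0.08, gt_boxes.shape) * np.stack([bw, bh, bw, bh], axis=1)
        j = gt_boxes + noise
        j[:, 0::2] = np.clip(j[:, 0::2], 0, w)
        j[:, 1::2] = np.clip(j[:, 1::2], 0, h)
        ok = (j[:, 2] - j[:, 0] > 2) & (j[:, 3] - j[:, 1] > 2)
        out.append(j[ok])
    return np.vstack(out) if out else np.zeros((0, 4))


def _clip_gradients(params: dict, max_norm: float) -> None:
    """Global gradient-norm clipping (stabilizes early SGD on small batches)."""
    total = np.sqrt(sum(float((p.grad ** 2).sum())
                        for p in params.values() if p.grad is not None))
    if total > max_norm:
        scale = max_norm / total
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale


def base_train(model: DetectorModel, base_dataset: SyntheticDataset,
               cfg: TrainConfig, progress=None) -> DetectorModel:
    """Train all detector parameters on abundant base-class images.

    Raises if the dataset contains annotations outside the classifier's
    classes.  Returns the same model, with ``base_trained`` set and a
    ``loss_history`` attribute of per-epoch mean losses.
    """
    if model.classes:
        allowed = set(model.classes)
        for a in base_dataset.annotations:
            if a["category_id"] not in allowed:
                raise ValueError(
                    f"annotation of class {a['category_id']} is not a base class")
    else:
        cats = sorted({a["category_id"] for a in base_dataset.annotations})
        if len(cats) + 1 != model.n_rows():
            raise ValueError(
                f"classifier has {model.n_rows()} rows but dataset has {len(cats)} classes")
        model.classes = cats
    row_of = {c: i + 1 for i, c in enumerate(model.classes)}
    params = {**model.extractor, **model.predictor}
    opt = SGD(params, lr=cfg.lr_base, momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    image_ids = [im["id"] for im in base_dataset.images if base_dataset.annotations_for(im["id"])]
    history = []
    step = 0
    warmup_steps = max(len(image_ids), 1)  # linear warmup over the first epoch
    for epoch in range(cfg.epochs_base):
        order = rng.permutation(len(image_ids))
        decay = 0.1 if epoch >= cfg.epochs_base - 2 else 1.0
        total, count, pending = 0.0, 0, 0
        opt.zero_grad()
        for pos in order:
            step += 1
            opt.lr = cfg.lr_base * decay * (0.1 + 0.9 * min(step / warmup_steps, 1.0))
            im = base_dataset.image_by_id(image_ids[pos])
            gt_boxes, gt_labels = _gt_arrays(base_dataset, im["id"])
            feat = _backbone(model.extractor, im["pixels"])
            obj, reg, shape = _rpn_heads(model.extractor, feat)
            loss = _rpn_loss(obj, reg, shape, gt_boxes, rng)
            props = _proposals(obj.data, reg.data, shape, (im["width"], im["height"]))
            rois = np.vstack([props, gt_boxes,
                              _jittered(gt_boxes, rng, (im["width"], im["height"]))])
            sel, labels, deltas, n_fg = _roi_targets(rois, gt_boxes, gt_labels, row_of, rng)
            roi_feat = _roi_features(model.extractor, feat, rois[sel])
            logits = linear(roi_feat, model.predictor["cls.w"], model.predictor["cls.b"])
            loss = loss + softmax_cross_entropy(logits, labels)
            if n_fg:
                fg_feat = take_rows(roi_feat, np.arange(n_fg))
                pred_deltas = linear(fg_feat, model.predictor["reg.w"], model.predictor["reg.b"])
                loss = loss + smooth_l1(pred_deltas, deltas, beta=1.0 / 9.0)
            loss.backward()
            total += float(loss.data)
            count += 1
            pending += 1
            if pending >= cfg.batch_size:
                _clip_gradients(params, 5.0)
                opt.step()
                opt.zero_grad()
                pending = 0
        if pending:
            _clip_gradients(params, 5.0)
            opt.step()
            opt.zero_grad()
        history.append((epoch, total / max(count, 1)))
        if progress is not None:
            progress(epoch, history[-1][1])
    model.base_trained = True
    model.loss_history = history
    return model


def fine_tune(model: DetectorModel, subset: SyntheticDataset, split: ClassSplit,
              cfg: TrainConfig) -> DetectorModel:
    """Predictor-only fine-tuning on a balanced n-shot subset.

    The classifier grows randomly initialized rows (std 0.01, seeded) for the
    novel classes; the feature extractor is untouched — ROI features are
    computed once per image under the frozen extractor and the classifier +
    regressor are trained on the cached features at ``cfg.lr_finetune``.
    """
    if not model.base_trained:
        raise ValueError("fine_tune requires a base-trained model")
    if list(model.classes) != sorted(split.base_classes):
        raise ValueError("model base classes do not match the split")
    rng = np.random.default_rng(cfg.seed + 1)
    novel = sorted(split.novel_classes)
    old_w, old_b = model.predictor["cls.w"].data, model.predictor["cls.b"].data
    new_w = np.concatenate([old_w, rng.normal(0, 0.01, (old_w.shape[0], len(novel)))], axis=1)
    new_b = np.concatenate([old_b, np.zeros(len(novel))])
    model.predictor["cls.w"] = Tensor(new_w, requires_grad=True)
    model.predictor["cls.b"] = Tensor(new_b, requires_grad=True)
    model.classes = list(model.classes) + novel
    row_of = {c: i + 1 for i, c in enumerate(model.classes)}

    # cache ROI features under the frozen extractor
    feats, labels, deltas_t, fg_rows = [], [], [], []
    offset = 0
    for im in subset.images:
        gt_boxes, gt_labels = _gt_arrays(subset, im["id"])
        if len(gt_boxes) == 0:
            continue
        feat = _backbone(model.extractor, im["pixels"])
        obj, reg, shape = _rpn_heads(model.extractor, feat)
        props = _proposals(obj.data, reg.data, shape, (im["width"], im["height"]))
        rois = np.vstack([props, gt_boxes,
                          _jittered(gt_boxes, rng, (im["width"], im["height"]), n=3)])
        sel, lab, deltas, n_fg = _roi_targets(rois, gt_boxes, gt_labels, row_of, rng,
                                              max_fg=12, max_bg=12)
        roi = _roi_features(model.extractor, feat, rois[sel]).data
        feats.append(roi)
        labels.append(lab)
        deltas_t.append(deltas)
        fg_rows.extend(range(offset, offset + n_fg))
        offset += len(sel)
    X = np.vstack(feats)
    y = np.concatenate(labels)
    D = np.vstack(deltas_t) if deltas_t else np.zeros((0, 4))
    fg_rows = np.asarray(fg_rows, dtype=int)

    opt = SGD(model.predictor, lr=cfg.lr_finetune, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    n = X.shape[0]
    bs = 64
    history = []
    for epoch in range(cfg.epochs_finetune):
        order = rng.permutation(n)
        total, steps = 0.0, 0
        for s in range(0, n, bs):
            idx = order[s : s + bs]
            xb = Tensor(X[idx])
            logits = linear(xb, model.predictor["cls.w"], model.predictor["cls.b"])
            loss = softmax_cross_entropy(logits, y[idx])
            fg_in_batch = np.flatnonzero(np.isin(idx, fg_rows))
            if len(fg_in_batch):
                pos_map = {r: i for i, r in enumerate(fg_rows)}
                rows = idx[fg_in_batch]
                fg_feat = Tensor(X[rows])
                pred = linear(fg_feat, model.predictor["reg.w"], model.predictor["reg.b"])
                loss = loss + smooth_l1(pred, D[[pos_map[r] for r in rows]], beta=1.0 / 9.0)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data)
            steps += 1
        history.append((epoch, total / max(steps, 1)))
    model.finetune_history = history
    return model


def detect(model: DetectorModel, image: np.ndarray, score_threshold: float = 0.05,
           nms_iou: float = 0.5, image_id: int = -1, max_det: int = 20) -> list[Detection]:
    """Detect objects in one image: proposals → heads → per-class NMS.

    Returns detections sorted by descending score (index tie-break).
    """
    if not model.base_trained:
        raise ValueError("detect requires a trained model")
    h, w = image.shape[:2]
    if h < _STRIDE or w < _STRIDE:
        raise ValueError("image smaller than the backbone stride")
    feat = _backbone(model.extractor, image)
    obj, reg, shape = _rpn_heads(model.extractor, feat)
    props = _proposals(obj.data, reg.data, shape, (w, h), pre_nms=300, post_nms=50)
    if len(props) == 0:
        return []
    roi_feat = _roi_features(model.extractor, feat, props).data
    logits = roi_feat @ model.predictor["cls.w"].data + model.predictor["cls.b"].data
    z = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    deltas = roi_feat @ model.predictor["reg.w"].data + model.predictor["reg.b"].data
    boxes = _apply_deltas(props, deltas)
    boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, w)
    boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, h)
    detections: list[Detection] = []
    for row, cat in enumerate(model.classes):
        scores = probs[:, row + 1]
        ok = np.flatnonzero(scores >= score_threshold)
        ok = ok[(boxes[ok, 2] - boxes[ok, 0] > 2) & (boxes[ok, 3] - boxes[ok, 1] > 2)]
        if len(ok) == 0:
            continue
        keep = nms(boxes[ok], scores[ok], nms_iou)
        for k in keep:
            i = ok[k]
            detections.append(Detection(
                box=BoundingBox(*boxes[i]), category_id=cat,
                score=float(scores[i]), image_id=image_id))
    detections.sort(key=lambda d: -d.score)
    return detections[:max_det]


def oracle_detections(dataset: SyntheticDataset, image_id: int) -> list[Detection]:
    """Ground-truth boxes injected as unit-score detections (oracle-detector mode)."""
    out = []
    for a in dataset.annotations_for(image_id):
        x, y, w, h = a["bbox"]
        out.append(Detection(box=BoundingBox(x, y, x + w, y + h),
                             category_id=a["category_id"], score=1.0, image_id=image_id))
    return out


def extractor_checksums(model: DetectorModel) -> dict:
    """Bitwise digests of every feature-extractor tensor (freeze auditing)."""
    import hashlib

    return {k: hashlib.sha256(np.ascontiguousarray(v.data).tobytes()).hexdigest()
            for k, v in model.extractor.items()}


def save_state(model: DetectorModel) -> dict:
    """Deep-copied in-memory snapshot (restart point for per-shot fine-tuning)."""
    return {
        "extractor": {k: v.data.copy() for k, v in model.extractor.items()},
        "predictor": {k: v.data.copy() for k, v in model.predictor.items()},
        "classes": list(model.classes),
        "base_trained": model.base_trained,
    }


def load_state(state: dict) -> DetectorModel:
    return DetectorModel(
        extractor={k: Tensor(v.copy(), requires_grad=True) for k, v in state["extractor"].items()},
        predictor={k: Tensor(v.copy(), requires_grad=True) for k, v in state["predictor"].items()},
        classes=list(state["classes"]),
        base_trained=state["base_trained"],
    )


def save_model(model: DetectorModel, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump({
            "extractor": {k: v.data for k, v in model.extractor.items()},
            "predictor": {k: v.data for k, v in model.predictor.items()},
            "classes": model.classes,
            "base_trained": model.base_trained,
        }, fh)


def load_model(path) -> DetectorModel:
    with open(path, "rb") as fh:
        raw = pickle.load(fh)
    return DetectorModel(
        extractor={k: Tensor(v, requires_grad=True) for k, v in raw["extractor"].items()},
        predictor={k: Tensor(v, requires_grad=True) for k, v in raw["predictor"].items()},
        classes=raw["classes"],
        base_trained=raw["base_trained"],
    )
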