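"""Seeded synthetic camera-trap scenes with COCO-style ground truth.

Real camera-trap imagery of wild mammals cannot be bundled, so every stage of
the pipeline trains and evaluates on generated scenes instead.  Each "species"
is a :class:`ShapeClass`: a simple closed curve drawn from a truncated radial
Fourier series r(θ) = R·(1 + Σ aₖ cos(kθ + φₖ)) with class-specific harmonic
frequencies, amplitudes and texture, composited onto a textured background.
Because r(θ) > 0 the curves are star-shaped and therefore simple, and the
ground-truth polygon, box, area and extreme points are all known analytically
from the dense contour.

Four challenge regimes mirror the hard cases of field imagery: multiple small
targets, overlapping bodies (later instances occlude earlier ones), camouflage
(foreground texture drawn from background statistics with a small contrast
offset), and truncation (bodies clipped by the image border).

Everything is a pure function of its seed: scene seeds are derived from the
dataset seed with ``numpy.random.SeedSequence`` spawn keys, so regenerating a
dataset reproduces it byte for byte.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon, box as shapely_box
from shapely.ops import unary_union

from . import geometry

__all__ = [
    "ShapeClass",
    "InstanceSpec",
    "SceneSpec",
    "DatasetManifest",
    "SyntheticDataset",
    "default_shape_classes",
    "make_shape",
    "sample_scene_spec",
    "render_scene",
    "generate_dataset",
    "manifest_summary",
    "radial_signature",
    "save_coco",
    "load_coco",
]

_CLASS_NAMES = [
    "bear", "cow", "cheetah", "deer", "elephant", "giraffe",
    "horse", "kangaroo", "koala", "lion", "tiger", "zebra",
]

# (harmonic frequencies, amplitudes): distinct per class so that a simple
# radial-signature classifier can separate them — the few-shot task must be
# learnable before the detector gets any credit for learning it.
_CLASS_HARMONICS = [
    ((2,), (0.28,)),
    ((3,), (0.26,)),
    ((4,), (0.22,)),
    ((5,), (0.20,)),
    ((2, 4), (0.18, 0.12)),
    ((3, 5), (0.18, 0.12)),
    ((2, 3), (0.16, 0.16)),
    ((4, 5), (0.15, 0.12)),
    ((2, 5), (0.20, 0.10)),
    ((3, 4), (0.14, 0.16)),
    ((6,), (0.18,)),
    ((2, 6), (0.20, 0.10)),
]

_CLASS_COLORS = [
    (0.35, 0.22, 0.12), (0.82, 0.80, 0.74), (0.85, 0.70, 0.30),
    (0.55, 0.38, 0.20), (0.45, 0.45, 0.48), (0.88, 0.62, 0.25),
    (0.30, 0.20, 0.35), (0.60, 0.45, 0.35), (0.50, 0.52, 0.45),
    (0.75, 0.55, 0.30), (0.80, 0.42, 0.15), (0.90, 0.88, 0.85),
]

_BG_COLOR = np.array([0.32, 0.40, 0.24])  # scrubland green-brown


@dataclass(frozen=True)
class ShapeClass:
    """A pseudo-species: radial-harmonic outline parameters plus texture."""

    class_id: int
    name: str
    frequencies: tuple
    amplitudes: tuple
    color: tuple
    noise_scale: float = 0.05
    amp_jitter: float = 0.15  # relative amplitude jitter per instance


def default_shape_classes(n_classes: int = 12) -> list[ShapeClass]:
    if not (2 <= n_classes <= 12):
        raise ValueError("between 2 and 12 shape classes are defined")
    return [
        ShapeClass(
            class_id=i + 1,
            name=_CLASS_NAMES[i],
            frequencies=_CLASS_HARMONICS[i][0],
            amplitudes=_CLASS_HARMONICS[i][1],
            color=_CLASS_COLORS[i],
            noise_scale=0.03 + 0.005 * (i % 5),
        )
        for i in range(n_classes)
    ]


def make_shape(cls: ShapeClass, scale: float, seed: int, n_dense: int = 180) -> np.ndarray:
    """A simple closed contour for one instance, centered at the origin.

    ``scale`` is the base radius R in pixels.  Returns an (n_dense, 2)
    clockwise contour.  Harmonic amplitudes are jittered and phases drawn
    from ``seed``; if the (theoretically impossible for r > 0, but cheap to
    check) self-intersection test fails, the draw is retried with a
    perturbed seed a bounded number of times.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    for attempt in range(5):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(attempt,)))
        theta = np.linspace(0.0, 2.0 * np.pi, n_dense, endpoint=False)
        r = np.full(n_dense, 1.0)
        for f, a in zip(cls.frequencies, cls.amplitudes):
            amp = a * (1.0 + cls.amp_jitter * (2.0 * rng.random() - 1.0))
            r += amp * np.cos(f * theta + rng.random() * 2.0 * np.pi)
        r = np.maximum(r, 0.05) * scale
        verts = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
        if Polygon(verts).is_valid:
            return geometry.ensure_clockwise(verts)
    raise geometry.InvalidGeometryError("could not generate a simple contour")


@dataclass(frozen=True)
class InstanceSpec:
    class_id: int
    center: tuple          # (x, y) pixels
    scale: float           # base radius, pixels
    shape_seed: int


@dataclass
class SceneSpec:
    width: int
    height: int
    instances: list
    small_targets: bool = False
    overlap: bool = False
    camouflage: bool = False
    truncation: bool = False

    def __post_init__(self) -> None:
        if not self.instances:
            raise ValueError("a scene needs at least one instance")


def sample_scene_spec(classes, primary_class_id: int, rng: np.random.Generator,
                      image_size: int = 128, regime_prob: float = 0.15) -> SceneSpec:
    """Draw a random scene layout for one primary class.

    All instances in a scene share the primary class (groups in camera-trap
    frames are usually conspecific).  Each challenge regime is switched on
    independently with probability ``regime_prob``.
    """
    s = image_size
    small = rng.random() < regime_prob
    overlap = rng.random() < regime_prob
    camo = rng.random() < regime_prob
    trunc = rng.random() < regime_prob
    if small:
        n_inst = int(rng.integers(3, 5))
        scales = rng.uniform(0.07, 0.10, n_inst) * s
    elif overlap:
        n_inst = 2
        scales = rng.uniform(0.16, 0.24, n_inst) * s
    else:
        n_inst = int(rng.integers(1, 3))
        scales = rng.uniform(0.18, 0.26, n_inst) * s
    # max radius = scale * (1 + Σ amplitudes + jitter) — keep centers inside
    reach = scales * 1.5
    centers = []
    for i in range(n_inst):
        lo, hi = reach[i], s - reach[i]
        if hi <= lo:
            lo, hi = s * 0.4, s * 0.6
        centers.append(np.array([rng.uniform(lo, hi), rng.uniform(lo, hi)]))
    if overlap and n_inst >= 2:
        # put the second body partially on top of the first
        d = 0.55 * (reach[0] + reach[1])
        ang = rng.uniform(0, 2 * np.pi)
        centers[1] = centers[0] + d * np.array([np.cos(ang), np.sin(ang)])
    if trunc:
        # push one body onto the border so its polygon is clipped; the offset
        # stays below the minimum guaranteed body radius (~0.63 * scale for
        # the strongest harmonics), so part of the body always remains visible
        c = centers[0]
        edge = int(rng.integers(4))
        off = rng.uniform(0.2, 0.55) * scales[0]
        if edge == 0:
            c[0] = -off  # left border
        elif edge == 1:
            c[0] = s + off
        elif edge == 2:
            c[1] = -off
        else:
            c[1] = s + off
        c[0] = float(np.clip(c[0], -reach[0] * 0.6, s + reach[0] * 0.6))
        c[1] = float(np.clip(c[1], -reach[0] * 0.6, s + reach[0] * 0.6))
        centers[0] = c
    instances = [
        InstanceSpec(
            class_id=primary_class_id,
            center=(float(centers[i][0]), float(centers[i][1])),
            scale=float(scales[i]),
            shape_seed=int(rng.integers(2**31 - 1)),
        )
        for i in range(n_inst)
    ]
    return SceneSpec(width=s, height=s, instances=instances,
                     small_targets=small, overlap=overlap,
                     camouflage=camo, truncation=trunc)


def _largest_polygon(geom):
    """Largest polygonal component of a shapely geometry, or None."""
    if geom.is_empty:
        return None
    if geom.geom_type == "Polygon":
        return geom
    polys = [g for g in getattr(geom, "geoms", []) if g.geom_type == "Polygon"]
    if not polys:
        return None
    return max(polys, key=lambda p: p.area)


def render_scene(spec: SceneSpec, classes, seed: int):
    """Render a scene spec to an RGB image plus COCO-style annotations.

    Instances are composited back to front, so later instances occlude
    earlier ones; each annotation carries the *visible* polygon (largest
    component after occlusion and border clipping), its tight box, class id
    and exact pixel area.  An instance whose outline misses the frame
    entirely raises ``ValueError``.
    """
    h, w = spec.height, spec.width
    rng = np.random.default_rng(seed)
    by_class = {c.class_id: c for c in classes}

    bg_noise = gaussian_filter(rng.standard_normal((h, w)), sigma=3.0)
    bg_noise /= max(np.abs(bg_noise).max(), 1e-9)
    img = np.empty((h, w, 3))
    img[:] = _BG_COLOR
    img += 0.10 * bg_noise[..., None]
    img += 0.02 * rng.standard_normal((h, w, 3))

    frame = shapely_box(0.0, 0.0, float(w), float(h))
    contours = []
    for inst in spec.instances:
        cls = by_class[inst.class_id]
        local = make_shape(cls, inst.scale, inst.shape_seed)
        contour = local + np.asarray(inst.center)
        if not Polygon(contour).intersects(frame):
            raise ValueError(f"instance of class {inst.class_id} lies fully outside the frame")
        contours.append(contour)

    annotations = []
    for i, (inst, contour) in enumerate(zip(spec.instances, contours)):
        cls = by_class[inst.class_id]
        mask = geometry.contour_to_mask(contour, h, w)
        if spec.camouflage:
            # same background noise field, small brightness offset: the body
            # is barely distinguishable from its surroundings
            tex = _BG_COLOR + 0.10 * bg_noise[..., None] + 0.08
        else:
            color = np.asarray(cls.color) + rng.uniform(-0.03, 0.03, 3)
            tex_noise = gaussian_filter(rng.standard_normal((h, w)), sigma=1.5)
            tex = color + cls.noise_scale * 4.0 * tex_noise[..., None]
        img[mask] = tex[mask] if tex.ndim == 3 else tex

        occluders = [Polygon(contours[j]) for j in range(i + 1, len(contours))]
        visible = Polygon(contour).intersection(frame)
        if occluders:
            visible = visible.difference(unary_union(occluders))
        poly = _largest_polygon(visible)
        if poly is None or poly.area < 4.0:
            continue  # fully hidden bodies get no annotation
        verts = np.asarray(poly.exterior.coords)[:-1]
        verts = geometry.ensure_clockwise(verts)
        x0, y0, x1, y1 = poly.bounds
        if x1 - x0 < 2.0 or y1 - y0 < 2.0:
            continue
        annotations.append({
            "category_id": inst.class_id,
            "bbox": [x0, y0, x1 - x0, y1 - y0],
            "segmentation": [geometry.contour_to_coco(verts)],
            "area": float(poly.area),
            "iscrowd": 0,
        })

    np.clip(img, 0.0, 1.0, out=img)
    return img, annotations


@dataclass
class DatasetManifest:
    """Per-class composition: images, training instances, validation instances."""

    rows: dict = field(default_factory=dict)  # name -> (n_images, n_train_inst, n_val_inst)
    split_ratio: float = 0.85

    def totals(self):
        return manifest_summary(self.rows.values())

    def to_dict(self) -> dict:
        ti, tt, tv = self.totals()
        return {
            "split_ratio": self.split_ratio,
            "classes": {k: list(v) for k, v in self.rows.items()},
            "totals": {"images": ti, "training_instances": tt, "validation_instances": tv},
        }


def manifest_summary(per_class_rows):
    """Column sums of (images, training instances, validation instances) rows."""
    rows = [tuple(int(c) for c in row) for row in per_class_rows]
    for row in rows:
        if len(row) != 3:
            raise ValueError("each manifest row needs exactly 3 counts")
        if any(c < 0 for c in row):
            raise ValueError(f"negative count in manifest row {row}")
    if not rows:
        return (0, 0, 0)
    arr = np.asarray(rows, dtype=np.int64)
    return tuple(int(t) for t in arr.sum(axis=0))


@dataclass
class SyntheticDataset:
    """In-memory dataset: images with pixels, COCO-style annotations, manifest."""

    images: list          # dicts: id, file_name, width, height, split, class_id, pixels
    annotations: list     # COCO-style dicts with id and image_id
    categories: list      # dicts: id, name
    manifest: DatasetManifest

    def image_ids(self, split: str | None = None) -> list:
        return [im["id"] for im in self.images if split is None or im["split"] == split]

    def image_by_id(self, image_id: int) -> dict:
        return self._index()[image_id]

    def _index(self) -> dict:
        if not hasattr(self, "_img_index"):
            self._img_index = {im["id"]: im for im in self.images}
        return self._img_index

    def annotations_for(self, image_id: int) -> list:
        if not hasattr(self, "_ann_index"):
            self._ann_index = {}
            for a in self.annotations:
                self._ann_index.setdefault(a["image_id"], []).append(a)
        return self._ann_index.get(image_id, [])

    def to_coco_dict(self, split: str | None = None) -> dict:
        ids = set(self.image_ids(split))
        return {
            "images": [
                {k: im[k] for k in ("id", "file_name", "width", "height")}
                for im in self.images if im["id"] in ids
            ],
            "annotations": [a for a in self.annotations if a["image_id"] in ids],
            "categories": self.categories,
        }


def generate_dataset(n_classes: int = 12, images_per_class: int = 40,
                     split_ratio: float = 0.85, regime_prob: float = 0.15,
                     seed: int = 0, image_size: int = 128,
                     classes: list | None = None) -> SyntheticDataset:
    """Generate a full dataset: stratified train/eval split, manifest, pixels.

    Per class, the first ``round(split_ratio * images_per_class)`` scenes are
    the training split and the rest the evaluation split.  Scene layouts and
    rendering are derived from ``seed`` through per-scene spawn keys, so the
    output (including annotation JSON) is reproducible bit for bit.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if classes is None:
        classes = default_shape_classes(n_classes)
    n_train = int(round(split_ratio * images_per_class))
    images, annotations = [], []
    rows = {}
    image_id = ann_id = 1
    for cls in classes:
        counts = [0, 0, 0]
        for j in range(images_per_class):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(cls.class_id, j))
            rng = np.random.default_rng(ss)
            spec = sample_scene_spec(classes, cls.class_id, rng,
                                     image_size=image_size, regime_prob=regime_prob)
            img, anns = render_scene(spec, classes, seed=ss.spawn(1)[0])
            split = "train" if j < n_train else "val"
            images.append({
                "id": image_id,
                "file_name": f"{cls.name}_{j:04d}.png",
                "width": image_size,
                "height": image_size,
                "split": split,
                "class_id": cls.class_id,
                "pixels": img.astype(np.float32),
            })
            for a in anns:
                a = dict(a)
                a["id"] = ann_id
                a["image_id"] = image_id
                annotations.append(a)
                ann_id += 1
            counts[0] += 1
            counts[1 if split == "train" else 2] += len(anns)
            image_id += 1
        rows[cls.name] = tuple(counts)
    manifest = DatasetManifest(rows=rows, split_ratio=split_ratio)
    categories = [{"id": c.class_id, "name": c.name} for c in classes]
    return SyntheticDataset(images=images, annotations=annotations,
                            categories=categories, manifest=manifest)


def radial_signature(contour: np.ndarray, n_bins: int = 64) -> np.ndarray:
    """Rotation-phase-invariant shape signature: |FFT| of the radius profile.

    The contour radius around the centroid is binned by angle, normalized by
    its mean, and reduced to the magnitudes of its first harmonics; instances
    of one shape class differ only in harmonic phase and jitter, so their
    signatures cluster tightly.
    """
    v = np.asarray(contour, dtype=float)
    c = v.mean(axis=0)
    d = v - c
    theta = np.arctan2(d[:, 1], d[:, 0])
    r = np.hypot(d[:, 0], d[:, 1])
    bins = ((theta + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    prof = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    np.add.at(prof, bins, r)
    np.add.at(cnt, bins, 1)
    filled = cnt > 0
    prof[filled] /= cnt[filled]
    if not filled.all():  # interpolate empty bins around the circle
        idx = np.arange(n_bins)
        prof = np.interp(idx, idx[filled], prof[filled], period=n_bins)
    prof /= max(prof.mean(), 1e-9)
    return np.abs(np.fft.rfft(prof))[1:9]


# --- disk round trip ------------------------------------------------------------

def save_coco(dataset: SyntheticDataset, outdir) -> None:
    """Write images as PNG plus per-split COCO JSON and the manifest."""
    os.makedirs(os.path.join(outdir, "images"), exist_ok=True)
    for im in dataset.images:
        arr = (np.clip(im["pixels"], 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr).save(os.path.join(outdir, "images", im["file_name"]))
    for split in ("train", "val"):
        with open(os.path.join(outdir, f"annotations_{split}.json"), "w") as fh:
            json.dump(dataset.to_coco_dict(split), fh, sort_keys=True)
    with open(os.path.join(outdir, "splits.json"), "w") as fh:
        json.dump({im["file_name"]: im["split"] for im in dataset.images}, fh, sort_keys=True)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(dataset.manifest.to_dict(), fh, indent=2, sort_keys=True)


def load_coco(outdir) -> SyntheticDataset:
    images, annotations = [], []
    with open(os.path.join(outdir, "splits.json")) as fh:
        splits = json.load(fh)
    categories = None
    for split in ("train", "val"):
        with open(os.path.join(outdir, f"annotations_{split}.json")) as fh:
            coco = json.load(fh)
        categories = coco["categories"]
        for im in coco["images"]:
            arr = np.asarray(Image.open(os.path.join(outdir, "images", im["file_name"])))
            im = dict(im)
            im["pixels"] = arr.astype(np.float32) / 255.0
            im["split"] = splits[im["file_name"]]
            images.append(im)
        annotations.extend(coco["annotations"])
    with open(os.path.join(outdir, "manifest.json")) as fh:
        mdict = json.load(fh)
    manifest = DatasetManifest(
        rows={k: tuple(v) for k, v in mdict["classes"].items()},
        split_ratio=mdict["split_ratio"],
    )
    return SyntheticDataset(images=images, annotations=annotations,
                            categories=categories, manifest=manifest)
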