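"""Deterministic contour geometry: boxes, diamonds, octagons, masks, IoU.

Conventions
-----------
* Continuous pixel coordinates with the origin at the top-left corner of
  pixel (0, 0); x grows rightward, y grows downward.  Pixel centers sit at
  half-integer coordinates, so pixel (row i, col j) is centered at
  (j + 0.5, i + 0.5).
* Boxes are corner-form ``(x0, y0, x1, y1)`` with ``x0 < x1`` and
  ``y0 < y1`` (half-open in the raster sense).
* Contours are ``(n, 2)`` float arrays of ``(x, y)`` vertices, cyclic
  (the last vertex connects back to the first, no duplicated endpoint),
  oriented clockwise when drawn in image coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BoundingBox",
    "ExtremePointSet",
    "InvalidGeometryError",
    "box_to_diamond",
    "resample_contour",
    "build_octagon",
    "contour_to_mask",
    "mask_iou",
    "box_iou",
    "polygon_area",
    "is_clockwise",
    "ensure_clockwise",
    "extreme_points_of",
    "contour_to_coco",
    "coco_to_contour",
    "box_to_coco",
    "coco_to_box",
]


class InvalidGeometryError(ValueError):
    """Raised for degenerate boxes or contours that break an operation's contract."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle in corner form, pixels."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (np.isfinite([self.x0, self.y0, self.x1, self.y1]).all()):
            raise InvalidGeometryError("box coordinates must be finite")
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise InvalidGeometryError(
                f"degenerate box: ({self.x0}, {self.y0}, {self.x1}, {self.y1})"
            )

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_array(self) -> np.ndarray:
        return np.array([self.x0, self.y0, self.x1, self.y1], dtype=float)

    @staticmethod
    def from_array(a) -> "BoundingBox":
        a = np.asarray(a, dtype=float)
        return BoundingBox(a[0], a[1], a[2], a[3])


@dataclass(frozen=True)
class ExtremePointSet:
    """Top-most, left-most, bottom-most and right-most object points."""

    top: tuple
    leftmost: tuple
    bottom: tuple
    rightmost: tuple

    def __post_init__(self) -> None:
        if self.top[1] > self.bottom[1] + 1e-9:
            raise InvalidGeometryError("top extreme lies below bottom extreme")
        if self.leftmost[0] > self.rightmost[0] + 1e-9:
            raise InvalidGeometryError("leftmost extreme lies right of rightmost")

    def as_array(self) -> np.ndarray:
        """Rows in clockwise order: top, rightmost, bottom, leftmost."""
        return np.array(
            [self.top, self.rightmost, self.bottom, self.leftmost], dtype=float
        )


def _as_contour(vertices) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise InvalidGeometryError(f"contour must be (n>=3, 2), got shape {v.shape}")
    if not np.isfinite(v).all():
        raise InvalidGeometryError("contour has non-finite vertices")
    return v


def polygon_area(vertices) -> float:
    """Signed shoelace area; positive for clockwise order in image coordinates."""
    v = _as_contour(vertices)
    x, y = v[:, 0], v[:, 1]
    # y grows downward, so the sign convention flips relative to math axes
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def is_clockwise(vertices) -> bool:
    return polygon_area(vertices) > 0


def ensure_clockwise(vertices) -> np.ndarray:
    v = _as_contour(vertices)
    return v if is_clockwise(v) else v[::-1].copy()


def box_to_diamond(box: BoundingBox) -> np.ndarray:
    """Diamond contour through the midpoints of the four box edges.

    Vertices are ordered clockwise starting from the top-edge midpoint:
    top, right, bottom, left.  The diamond's area is exactly half the
    box area.
    """
    if not isinstance(box, BoundingBox):
        box = BoundingBox.from_array(box)
    cx = 0.5 * (box.x0 + box.x1)
    cy = 0.5 * (box.y0 + box.y1)
    return np.array(
        [[cx, box.y0], [box.x1, cy], [cx, box.y1], [box.x0, cy]], dtype=float
    )


def resample_contour(vertices, n: int) -> np.ndarray:
    """Resample a closed contour to ``n`` vertices uniformly spaced by arc length.

    The walk starts at the original first vertex and proceeds in the original
    vertex order; the perimeter is preserved to floating-point accuracy.
    """
    if n < 3:
        raise ValueError(f"need at least 3 output vertices, got {n}")
    v = _as_contour(vertices)
    closed = np.vstack([v, v[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    perim = float(seglen.sum())
    if perim <= 0:
        raise InvalidGeometryError("contour has zero perimeter")
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    targets = np.arange(n) * (perim / n)
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seglen) - 1)
    denom = np.where(seglen[idx] > 0, seglen[idx], 1.0)
    frac = (targets - cum[idx]) / denom
    return closed[idx] + frac[:, None] * seg[idx]


def build_octagon(extremes: ExtremePointSet, box: BoundingBox, tol=None) -> np.ndarray:
    """Octagon contour from the four extreme points and their bounding box.

    For each extreme point two endpoints are placed on its box edge at a
    quarter of that edge's length to either side (top/bottom edges use the
    box width, left/right edges the box height), clipped so they never
    leave the box.  The eight endpoints are returned clockwise starting
    from the top extreme's left endpoint.

    Extreme points are first projected onto their corresponding box edge
    (learned predictions may drift off it); a point farther from the box
    than ``tol`` (default: half the larger box side) raises
    :class:`InvalidGeometryError`.
    """
    if not isinstance(box, BoundingBox):
        box = BoundingBox.from_array(box)
    if tol is None:
        tol = 0.5 * max(box.width, box.height)
    pts = extremes.as_array()  # top, right, bottom, left
    dx = np.maximum(np.maximum(box.x0 - pts[:, 0], pts[:, 0] - box.x1), 0.0)
    dy = np.maximum(np.maximum(box.y0 - pts[:, 1], pts[:, 1] - box.y1), 0.0)
    dist = np.hypot(dx, dy)
    if np.any(dist > tol):
        raise InvalidGeometryError(
            f"extreme point {dist.max():.3g} px outside the box (tol {tol:.3g})"
        )
    xt = float(np.clip(pts[0, 0], box.x0, box.x1))  # top on edge y=y0
    yr = float(np.clip(pts[1, 1], box.y0, box.y1))  # right on edge x=x1
    xb = float(np.clip(pts[2, 0], box.x0, box.x1))  # bottom on edge y=y1
    yl = float(np.clip(pts[3, 1], box.y0, box.y1))  # left on edge x=x0
    ext_w = box.width / 4.0
    ext_h = box.height / 4.0

    def cx(x):
        return float(np.clip(x, box.x0, box.x1))

    def cy(y):
        return float(np.clip(y, box.y0, box.y1))

    return np.array(
        [
            [cx(xt - ext_w), box.y0],  # top extreme, left endpoint
            [cx(xt + ext_w), box.y0],
            [box.x1, cy(yr - ext_h)],  # right extreme, upper endpoint
            [box.x1, cy(yr + ext_h)],
            [cx(xb + ext_w), box.y1],  # bottom extreme, right endpoint
            [cx(xb - ext_w), box.y1],
            [box.x0, cy(yl + ext_h)],  # left extreme, lower endpoint
            [box.x0, cy(yl - ext_h)],
        ],
        dtype=float,
    )


def contour_to_mask(vertices, height: int, width: int) -> np.ndarray:
    """Rasterize a polygon: pixels whose centers fall inside under the even-odd rule.

    Self-intersecting input is rasterized under the same parity rule without
    error.  Returns an ``(height, width)`` boolean array.
    """
    if height <= 0 or width <= 0:
        raise ValueError(f"raster dimensions must be positive, got {height}x{width}")
    v = _as_contour(vertices)
    ys = np.arange(height) + 0.5
    xs = np.arange(width) + 0.5
    crossings = np.zeros((height, width), dtype=np.int64)
    nv = v.shape[0]
    for i in range(nv):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % nv]
        if y1 == y2:
            continue  # horizontal edges never cross a scanline strictly
        rows = (y1 <= ys) != (y2 <= ys)
        if not rows.any():
            continue
        yc = ys[rows]
        xi = x1 + (yc - y1) * (x2 - x1) / (y2 - y1)
        crossings[rows] += xs[None, :] < xi[:, None]
    return (crossings % 2).astype(bool)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two same-shape boolean masks (0 if both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 for disjoint or touching boxes."""
    if not isinstance(a, BoundingBox):
        a = BoundingBox.from_array(a)
    if not isinstance(b, BoundingBox):
        b = BoundingBox.from_array(b)
    iw = min(a.x1, b.x1) - max(a.x0, b.x0)
    ih = min(a.y1, b.y1) - max(a.y0, b.y0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return float(inter / (a.area + b.area - inter))


def extreme_points_of(vertices) -> ExtremePointSet:
    """Exact extreme points of a polygon: top-, left-, bottom- and right-most vertices."""
    v = _as_contour(vertices)
    return ExtremePointSet(
        top=tuple(v[np.argmin(v[:, 1])]),
        leftmost=tuple(v[np.argmin(v[:, 0])]),
        bottom=tuple(v[np.argmax(v[:, 1])]),
        rightmost=tuple(v[np.argmax(v[:, 0])]),
    )


# --- COCO serialization helpers -------------------------------------------------

def contour_to_coco(vertices) -> list:
    """Flatten an (n, 2) contour to a COCO segmentation list [x1, y1, x2, y2, ...]."""
    v = _as_contour(vertices)
    return [float(c) for c in v.ravel()]


def coco_to_contour(flat) -> np.ndarray:
    a = np.asarray(flat, dtype=float)
    if a.size % 2 != 0 or a.size < 6:
        raise ValueError("COCO segmentation must hold >= 3 (x, y) pairs")
    return a.reshape(-1, 2)


def box_to_coco(box: BoundingBox) -> list:
    """Corner-form box to COCO [x, y, width, height]."""
    if not isinstance(box, BoundingBox):
        box = BoundingBox.from_array(box)
    return [box.x0, box.y0, box.width, box.height]


def coco_to_box(xywh) -> BoundingBox:
    x, y, w, h = (float(c) for c in xywh)
    return BoundingBox(x, y, x + w, y + h)
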