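"""Axis-aligned box geometry and YOLO-style decoding.

The detector head predicts, for every grid cell and anchor prior, four raw
logits ``(tx, ty, tw, th)`` plus an objectness logit and per-class logits.
They are decoded to an image-plane box in the standard YOLO form::

    bu = (sigma(tx) + cx) * stride        bw = pw * exp(tw)
    bv = (sigma(ty) + cy) * stride        bh = ph * exp(th)

with ``(cx, cy)`` the integer grid-cell indices and ``(pw, ph)`` the anchor
prior in input-scale pixels.  Boxes are stored centre-based; corner form is
used internally for IOU.  Coordinates are continuous pixels, origin top-left,
x right / y down.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridCell",
    "AnchorBox",
    "RawPrediction",
    "BoundingBox",
    "ANCHOR_TABLE",
    "BASE_BOX_SIZES",
    "SCALE_AREA_CUTOFFS",
    "decode_box",
    "encode_box",
    "iou",
    "iou_matrix",
    "classify_scale",
    "read_mot_csv",
    "write_mot_csv",
]

# Anchor priors (pw, ph) in input-scale pixels, per scale class and feature
# map 1..3 (strides 8/16/32 on a 640-px input).  Small and medium priors are
# retuned to suppress background-row fruit; large priors keep the classic
# COCO values.
ANCHOR_TABLE: dict[str, tuple[tuple[int, int], ...]] = {
    "small": ((80, 70), (75, 75), (85, 100)),
    "medium": ((95, 110), (130, 110), (115, 125)),
    "large": ((116, 90), (156, 198), (373, 326)),
}

#: Base bounding-box size per feature map 1..3.
BASE_BOX_SIZES: tuple[int, int, int] = (20, 40, 80)

#: COCO-convention area cutoffs (px^2) separating small/medium/large objects.
SCALE_AREA_CUTOFFS: tuple[float, float] = (32.0**2, 96.0**2)

_STRIDES: tuple[int, int, int] = (8, 16, 32)


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    from scipy.special import expit
    return expit(np.asarray(x, dtype=float))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class GridCell:
    """A cell of the detection grid on one feature map."""

    cx: int
    cy: int
    stride: int

    def __post_init__(self) -> None:
        if self.stride not in _STRIDES:
            raise ValueError(f"stride must be one of {_STRIDES}, got {self.stride}")
        if self.cx < 0 or self.cy < 0:
            raise ValueError("grid indices must be non-negative")


@dataclass(frozen=True)
class AnchorBox:
    """Prior box shape attached to one feature map."""

    pw: float
    ph: float
    scale: str = "medium"
    map_index: int = 1

    def __post_init__(self) -> None:
        if self.pw <= 0 or self.ph <= 0:
            raise ValueError("anchor dimensions must be positive")
        if self.scale not in ANCHOR_TABLE:
            raise ValueError(f"unknown scale class {self.scale!r}")
        if not 1 <= self.map_index <= 3:
            raise ValueError("map_index must be 1..3")

    @property
    def stride(self) -> int:
        return _STRIDES[self.map_index - 1]


@dataclass(frozen=True)
class RawPrediction:
    """Raw head outputs for one (cell, anchor) slot."""

    tx: float
    ty: float
    tw: float
    th: float
    objectness: float = 0.0
    class_scores: tuple[float, ...] = (0.0,)

    def is_finite(self) -> bool:
        vals = (self.tx, self.ty, self.tw, self.th, self.objectness, *self.class_scores)
        return all(math.isfinite(v) for v in vals)


@dataclass
class BoundingBox:
    """Centre-based axis-aligned box in pixel coordinates."""

    bu: float
    bv: float
    bw: float
    bh: float
    conf: float = 1.0
    scale_class: str | None = None
    frame: int = 0
    camera: int | str | None = None

    def __post_init__(self) -> None:
        if self.bw <= 0 or self.bh <= 0:
            raise ValueError("box width/height must be positive")
        if not 0.0 <= self.conf <= 1.0:
            raise ValueError("conf must lie in [0, 1]")

    # -- corner conversions ------------------------------------------------
    @property
    def left(self) -> float:
        return self.bu - self.bw / 2.0

    @property
    def top(self) -> float:
        return self.bv - self.bh / 2.0

    @property
    def right(self) -> float:
        return self.bu + self.bw / 2.0

    @property
    def bottom(self) -> float:
        return self.bv + self.bh / 2.0

    @property
    def area(self) -> float:
        return self.bw * self.bh

    @property
    def gamma(self) -> float:
        """Width/height aspect ratio (the tracker's measurement)."""
        return self.bw / self.bh

    @classmethod
    def from_corners(cls, left: float, top: float, right: float, bottom: float,
                     **kw) -> "BoundingBox":
        return cls(bu=(left + right) / 2.0, bv=(top + bottom) / 2.0,
                   bw=right - left, bh=bottom - top, **kw)

    @classmethod
    def from_ltwh(cls, left: float, top: float, width: float, height: float,
                  **kw) -> "BoundingBox":
        return cls(bu=left + width / 2.0, bv=top + height / 2.0,
                   bw=width, bh=height, **kw)

    def shifted(self, du: float = 0.0, dv: float = 0.0) -> "BoundingBox":
        return replace(self, bu=self.bu + du, bv=self.bv + dv)


def decode_box(raw: RawPrediction, cell: GridCell, anchor: AnchorBox,
               frame: int = 0, camera: int | str | None = None) -> BoundingBox | None:
    """Decode one raw prediction into an image-plane box.

    Returns ``None`` (with a warning) if any logit is non-finite.  The
    confidence is ``sigma(objectness) * max(sigma(class_scores))``.
    """
    if anchor.stride != cell.stride:
        raise ValueError(
            f"anchor (map {anchor.map_index}, stride {anchor.stride}) and cell "
            f"(stride {cell.stride}) belong to different feature maps")
    if not raw.is_finite():
        warnings.warn("rejecting prediction with non-finite logits", stacklevel=2)
        return None
    bu = (float(_sigmoid(raw.tx)) + cell.cx) * cell.stride
    bv = (float(_sigmoid(raw.ty)) + cell.cy) * cell.stride
    bw = anchor.pw * math.exp(raw.tw)
    bh = anchor.ph * math.exp(raw.th)
    conf = float(_sigmoid(raw.objectness)) * float(
        max(_sigmoid(s) for s in raw.class_scores))
    return BoundingBox(bu=bu, bv=bv, bw=bw, bh=bh, conf=conf,
                       scale_class=anchor.scale, frame=frame, camera=camera)


def encode_box(box: BoundingBox, cell: GridCell, anchor: AnchorBox) -> RawPrediction:
    """Inverse of :func:`decode_box` for the geometric logits.

    The centre must lie strictly inside the cell's pixel extent for the
    sigmoid to be invertible.
    """
    fx = box.bu / cell.stride - cell.cx
    fy = box.bv / cell.stride - cell.cy
    if not (0.0 < fx < 1.0 and 0.0 < fy < 1.0):
        raise ValueError("box centre does not lie strictly inside the cell")
    return RawPrediction(
        tx=_logit(fx), ty=_logit(fy),
        tw=math.log(box.bw / anchor.pw), th=math.log(box.bh / anchor.ph))


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; degenerate boxes give 0."""
    area_a, area_b = a.area, b.area
    if area_a <= 0 or area_b <= 0:
        warnings.warn("degenerate (zero-area) box in IOU", stacklevel=2)
        return 0.0
    iw = min(a.right, b.right) - max(a.left, b.left)
    ih = min(a.bottom, b.bottom) - max(a.top, b.top)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def iou_matrix(a: Sequence[BoundingBox], b: Sequence[BoundingBox]) -> np.ndarray:
    """Pairwise IOU matrix, vectorized over corner arrays."""
    if not a or not b:
        return np.zeros((len(a), len(b)))
    la = np.array([[x.left, x.top, x.right, x.bottom] for x in a])
    lb = np.array([[x.left, x.top, x.right, x.bottom] for x in b])
    iw = np.minimum(la[:, None, 2], lb[None, :, 2]) - np.maximum(la[:, None, 0], lb[None, :, 0])
    ih = np.minimum(la[:, None, 3], lb[None, :, 3]) - np.maximum(la[:, None, 1], lb[None, :, 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    area_a = (la[:, 2] - la[:, 0]) * (la[:, 3] - la[:, 1])
    area_b = (lb[:, 2] - lb[:, 0]) * (lb[:, 3] - lb[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def classify_scale(box: BoundingBox,
                   thresholds: tuple[float, float] = SCALE_AREA_CUTOFFS) -> str:
    """Partition a box into small/medium/large by area.

    Used for externally supplied detections; detections decoded in-house carry
    the scale class of the anchor that produced them.
    """
    lo, hi = thresholds
    if lo >= hi:
        raise ValueError("thresholds must be increasing")
    a = box.area
    if a < lo:
        return "small"
    if a < hi:
        return "medium"
    return "large"


MOT_COLUMNS = ["frame", "id", "bb_left", "bb_top", "bb_width", "bb_height",
               "conf", "class", "visibility"]


def read_mot_csv(path) -> list[BoundingBox]:
    """Read a MOT-challenge-style detection CSV into boxes.

    Columns: frame, id, bb_left, bb_top, bb_width, bb_height, conf, class,
    visibility.  Frames are 1-based in the file and preserved as given.
    The MOT ``id`` column (ground-truth identity, -1 for plain detections) is
    attached as attribute ``mot_id``.
    """
    df = pd.read_csv(path, header=None, names=MOT_COLUMNS)
    out: list[BoundingBox] = []
    for row in df.itertuples(index=False):
        box = BoundingBox.from_ltwh(
            float(row.bb_left), float(row.bb_top),
            float(row.bb_width), float(row.bb_height),
            conf=float(min(max(row.conf, 0.0), 1.0)), frame=int(row.frame))
        box.mot_id = int(row.id)  # type: ignore[attr-defined]
        box.scale_class = classify_scale(box)
        out.append(box)
    return out


def write_mot_csv(path, boxes: Iterable[BoundingBox], ids: Iterable[int] | None = None) -> None:
    """Write boxes as MOT-challenge CSV (corner form, 1-based frames kept)."""
    boxes = list(boxes)
    if ids is None:
        ids_list = [getattr(b, "mot_id", -1) for b in boxes]
    else:
        ids_list = list(ids)
    rows = [
        (b.frame, i, b.left, b.top, b.bw, b.bh, b.conf, 1, 1.0)
        for b, i in zip(boxes, ids_list)
    ]
    pd.DataFrame(rows, columns=MOT_COLUMNS).to_csv(path, header=False, index=False)
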