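"""Registry-based unique-object counting.

Detections on each composite frame are filtered (small-scale boxes and boxes
outside the operational zone are excluded), cross-camera duplicates inside
overlap strips are collapsed to their highest-confidence member, and the
survivors feed the tracker.  A track entering the *active* state is
registered — that is the moment the object is counted; losing the track
later flips its registry status to *inactive* but never removes the entry,
so the count is monotone and replay-idempotent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .boxes import BoundingBox, iou_matrix
from .tracker import Track

__all__ = [
    "Zone",
    "RegistryEntry",
    "Registry",
    "CountReport",
    "filter_detections",
    "dedup_cross_camera",
]

DEDUP_IOU_MIN = 0.6
DEDUP_APPEARANCE_SIM_MIN = 0.9


@dataclass(frozen=True)
class Zone:
    """Operational zone rectangle in composite coordinates."""

    left: float
    top: float
    right: float
    bottom: float

    @classmethod
    def from_canvas(cls, width: float, height: float, margin: float = 0.0) -> "Zone":
        return cls(margin, margin, width - margin, height - margin)

    def contains(self, box: BoundingBox) -> bool:
        return (self.left <= box.bu <= self.right
                and self.top <= box.bv <= self.bottom)


def filter_detections(detections: Sequence[BoundingBox], zone: Zone,
                      keep_scales: tuple[str, ...] = ("medium", "large")
                      ) -> tuple[list[BoundingBox], dict[str, int]]:
    """Keep in-zone medium/large detections; tally exclusions by reason.

    Small boxes belong to background-row fruit and are irrelevant for
    tracking; out-of-zone boxes are detected but not counted.
    """
    kept: list[BoundingBox] = []
    excluded = {"scale": 0, "zone": 0}
    for d in detections:
        if d.scale_class is not None and d.scale_class not in keep_scales:
            excluded["scale"] += 1
        elif not zone.contains(d):
            excluded["zone"] += 1
        else:
            kept.append(d)
    return kept, excluded


def _strip_membership(det: BoundingBox,
                      overlaps: Sequence[tuple]) -> list[int]:
    # pad by half the box height so jittered copies of a fruit straddling a
    # strip boundary still qualify as overlap-strip candidates
    pad = det.bh / 2.0
    out = []
    for k, (cam_a, cam_b, top, bottom) in enumerate(overlaps):
        if det.camera in (cam_a, cam_b) and top - pad <= det.bv <= bottom + pad:
            out.append(k)
    return out


def dedup_cross_camera(detections: Sequence[BoundingBox],
                       overlaps: Sequence[tuple],
                       iou_min: float = DEDUP_IOU_MIN,
                       appearance_sim_min: float = DEDUP_APPEARANCE_SIM_MIN
                       ) -> tuple[list[BoundingBox], int]:
    """Collapse cross-camera duplicates inside overlap strips.

    ``overlaps`` are ``(camera_a, camera_b, top_row, bottom_row)`` strips of
    the composite (as recorded by the merger).  Within a strip, detections
    from *different* cameras whose IOU reaches ``iou_min`` are taken as one
    physical object; the highest-confidence member survives.  When both
    members carry appearance descriptors, their cosine similarity must also
    reach ``appearance_sim_min`` — and because that identity evidence is
    strongly discriminative, the geometric floor is relaxed to
    ``iou_min / 2`` so localization jitter cannot split a genuine duplicate.
    Returns the surviving detections and the number suppressed.
    """
    if not overlaps or not detections:
        return list(detections), 0
    n = len(detections)
    strips = [_strip_membership(d, overlaps) for d in detections]
    m = iou_matrix(detections, detections)
    suppressed = np.zeros(n, dtype=bool)
    order = sorted(range(n), key=lambda i: -detections[i].conf)
    dup_count = 0
    for i in order:
        if suppressed[i]:
            continue
        for j in order:
            if j == i or suppressed[j]:
                continue
            if detections[j].camera == detections[i].camera:
                continue
            if not set(strips[i]) & set(strips[j]):
                continue
            di = getattr(detections[i], "descriptor", None)
            dj = getattr(detections[j], "descriptor", None)
            if di is not None and dj is not None:
                if m[i, j] < iou_min / 2.0:
                    continue
                ri = di.r if hasattr(di, "r") else np.asarray(di, dtype=float)
                rj = dj.r if hasattr(dj, "r") else np.asarray(dj, dtype=float)
                if float(ri @ rj) < appearance_sim_min:
                    continue
            elif m[i, j] < iou_min:
                continue
            suppressed[j] = True
            dup_count += 1
    return [d for d, s in zip(detections, suppressed) if not s], dup_count


@dataclass
class RegistryEntry:
    """One counted object: identity, last motion, status, registration time."""

    uid: int
    object_type: str
    movement: tuple[float, float]
    status: str
    registered_at: int


class Registry:
    """Append-only ledger of confirmed tracks; its size is the count."""

    def __init__(self) -> None:
        self._entries: dict[int, RegistryEntry] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, uid: int) -> bool:
        return uid in self._entries

    @property
    def entries(self) -> list[RegistryEntry]:
        return list(self._entries.values())

    def register(self, track: Track, frame: int,
                 object_type: str = "fruit") -> RegistryEntry:
        """Record a track at its tentative -> active transition."""
        if track.id in self._entries:
            raise ValueError(f"uid {track.id} already registered")
        vx, vy = float(track.state.mean[4]), float(track.state.mean[5])
        e = RegistryEntry(uid=track.id, object_type=object_type,
                          movement=(vx, vy), status="active",
                          registered_at=frame)
        self._entries[track.id] = e
        return e

    def deactivate(self, track: Track) -> RegistryEntry:
        """Flip a registered track to inactive; entries are never removed."""
        e = self._entries.get(track.id)
        if e is None:
            raise ValueError(f"uid {track.id} was never registered")
        e.status = "inactive"
        vx, vy = float(track.state.mean[4]), float(track.state.mean[5])
        e.movement = (vx, vy)
        return e

    def n_active(self) -> int:
        return sum(1 for e in self._entries.values() if e.status == "active")


@dataclass
class CountReport:
    """Final tallies of one counting run.

    ``counted`` is the registry size; ``detected_not_counted`` itemizes the
    filtered detections by reason; ``multi_camera_once`` is the number of
    cross-camera duplicates collapsed at deduplication.
    """

    counted: int = 0
    detected_not_counted: int = 0
    multi_camera_once: int = 0
    excluded_by_reason: dict[str, int] = field(default_factory=dict)
    frames_processed: int = 0
    frames_distorted: int = 0

    def __post_init__(self) -> None:
        if min(self.counted, self.detected_not_counted, self.multi_camera_once) < 0:
            raise ValueError("tallies must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_row(self, label: str = "") -> pd.DataFrame:
        """One CSV row: counted / not counted / counted-once columns."""
        return pd.DataFrame([{
            "label": label,
            "detected_and_counted": self.counted,
            "detected_not_counted": self.detected_not_counted,
            "multi_camera_counted_once": self.multi_camera_once,
        }])
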