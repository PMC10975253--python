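"""Multi-stream synchronization and composite-frame quality gating.

Frames from the bottom/middle/top cameras of one time slice are aligned by
timestamp against the slowest stream, stacked vertically (top camera on top)
with linearly blended overlap strips, and gated by SSIM/PSNR: a composite is
*distorted* — and excluded downstream — only when **both** its SSIM falls
below ``ssim_min`` (default 0.50) and its PSNR falls below ``psnr_min``
(default 30 dB).  The composite indices are the minimum over the overlap-strip
pairs, a conservative choice since the merge quality is only observable where
sources disagree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity as _sk_ssim

__all__ = [
    "VideoStream",
    "MergeLayout",
    "CompositeFrame",
    "SyncResult",
    "align_streams",
    "merge_frames",
    "ssim",
    "psnr",
    "quality_gate",
    "quality_report",
]

log = logging.getLogger(__name__)

PSNR_CAP_DB = 100.0

# ITU-R BT.601 luminance weights for colour -> grayscale conversion.
_BT601 = np.array([0.299, 0.587, 0.114])


@dataclass
class VideoStream:
    """One camera's ordered frame sequence with timestamps in seconds."""

    camera: int | str
    timestamps: np.ndarray
    frames: list[np.ndarray] | None = None
    fps: float | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1 or len(self.timestamps) == 0:
            raise ValueError("timestamps must be a non-empty 1-D sequence")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.frames is not None:
            if len(self.frames) != len(self.timestamps):
                raise ValueError("frames and timestamps length mismatch")
            shapes = {f.shape for f in self.frames}
            if len(shapes) > 1:
                raise ValueError("all frames must share dimensions")
        if self.fps is None:
            if len(self.timestamps) > 1:
                self.fps = 1.0 / float(np.median(np.diff(self.timestamps)))
            else:
                self.fps = 1.0

    @property
    def interval(self) -> float:
        return 1.0 / self.fps if self.fps else 1.0


@dataclass
class SyncResult:
    """Chronological synchronized tuples of per-stream frame indices."""

    cameras: list[int | str]
    tuples: list[tuple[int, ...]]
    timestamps: list[float]
    skipped: int = 0


def align_streams(streams: Sequence[VideoStream],
                  tolerance: float | None = None) -> SyncResult:
    """Pair frames across streams by nearest timestamp.

    The slowest stream sets the output rate; for each of its frames inside the
    common time range the nearest frame of every other stream is selected.  A
    tuple whose worst pairwise gap exceeds ``tolerance`` (default: half the
    slowest frame interval) is skipped and logged.
    """
    if len(streams) < 2:
        raise ValueError("need at least two streams to synchronize")
    ref = max(streams, key=lambda s: s.interval)
    if tolerance is None:
        tolerance = ref.interval / 2.0
    t_lo = max(s.timestamps[0] for s in streams)
    t_hi = min(s.timestamps[-1] for s in streams)
    cameras = [s.camera for s in streams]
    if t_lo > t_hi:
        warnings.warn("streams have no overlapping time range", stacklevel=2)
        return SyncResult(cameras, [], [], 0)

    out: list[tuple[int, ...]] = []
    times: list[float] = []
    skipped = 0
    for ri, t in enumerate(ref.timestamps):
        if t < t_lo - tolerance or t > t_hi + tolerance:
            continue
        picks: list[int] = []
        ok = True
        for s in streams:
            if s is ref:
                picks.append(ri)
                continue
            j = int(np.searchsorted(s.timestamps, t))
            best, gap = None, np.inf
            for k in (j - 1, j):
                if 0 <= k < len(s.timestamps):
                    g = abs(s.timestamps[k] - t)
                    if g < gap:
                        best, gap = k, g
            if best is None or gap > tolerance:
                ok = False
                break
            picks.append(best)
        if ok:
            out.append(tuple(picks))
            times.append(float(t))
        else:
            skipped += 1
            log.debug("skipped tuple at t=%.4f: gap beyond tolerance", t)
    if skipped:
        log.info("align_streams: skipped %d tuples beyond tolerance", skipped)
    return SyncResult(cameras, out, times, skipped)


@dataclass
class MergeLayout:
    """Vertical stacking order (top of canvas first) and overlap fraction."""

    order: Sequence[int]
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")


@dataclass
class CompositeFrame:
    """Merged multi-camera canvas with provenance and quality indices."""

    image: np.ndarray
    regions: dict[int | str, tuple[int, int]]       # camera -> (top, bottom) rows
    overlaps: list[tuple[int | str, int | str, int, int]]  # (cam_a, cam_b, top, bottom)
    ssim: float = 1.0
    psnr: float = PSNR_CAP_DB
    status: str = "accepted"
    cameras: list[int | str] = field(default_factory=list)
    index: int = 0

    def to_composite(self, camera: int | str, u: float, v: float) -> tuple[float, float]:
        """Map a point in a source frame into composite coordinates."""
        top, _ = self.regions[camera]
        return u, v + top

    def to_source(self, camera: int | str, u: float, v: float) -> tuple[float, float]:
        """Map a composite point back into a source frame's coordinates."""
        top, _ = self.regions[camera]
        return u, v - top


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        img = img @ _BT601
    return img.astype(float)


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Structural similarity of two 8-bit images (colour via BT.601 luma).

    Standard constants C1=(0.01*255)^2, C2=(0.03*255)^2.
    """
    if np.asarray(a).shape != np.asarray(b).shape:
        raise ValueError("image dimensions must match")
    ga, gb = _to_gray(a), _to_gray(b)
    side = min(ga.shape)
    win = min(7, side if side % 2 == 1 else side - 1)
    return float(_sk_ssim(ga, gb, data_range=255.0, win_size=win,
                          gaussian_weights=False))


def psnr(a: np.ndarray, b: np.ndarray, cap: float = PSNR_CAP_DB) -> float:
    """Peak signal-to-noise ratio in dB: 10*log10(255^2 / MSE), capped."""
    if np.asarray(a).shape != np.asarray(b).shape:
        raise ValueError("image dimensions must match")
    mse = float(np.mean((_to_gray(a) - _to_gray(b)) ** 2))
    if mse == 0.0:
        return cap
    return min(cap, 10.0 * np.log10(255.0**2 / mse))


def merge_frames(frames: Sequence[np.ndarray], layout: MergeLayout,
                 cameras: Sequence[int | str] | None = None,
                 index: int = 0) -> CompositeFrame:
    """Stack one synchronized frame tuple into a composite canvas.

    ``layout.order`` indexes ``frames`` from the top of the canvas downward
    (the top camera first).  Adjacent frames overlap by
    ``overlap_fraction * height`` rows, blended linearly; the per-camera
    region map is retained for coordinate back-projection.
    """
    ordered = [np.asarray(frames[i]) for i in layout.order]
    if cameras is None:
        cameras = list(layout.order)
    cams = [cameras[i] for i in layout.order]
    widths = {f.shape[1] for f in ordered}
    if len(widths) > 1:
        raise ValueError("frames must share width for vertical merging")
    heights = [f.shape[0] for f in ordered]
    ov = [int(round(layout.overlap_fraction * min(heights[i], heights[i + 1])))
          for i in range(len(ordered) - 1)]
    canvas_h = sum(heights) - sum(ov)
    shape = (canvas_h,) + ordered[0].shape[1:]
    canvas = np.zeros(shape, dtype=float)
    weight = np.zeros((canvas_h,) + (1,) * (len(shape) - 1), dtype=float)

    regions: dict[int | str, tuple[int, int]] = {}
    overlaps: list[tuple[int | str, int | str, int, int]] = []
    top = 0
    for k, (cam, f) in enumerate(zip(cams, ordered)):
        h = f.shape[0]
        w = np.ones(h)
        if k > 0 and ov[k - 1] > 0:           # blend-in against the frame above
            w[: ov[k - 1]] = np.linspace(0.0, 1.0, ov[k - 1] + 2)[1:-1]
        if k < len(ordered) - 1 and ov[k] > 0:  # blend-out against the frame below
            w[h - ov[k]:] = np.linspace(1.0, 0.0, ov[k] + 2)[1:-1]
        wcol = w.reshape((h,) + (1,) * (len(shape) - 1))
        canvas[top: top + h] += f * wcol
        weight[top: top + h] += wcol
        regions[cam] = (top, top + h)
        if k < len(ordered) - 1 and ov[k] > 0:
            overlaps.append((cam, cams[k + 1], top + h - ov[k], top + h))
        top += h - (ov[k] if k < len(ordered) - 1 else 0)
    canvas = canvas / np.maximum(weight, 1e-12)
    canvas = np.clip(canvas, 0, 255)

    # Composite quality = minimum over overlap-strip pairs.
    s_vals, p_vals = [], []
    for k, (cam_a, cam_b, o_top, o_bot) in enumerate(overlaps):
        n = o_bot - o_top
        strip_a = ordered[k][heights[k] - n:]
        strip_b = ordered[k + 1][:n]
        s_vals.append(ssim(strip_a, strip_b))
        p_vals.append(psnr(strip_a, strip_b))
    comp = CompositeFrame(
        image=canvas.astype(ordered[0].dtype if np.issubdtype(ordered[0].dtype, np.integer) else float),
        regions=regions, overlaps=overlaps,
        ssim=min(s_vals) if s_vals else 1.0,
        psnr=min(p_vals) if p_vals else PSNR_CAP_DB,
        cameras=cams, index=index)
    comp.status = quality_gate(comp)
    return comp


def quality_gate(frame: CompositeFrame, ssim_min: float = 0.50,
                 psnr_min: float = 30.0) -> str:
    """Classify a composite as accepted/distorted.

    Distorted iff SSIM < ssim_min AND PSNR < psnr_min (both strict); a frame
    failing exactly one condition is accepted with a borderline warning.
    """
    low_s = frame.ssim < ssim_min
    low_p = frame.psnr < psnr_min
    if low_s and low_p:
        return "distorted"
    if low_s or low_p:
        log.warning("composite %s borderline: ssim=%.3f psnr=%.1f",
                    frame.index, frame.ssim, frame.psnr)
    return "accepted"


def quality_report(frames: Sequence[CompositeFrame]) -> pd.DataFrame:
    """Per-composite quality table (index, ssim, psnr, status).

    The attached means are plain arithmetic means over all rows, labelled as
    such in the column attributes.
    """
    df = pd.DataFrame({
        "index": [f.index for f in frames],
        "ssim": [f.ssim for f in frames],
        "psnr": [f.psnr for f in frames],
        "status": [f.status for f in frames],
    })
    df.attrs["ssim_arithmetic_mean"] = float(df["ssim"].mean()) if len(df) else None
    df.attrs["psnr_arithmetic_mean"] = float(df["psnr"].mean()) if len(df) else None
    return df
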