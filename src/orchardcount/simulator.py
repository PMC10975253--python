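"""Seeded synthetic orchard-flight generator.

Stands in for field footage: a slender-spindle apple row (trees every 2 m,
4 m between rows, 3.5 m tall, ~200 fruits per tree in season), a three-camera
UAV rig at heights 1.2 / 2.2 / 3.2 m with view pitches +25 / 0 / -20 degrees,
and a constant-speed pass along the row face.

Geometry is a planar-face model: fruit crowns live near the row plane and
each camera images a vertical band of that plane, the band centre given by
pinhole intersection of the camera's central ray with the plane and a common
pixel scale ``s = f / d`` (focal length over working distance).  Cross-camera
parallax and stitching error are deliberately not modelled — they are folded
into the jitter noise term — so a fruit inside an overlap band projects to
geometrically coincident composite positions in both cameras.  Every record
carries the true fruit id for oracle use; the ground-truth stream is
noise-free and complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .boxes import BoundingBox, classify_scale, write_mot_csv
from .tracker import AppearanceDescriptor

__all__ = [
    "SceneParams",
    "OrchardScene",
    "CameraPose",
    "CameraRig",
    "CompositeGeometry",
    "NoiseModel",
    "NOISE_PRESETS",
    "generate_scene",
    "simulate_flight",
    "render_frames",
    "FlightSim",
]

DESCRIPTOR_DIM = 32


@dataclass(frozen=True)
class SceneParams:
    """Orchard geometry; defaults follow the surveyed planting scheme."""

    row_length: float = 500.0        # m (rows run 500-800 m in the field)
    tree_spacing: float = 2.0        # m between trees
    row_spacing: float = 4.0         # m between rows
    tree_height: float = 3.5         # m
    fruits_per_tree: int = 200       # seasonal average per tree
    fruit_radius: float = 0.04       # m (sphere model)
    crown_center_z: float = 2.25     # m, centre of the fruiting zone
    crown_half_height: float = 0.75  # m -> fruits in [1.5, 3.0]
    crown_half_width: float = 0.5    # m along the row
    crown_half_depth: float = 0.35   # m into the canopy

    @property
    def n_trees(self) -> int:
        return max(1, int(self.row_length / self.tree_spacing))


@dataclass
class OrchardScene:
    """Fruit positions (x along row, y depth, z height) plus provenance."""

    params: SceneParams
    fruits: np.ndarray               # (N, 3) metres
    radius: float
    colors: np.ndarray               # (N, 3) RGB in [0, 1]
    seed: int

    @property
    def n_fruits(self) -> int:
        return len(self.fruits)


def generate_scene(params: SceneParams | None = None, seed: int = 0,
                   n_trees: int | None = None) -> OrchardScene:
    """Sample fruit positions uniformly within per-tree crown ellipsoids.

    Deterministic for a fixed seed; the fruit count is exactly
    ``n_trees * fruits_per_tree``.
    """
    p = params or SceneParams()
    rng = np.random.default_rng(seed)
    trees = n_trees if n_trees is not None else p.n_trees
    pts = []
    for t in range(trees):
        cx = (t + 0.5) * p.tree_spacing
        k = p.fruits_per_tree
        got = 0
        while got < k:
            u = rng.uniform(-1, 1, size=(max(k * 2, 8), 3))
            inside = (u**2).sum(axis=1) <= 1.0
            u = u[inside][: k - got]
            pts.append(np.column_stack([
                cx + u[:, 0] * p.crown_half_width,
                u[:, 1] * p.crown_half_depth,
                p.crown_center_z + u[:, 2] * p.crown_half_height,
            ]))
            got += len(u)
    fruits = np.vstack(pts) if pts else np.zeros((0, 3))
    # raspberry-blush apples: reddish with per-fruit variation
    colors = np.column_stack([
        rng.uniform(0.75, 0.95, len(fruits)),
        rng.uniform(0.10, 0.35, len(fruits)),
        rng.uniform(0.10, 0.25, len(fruits)),
    ])
    return OrchardScene(params=p, fruits=fruits, radius=p.fruit_radius,
                        colors=colors, seed=seed)


@dataclass(frozen=True)
class CameraPose:
    """One UAV camera: mount height and view pitch (positive = upward)."""

    camera: int
    height: float
    pitch_deg: float


@dataclass(frozen=True)
class CameraRig:
    """Three-camera rig; heights and pitches default to the flight plan."""

    cameras: tuple[CameraPose, ...] = (
        CameraPose(0, 1.2, +25.0),    # bottom, looking up
        CameraPose(1, 2.2, 0.0),      # middle, level
        CameraPose(2, 3.2, -20.0),    # top, looking down
    )
    fov_v_deg: float = 34.0
    resolution: tuple[int, int] = (640, 480)   # (width, height) px
    # 20 fps at the default 0.5 m/s pass gives 2.5 cm (~16 px) of apparent
    # motion per frame, well inside the association gates for 5-cm boxes
    fps: float = 20.0
    distance: float = 1.2             # working distance to the row face, m

    @property
    def focal_px(self) -> float:
        return (self.resolution[1] / 2.0) / math.tan(math.radians(self.fov_v_deg / 2))

    @property
    def scale(self) -> float:
        """Common pixel scale on the row face, px per metre."""
        return self.focal_px / self.distance

    def band(self, cam: CameraPose) -> tuple[float, float]:
        """Vertical extent (z_lo, z_hi) of the camera's face band, metres."""
        zc = cam.height + self.distance * math.tan(math.radians(cam.pitch_deg))
        half = self.resolution[1] / (2.0 * self.scale)
        return zc - half, zc + half

    @property
    def half_width_m(self) -> float:
        return self.resolution[0] / (2.0 * self.scale)


@dataclass
class CompositeGeometry:
    """Mapping from per-camera pixels into the stacked composite canvas."""

    scale: float                                  # px per metre
    z_top: float                                  # face height at canvas row 0
    canvas_height: int
    canvas_width: int
    regions: dict[int, tuple[int, int]]           # camera -> (top, bottom) rows
    overlaps: list[tuple[int, int, int, int]]     # (cam_a, cam_b, top, bottom)
    bands: dict[int, tuple[float, float]]

    @classmethod
    def from_rig(cls, rig: CameraRig) -> "CompositeGeometry":
        bands = {c.camera: rig.band(c) for c in rig.cameras}
        z_top = max(hi for _, hi in bands.values())
        z_bot = min(lo for lo, _ in bands.values())
        s = rig.scale
        regions = {}
        for cam, (lo, hi) in bands.items():
            top = int(round((z_top - hi) * s))
            regions[cam] = (top, top + rig.resolution[1])
        overlaps = []
        cams = sorted(bands, key=lambda c: -bands[c][1])   # top of canvas first
        for a, b in zip(cams, cams[1:]):
            lo = max(regions[a][0], regions[b][0])
            hi = min(regions[a][1], regions[b][1])
            if hi > lo:
                overlaps.append((a, b, lo, hi))
        return cls(scale=s, z_top=z_top,
                   canvas_height=int(round((z_top - z_bot) * s)),
                   canvas_width=rig.resolution[0],
                   regions=regions, overlaps=overlaps, bands=bands)

    def to_composite(self, camera: int, u: float, v: float) -> tuple[float, float]:
        top, _ = self.regions[camera]
        return u, v + top


@dataclass(frozen=True)
class NoiseModel:
    """Detection-level degradation emulating foliage and weather effects."""

    miss_prob: float = 0.0            # P(visible fruit yields no detection)
    fp_rate: float = 0.0              # spurious detections per composite frame
    jitter_px: float = 0.0            # centre/size Gaussian std
    occlusion_prob: float = 0.0       # stationary foliage-occlusion rate
    occlusion_persistence: float = 0.8  # Markov streakiness along the pass
    descriptor_noise: float = 0.0     # appearance perturbation std

    def __post_init__(self) -> None:
        for name in ("miss_prob", "occlusion_prob", "occlusion_persistence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


#: The "cloudy" preset approximates the cloudy-weather field error rates
#: (false positives ~15% of detections, ~18% of fruit emissions missed) as a
#: stress fixture, not a claim reproduction.  The per-emission miss 0.14
#: combines with the 5% streaky occlusion to a net ~18.3% miss rate; one
#: spurious box per composite frame is ~15% of the typical detection load.
NOISE_PRESETS: dict[str, NoiseModel] = {
    "none": NoiseModel(),
    "cloudy": NoiseModel(miss_prob=0.14, fp_rate=1.0, jitter_px=2.0,
                         occlusion_prob=0.05, descriptor_noise=0.03),
}


def _replace_keeping_tags(box: BoundingBox, **kw) -> BoundingBox:
    """dataclasses.replace, preserving the dynamic fruit_id/descriptor tags."""
    out = replace(box, **kw)
    for attr in ("fruit_id", "descriptor", "mot_id"):
        if hasattr(box, attr):
            setattr(out, attr, getattr(box, attr))
    return out


def _fruit_descriptors(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed + 7919)
    d = rng.normal(size=(n, DESCRIPTOR_DIM))
    return d / np.linalg.norm(d, axis=1, keepdims=True)


@dataclass
class FlightSim:
    """Output of one simulated pass: per-frame, per-camera detections."""

    rig: CameraRig
    geometry: CompositeGeometry
    timestamps: np.ndarray
    detections: list[dict[int, list[BoundingBox]]]      # noisy streams
    ground_truth: list[dict[int, list[BoundingBox]]]    # complete, noise-free
    visible_fruit_ids: set[int]                          # ever fully visible
    duplicate_emissions: int                             # post-noise extras
    seed: int

    @property
    def n_frames(self) -> int:
        return len(self.detections)

    def frame_detections(self, i: int, composite: bool = True) -> list[BoundingBox]:
        """All cameras' detections of frame ``i``, optionally mapped to
        composite coordinates."""
        out = []
        for cam, dets in sorted(self.detections[i].items()):
            for d in dets:
                if composite:
                    u, v = self.geometry.to_composite(cam, d.bu, d.bv)
                    d = _replace_keeping_tags(d, bu=u, bv=v)
                out.append(d)
        return out

    def write_mot(self, det_path, truth_path=None) -> None:
        """Export composite-coordinate streams as MOT-style CSVs."""
        dets, truths = [], []
        for i in range(self.n_frames):
            for cam, lst in sorted(self.detections[i].items()):
                for d in lst:
                    u, v = self.geometry.to_composite(cam, d.bu, d.bv)
                    b = replace(d, bu=u, bv=v)
                    b.mot_id = -1
                    dets.append(b)
            for cam, lst in sorted(self.ground_truth[i].items()):
                for d in lst:
                    u, v = self.geometry.to_composite(cam, d.bu, d.bv)
                    b = replace(d, bu=u, bv=v)
                    b.mot_id = getattr(d, "fruit_id", -1)
                    truths.append(b)
        write_mot_csv(det_path, dets)
        if truth_path is not None:
            write_mot_csv(truth_path, truths)


def simulate_flight(scene: OrchardScene, rig: CameraRig | None = None,
                    speed: float = 0.5, noise: NoiseModel | None = None,
                    seed: int = 0, margin: float | None = None) -> FlightSim:
    """Fly the rig along the row at constant speed and emit detections.

    Per frame and camera, every fruit whose box lies fully inside the frame
    and whose height falls in the camera's face band yields a ground-truth
    box tagged with its true fruit id; the noisy stream applies per-emission
    misses, streaky occlusion, centre/size jitter and per-frame spurious
    boxes.  Deterministic for fixed (scene, rig, noise, seed).
    """
    rig = rig or CameraRig()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    geom = CompositeGeometry.from_rig(rig)
    s = geom.scale
    W, H = rig.resolution
    r_px = scene.radius * s
    box_px = 2.0 * r_px

    if margin is None:
        margin = rig.half_width_m + 0.1
    if scene.n_fruits:
        x_lo = float(scene.fruits[:, 0].min()) - margin
        x_hi = float(scene.fruits[:, 0].max()) + margin
    else:
        x_lo, x_hi = -margin, margin
    dx = speed / rig.fps
    n_frames = int(math.ceil((x_hi - x_lo) / dx)) + 1
    timestamps = np.arange(n_frames) / rig.fps

    desc = _fruit_descriptors(scene.n_fruits, scene.seed)
    occluded = np.zeros(scene.n_fruits, dtype=bool)
    if noise.occlusion_prob > 0:
        occluded = rng.random(scene.n_fruits) < noise.occlusion_prob

    detections: list[dict[int, list[BoundingBox]]] = []
    ground_truth: list[dict[int, list[BoundingBox]]] = []
    visible_ids: set[int] = set()
    duplicate_emissions = 0

    bands = {c.camera: rig.band(c) for c in rig.cameras}
    fx, fz = (scene.fruits[:, 0], scene.fruits[:, 2]) if scene.n_fruits else \
        (np.zeros(0), np.zeros(0))

    for fi in range(n_frames):
        x_cam = x_lo + fi * dx
        if noise.occlusion_prob > 0:
            # streaky occlusion: persist with high probability along the pass
            stay = rng.random(scene.n_fruits) < noise.occlusion_persistence
            fresh = rng.random(scene.n_fruits) < noise.occlusion_prob
            occluded = np.where(stay, occluded, fresh)
        frame_truth: dict[int, list[BoundingBox]] = {}
        frame_det: dict[int, list[BoundingBox]] = {}
        emitted_fruits: dict[int, int] = {}
        for cam in rig.cameras:
            z_lo, z_hi = bands[cam.camera]
            du = (fx - x_cam) * s
            horiz = np.abs(du) <= (W / 2.0 - r_px)
            vert = (fz >= z_lo + scene.radius) & (fz <= z_hi - scene.radius)
            vis = np.nonzero(horiz & vert)[0]
            truth_list, det_list = [], []
            for idx in vis:
                u = W / 2.0 + du[idx]
                v = (z_hi - fz[idx]) * s
                tb = BoundingBox(bu=u, bv=v, bw=box_px, bh=box_px, conf=1.0,
                                 frame=fi + 1, camera=cam.camera)
                tb.fruit_id = int(idx)
                tb.scale_class = classify_scale(tb)
                truth_list.append(tb)
                visible_ids.add(int(idx))
                if occluded[idx] or rng.random() < noise.miss_prob:
                    continue
                if noise.jitter_px > 0:
                    j = rng.normal(0.0, noise.jitter_px, size=4)
                else:
                    j = np.zeros(4)
                db = BoundingBox(
                    bu=u + j[0], bv=v + j[1],
                    bw=max(2.0, box_px + j[2]), bh=max(2.0, box_px + j[3]),
                    conf=float(np.clip(rng.uniform(0.75, 0.99), 0, 1)),
                    frame=fi + 1, camera=cam.camera)
                db.fruit_id = int(idx)
                db.scale_class = classify_scale(db)
                rv = desc[idx]
                if noise.descriptor_noise > 0:
                    rv = rv + rng.normal(0, noise.descriptor_noise, DESCRIPTOR_DIM)
                    rv = rv / np.linalg.norm(rv)
                db.descriptor = AppearanceDescriptor(rv)
                det_list.append(db)
                emitted_fruits[int(idx)] = emitted_fruits.get(int(idx), 0) + 1
            # spurious detections, uniform over the frame
            if noise.fp_rate > 0:
                for _ in range(rng.poisson(noise.fp_rate / len(rig.cameras))):
                    fb = BoundingBox(
                        bu=rng.uniform(box_px, W - box_px),
                        bv=rng.uniform(box_px, H - box_px),
                        bw=box_px * rng.uniform(0.7, 1.3),
                        bh=box_px * rng.uniform(0.7, 1.3),
                        conf=float(rng.uniform(0.5, 0.9)),
                        frame=fi + 1, camera=cam.camera)
                    fb.fruit_id = -1
                    fb.scale_class = classify_scale(fb)
                    fv = rng.normal(size=DESCRIPTOR_DIM)
                    fb.descriptor = AppearanceDescriptor(fv / np.linalg.norm(fv))
                    det_list.append(fb)
            frame_truth[cam.camera] = truth_list
            frame_det[cam.camera] = det_list
        duplicate_emissions += sum(n - 1 for n in emitted_fruits.values() if n > 1)
        ground_truth.append(frame_truth)
        detections.append(frame_det)

    return FlightSim(rig=rig, geometry=geom, timestamps=timestamps,
                     detections=detections, ground_truth=ground_truth,
                     visible_fruit_ids=visible_ids,
                     duplicate_emissions=duplicate_emissions, seed=seed)


def render_frames(scene: OrchardScene, rig: CameraRig | None = None,
                  frame_range: Sequence[int] = (0,), speed: float = 0.5,
                  seed: int = 0, margin: float | None = None
                  ) -> dict[int, list[np.ndarray]]:
    """Render simple shaded-disk frames per camera for the given frames.

    Background is seeded green-tinted texture; fruits are drawn as radially
    shaded disks in their per-fruit colour.  Deterministic per seed.
    """
    rig = rig or CameraRig()
    geom = CompositeGeometry.from_rig(rig)
    s = geom.scale
    W, H = rig.resolution
    r_px = scene.radius * s
    if margin is None:
        margin = rig.half_width_m + 0.1
    x_lo = (float(scene.fruits[:, 0].min()) - margin) if scene.n_fruits else -margin
    dx = speed / rig.fps
    rng = np.random.default_rng(seed + 104729)
    base = rng.uniform(0.25, 0.45, size=(H, W, 1)) * np.array([[0.5, 1.0, 0.45]])
    base = (base * 255).astype(np.uint8)

    out: dict[int, list[np.ndarray]] = {c.camera: [] for c in rig.cameras}
    yy, xx = np.mgrid[0:H, 0:W]
    for fi in frame_range:
        x_cam = x_lo + fi * dx
        for cam in rig.cameras:
            z_lo, z_hi = rig.band(cam)
            img = base.astype(float).copy()
            for idx in range(scene.n_fruits):
                u = W / 2.0 + (scene.fruits[idx, 0] - x_cam) * s
                v = (z_hi - scene.fruits[idx, 2]) * s
                if not (-r_px < u < W + r_px and -r_px < v < H + r_px):
                    continue
                d2 = (xx - u) ** 2 + (yy - v) ** 2
                mask = d2 <= r_px**2
                if not mask.any():
                    continue
                shade = 1.0 - 0.5 * np.sqrt(d2[mask]) / r_px
                img[mask] = scene.colors[idx] * 255.0 * shade[:, None]
            out[cam.camera].append(np.clip(img, 0, 255).astype(np.uint8))
    return out
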