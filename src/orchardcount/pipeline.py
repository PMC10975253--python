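"""End-to-end orchestration: simulate/load -> filter -> dedup -> track -> count.

The pipeline consumes per-camera detection streams (from the bundled
simulator or MOT-style CSV files), maps them into composite coordinates,
filters small/out-of-zone boxes, collapses cross-camera duplicates inside
the declared overlap strips, associates the survivors frame to frame, and
maintains the count registry.  Every run writes a manifest (config, seeds,
version) sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .boxes import BoundingBox
from .counter import (CountReport, Registry, Zone, dedup_cross_camera,
                      filter_detections)
from .metrics import ConfusionCounts, f1, fnr, match_to_truth, precision, recall
from .simulator import (CameraRig, FlightSim, NOISE_PRESETS, SceneParams,
                        generate_scene, simulate_flight)
from .tracker import Tracker, TrackerParams

__all__ = ["PipelineConfig", "PipelineResult", "count_flight",
           "evaluate_flight", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of one run; unknown keys are rejected at load time."""

    seed: int = 0
    # simulator
    n_trees: int = 5
    fruits_per_tree: int = 10
    noise_preset: str = "none"
    speed: float = 0.5
    # detection thresholds
    conf_threshold: float = 0.5
    # quality gate
    ssim_min: float = 0.50
    psnr_min: float = 30.0
    # association
    t1: float = 0.2
    t2: float = 9.487729036781154
    lam: float = 0.5
    iou_min: float = 0.3
    n_init: int = 3
    max_age: int = 30
    # counting
    zone_margin: float = 0.0
    dedup_iou_min: float = 0.6
    # I/O
    detections_csv: str | None = None
    out_dir: str | None = None

    def tracker_params(self) -> TrackerParams:
        return TrackerParams(t1=self.t1, t2=self.t2, lam=self.lam,
                             iou_min=self.iou_min, n_init=self.n_init,
                             max_age=self.max_age)

    def validate(self) -> None:
        checks = [
            (0.0 <= self.conf_threshold <= 1.0, "conf_threshold in [0,1]"),
            (-1.0 <= self.ssim_min <= 1.0, "ssim_min in [-1,1]"),
            (self.psnr_min >= 0, "psnr_min >= 0"),
            (self.t1 > 0 and self.t2 > 0, "gates positive"),
            (0.0 <= self.lam <= 1.0, "lambda in [0,1]"),
            (0.0 <= self.iou_min <= 1.0, "iou_min in [0,1]"),
            (self.n_init >= 1 and self.max_age >= 1, "lifecycle constants >= 1"),
            (self.noise_preset in NOISE_PRESETS, f"noise preset known {list(NOISE_PRESETS)}"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"config invariant violated: {msg}")


def load_config(path) -> PipelineConfig:
    """Load a YAML config; unknown keys raise a config error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


@dataclass
class PipelineResult:
    report: CountReport
    registry: Registry
    track_rows: pd.DataFrame
    events: pd.DataFrame
    manifest: dict
    evaluation: dict | None = None


def count_flight(sim: FlightSim, config: PipelineConfig | None = None
                 ) -> PipelineResult:
    """Run filtering, dedup, tracking and counting over one simulated pass."""
    cfg = config or PipelineConfig()
    cfg.validate()
    zone = Zone.from_canvas(sim.geometry.canvas_width,
                            sim.geometry.canvas_height, cfg.zone_margin)
    tracker = Tracker(cfg.tracker_params())
    registry = Registry()
    report = CountReport(excluded_by_reason={"scale": 0, "zone": 0})
    rows, events = [], []

    for fi in range(sim.n_frames):
        dets = sim.frame_detections(fi, composite=True)
        dets = [d for d in dets if d.conf >= cfg.conf_threshold]
        kept, excluded = filter_detections(dets, zone)
        for k, v in excluded.items():
            report.excluded_by_reason[k] = report.excluded_by_reason.get(k, 0) + v
        kept, dups = dedup_cross_camera(kept, sim.geometry.overlaps,
                                        iou_min=cfg.dedup_iou_min)
        report.multi_camera_once += dups
        if dups:
            events.append({"frame": fi + 1, "event": "dedup", "uid": -1,
                           "n": dups})
        res = tracker.step(kept, frame=fi + 1)
        for t in res.confirmed:
            registry.register(t, frame=fi + 1)
            events.append({"frame": fi + 1, "event": "register", "uid": t.id,
                           "n": 1})
        for t in res.deactivated:
            registry.deactivate(t)
            events.append({"frame": fi + 1, "event": "deactivate", "uid": t.id,
                           "n": 1})
        for t in tracker.tracks:
            if t.status in ("tentative", "active") and t.last_box is not None:
                b = t.last_box
                rows.append((fi + 1, t.id, b.left, b.top, b.bw, b.bh, b.conf,
                             t.status))
        report.frames_processed += 1

    for t in tracker.finish():
        registry.deactivate(t)
        events.append({"frame": sim.n_frames, "event": "deactivate",
                       "uid": t.id, "n": 1})

    report.counted = len(registry)
    report.detected_not_counted = sum(report.excluded_by_reason.values())
    track_rows = pd.DataFrame(rows, columns=[
        "frame", "track_id", "bb_left", "bb_top", "bb_width", "bb_height",
        "conf", "status"])
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "n_frames": sim.n_frames,
        "counted": report.counted,
    }
    return PipelineResult(report=report, registry=registry,
                          track_rows=track_rows,
                          events=pd.DataFrame(events), manifest=manifest)


def evaluate_flight(sim: FlightSim, iou_min: float = 0.5) -> dict:
    """Detection-quality metrics of the noisy stream against ground truth.

    Confusion counts are accumulated per frame and camera; rates are percent.
    FPR is withheld (None) because true negatives are undefined for
    detection.
    """
    total = ConfusionCounts()
    for fi in range(sim.n_frames):
        for cam in sim.detections[fi]:
            total = total + match_to_truth(sim.detections[fi][cam],
                                           sim.ground_truth[fi][cam],
                                           iou_min=iou_min)
    return {
        "tp": total.tp, "fp": total.fp, "fn": total.fn,
        "precision": precision(total), "recall": recall(total),
        "f1": f1(total), "fnr": fnr(total), "fpr": None,
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Simulate (or load), count, evaluate, and write artifacts.

    Artifact files (track CSV, event log, count report, manifest) go to
    ``config.out_dir`` when set.
    """
    config.validate()
    if config.detections_csv is not None and not Path(config.detections_csv).exists():
        raise FileNotFoundError(f"detections_csv not found: {config.detections_csv}")

    scene = generate_scene(
        SceneParams(fruits_per_tree=config.fruits_per_tree),
        seed=config.seed, n_trees=config.n_trees)
    sim = simulate_flight(scene, CameraRig(), speed=config.speed,
                          noise=NOISE_PRESETS[config.noise_preset],
                          seed=config.seed + 1)
    result = count_flight(sim, config)
    result.evaluation = evaluate_flight(sim)
    result.manifest["ground_truth_visible"] = len(sim.visible_fruit_ids)
    result.manifest["duplicate_emissions"] = sim.duplicate_emissions

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.track_rows.to_csv(out / "tracks.csv", index=False)
        result.events.to_csv(out / "events.csv", index=False)
        (out / "count_report.json").write_text(result.report.to_json())
        result.report.to_row("run").to_csv(out / "count_report.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    return result
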