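"""Tracking-by-detection with motion and appearance association.

Each track carries an 8-dimensional constant-velocity state
``(x, y, gamma, h, vx, vy, vgamma, vh)`` — box centre, width/height ratio,
height and their per-frame rates — estimated by a linear Kalman filter, plus
an appearance gallery of up to 100 unit-norm descriptors.

Association per frame is a two-stage cascade:

* **Stage A** — active tracks, grouped by increasing consecutive misses, are
  matched to detections by the convex cost
  ``c = lambda * d1 + (1 - lambda) * d2`` where ``d1`` is the minimum cosine
  distance to the gallery and ``d2`` the squared Mahalanobis distance of the
  detection's ``(x, y, gamma, h)`` from the Kalman prediction.  A pair is
  admissible only when both distances pass their gates
  (``b = b1 * b2``); the Hungarian algorithm resolves the admissible matrix.
* **Stage B** — remaining tracks and detections are matched greedily by
  maximal IOU subject to ``IOU >= iou_min``.

Unmatched detections spawn tentative tracks; a track becomes active after
``n_init`` consecutive hits and inactive after ``max_age`` consecutive
misses.  Track ids are unique and never reused.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .boxes import BoundingBox, iou_matrix

__all__ = [
    "CHI2_95_4DOF",
    "TrackState",
    "KalmanPrediction",
    "AppearanceDescriptor",
    "Track",
    "CostMatrix",
    "TrackerParams",
    "Tracker",
    "StepResult",
    "kalman_predict",
    "appearance_distance",
    "mahalanobis_distance",
    "gate",
    "combined_cost",
    "assign",
    "cascade_match",
    "hsv_histogram_descriptor",
]

#: 0.95 quantile of the chi-square distribution with 4 degrees of freedom —
#: the standard gate for a 4-dimensional box measurement.
CHI2_95_4DOF = 9.487729036781154

GALLERY_SIZE = 100
_SENTINEL = 1e9

# Kalman noise weights relative to the box height (conventional
# tracking-by-detection settings).
_W_POS = 1.0 / 20.0
_W_VEL = 1.0 / 160.0


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


@dataclass
class AppearanceDescriptor:
    """Unit-norm fixed-length feature vector of one detection."""

    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if abs(np.linalg.norm(self.r) - 1.0) > 1e-6:
            raise ValueError("descriptor must be unit-norm")


@dataclass
class TrackState:
    """Kinematic mean and covariance of one track."""

    mean: np.ndarray          # (8,)
    covariance: np.ndarray    # (8, 8), symmetric PSD

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.mean.shape != (8,) or self.covariance.shape != (8, 8):
            raise ValueError("state is 8-dimensional")
        if self.mean[3] <= 0 or self.mean[2] <= 0:
            raise ValueError("height and aspect ratio must be positive")

    @property
    def x(self) -> float: return float(self.mean[0])
    @property
    def y(self) -> float: return float(self.mean[1])
    @property
    def gamma(self) -> float: return float(self.mean[2])
    @property
    def h(self) -> float: return float(self.mean[3])


@dataclass
class KalmanPrediction:
    """Predicted measurement-space box and innovation covariance."""

    y: np.ndarray             # (4,) predicted (x, y, gamma, h)
    S: np.ndarray             # (4, 4) symmetric positive-definite


def _measurement(box: BoundingBox) -> np.ndarray:
    return np.array([box.bu, box.bv, box.gamma, box.bh], dtype=float)


def _box_from_state(state: TrackState, frame: int = 0) -> BoundingBox:
    h = max(state.h, 1e-6)
    w = max(state.gamma * h, 1e-6)
    return BoundingBox(bu=state.x, bv=state.y, bw=w, bh=h, conf=1.0, frame=frame)


def initiate_state(box: BoundingBox) -> TrackState:
    """Start a state at a detection with zero velocities and a wide prior."""
    mean = np.zeros(8)
    mean[:4] = _measurement(box)
    h = box.bh
    std = np.array([
        2 * _W_POS * h, 2 * _W_POS * h, 1e-2, 2 * _W_POS * h,
        10 * _W_VEL * h, 10 * _W_VEL * h, 1e-5, 10 * _W_VEL * h,
    ])
    return TrackState(mean=mean, covariance=np.diag(std**2))


def _motion_matrices(h: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    F = np.eye(8)
    F[:4, 4:] = np.eye(4)
    q = np.array([_W_POS * h, _W_POS * h, 1e-2, _W_POS * h,
                  _W_VEL * h, _W_VEL * h, 1e-5, _W_VEL * h])
    Q = np.diag(q**2)
    r = np.array([_W_POS * h, _W_POS * h, 1e-1, _W_POS * h])
    R = np.diag(r**2)
    return F, Q, R


def _clamp_mean(mean: np.ndarray) -> np.ndarray:
    # physical floors: extrapolation on noisy short tracks must not drive
    # the aspect ratio or height non-positive
    mean = mean.copy()
    mean[2] = max(mean[2], 1e-3)
    mean[3] = max(mean[3], 1.0)
    return mean


def predict_state(state: TrackState, process_noise: bool = True) -> TrackState:
    """Constant-velocity propagation of the state by one frame."""
    F, Q, _ = _motion_matrices(state.h)
    mean = _clamp_mean(F @ state.mean)
    cov = F @ state.covariance @ F.T + (Q if process_noise else 0.0)
    cov = _ensure_psd(cov)
    return TrackState(mean=mean, covariance=cov)


def _ensure_psd(m: np.ndarray) -> np.ndarray:
    if not np.allclose(m, m.T, atol=1e-8):
        warnings.warn("covariance lost symmetry; re-symmetrized", stacklevel=3)
        m = (m + m.T) / 2.0
    return m


def project_state(state: TrackState, measurement_noise: bool = True
                  ) -> KalmanPrediction:
    """Project a state through the observation map (x, y, gamma, h)."""
    H = np.zeros((4, 8))
    H[:, :4] = np.eye(4)
    _, _, R = _motion_matrices(state.h)
    y = H @ state.mean
    S = H @ state.covariance @ H.T + (R if measurement_noise else 0.0)
    return KalmanPrediction(y=y, S=_ensure_psd(S))


def update_state(state: TrackState, box: BoundingBox) -> TrackState:
    """Standard Kalman measurement update with a detection's box."""
    pred = project_state(state)
    H = np.zeros((4, 8))
    H[:, :4] = np.eye(4)
    K = np.linalg.solve(pred.S.T, (state.covariance @ H.T).T).T
    innov = _measurement(box) - pred.y
    mean = _clamp_mean(state.mean + K @ innov)
    cov = state.covariance - K @ pred.S @ K.T
    return TrackState(mean=mean, covariance=_ensure_psd(cov))


@dataclass
class Track:
    """One tracked object with lifecycle, state and appearance gallery."""

    id: int
    state: TrackState
    registered_at: int
    gallery: deque = field(default_factory=lambda: deque(maxlen=GALLERY_SIZE))
    hits: int = 1
    misses: int = 0
    status: str = "tentative"
    confirmed_unique: bool = False
    last_box: BoundingBox | None = None

    def to_box(self, frame: int = 0) -> BoundingBox:
        if self.last_box is not None:
            return self.last_box
        return _box_from_state(self.state, frame)


@dataclass
class CostMatrix:
    """Combined costs and gated admissibility over tracks x detections."""

    c: np.ndarray
    admissible: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.atleast_2d(np.asarray(self.c, dtype=float))
        self.admissible = np.atleast_2d(np.asarray(self.admissible))
        if self.c.shape != self.admissible.shape:
            raise ValueError("cost and admissibility shapes must agree")
        if not np.isin(self.admissible, (0, 1)).all():
            raise ValueError("admissibility entries must be 0/1")


# --------------------------------------------------------------------------
# distances and gates

def kalman_predict(track: Track) -> KalmanPrediction:
    """Predicted measurement-space box of a track (after propagation)."""
    return project_state(track.state)


def appearance_distance(det: AppearanceDescriptor, track: Track) -> float:
    """Minimum cosine distance of a descriptor to the track's gallery.

    An empty gallery yields the maximal distance 2 with a warning.
    """
    if not track.gallery:
        warnings.warn(f"track {track.id}: empty appearance gallery", stacklevel=2)
        return 2.0
    sims = [float(det.r @ g.r) for g in track.gallery]
    return 1.0 - max(sims)


def mahalanobis_distance(det: BoundingBox, pred: KalmanPrediction) -> float:
    """Squared Mahalanobis distance of a detection from the prediction."""
    d = _measurement(det) - pred.y
    S = pred.S
    try:
        z = np.linalg.solve(S, d)
    except np.linalg.LinAlgError:
        warnings.warn("singular innovation covariance; regularized", stacklevel=2)
        z = np.linalg.solve(S + 1e-8 * np.eye(4), d)
    return float(d @ z)


def gate(d: float, t: float) -> int:
    """1 iff the distance passes its control threshold (inclusive)."""
    if t <= 0:
        raise ValueError("gate threshold must be positive")
    return 1 if d <= t else 0


def combined_cost(d1: float, d2: float, lam: float) -> float:
    """Convex combination of appearance and motion distances."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return lam * d1 + (1.0 - lam) * d2


def assign(costs: CostMatrix) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-cost one-to-one matching over admissible cells.

    Returns (matched (track, detection) index pairs, unmatched track indices,
    unmatched detection indices).  No match is ever made through an
    inadmissible cell.
    """
    c = costs.c
    n_t, n_d = c.shape
    if n_t == 0 or n_d == 0:
        return [], list(range(n_t)), list(range(n_d))
    masked = np.where(costs.admissible == 1, c, _SENTINEL)
    rows, cols = linear_sum_assignment(masked)
    matches = [(int(r), int(col)) for r, col in zip(rows, cols)
               if costs.admissible[r, col] == 1]
    mt = {r for r, _ in matches}
    md = {d for _, d in matches}
    return (matches,
            [i for i in range(n_t) if i not in mt],
            [j for j in range(n_d) if j not in md])


# --------------------------------------------------------------------------
# cascade and stepping

@dataclass
class TrackerParams:
    """Association thresholds and lifecycle constants."""

    t1: float = 0.2                 # appearance gate
    t2: float = CHI2_95_4DOF        # motion gate (chi-square 0.95, 4 dof)
    lam: float = 0.5                # appearance weight in the combined cost
    iou_min: float = 0.3            # stage-B IOU floor
    n_init: int = 3                 # consecutive hits to confirm
    max_age: int = 30               # consecutive misses to deactivate
    confirm_unique_hits: int = 100  # hits that freeze a track's identity


@dataclass
class AssociationResult:
    matches: list[tuple[int, int]]
    unmatched_tracks: list[int]
    unmatched_detections: list[int]
    stage: dict[tuple[int, int], str] = field(default_factory=dict)


def _descriptor_of(det: BoundingBox) -> AppearanceDescriptor | None:
    d = getattr(det, "descriptor", None)
    if d is None:
        return None
    if isinstance(d, AppearanceDescriptor):
        return d
    return AppearanceDescriptor(np.asarray(d, dtype=float))


def cascade_match(tracks: Sequence[Track], detections: Sequence[BoundingBox],
                  params: TrackerParams | None = None,
                  predictions: Sequence[KalmanPrediction] | None = None
                  ) -> AssociationResult:
    """Two-stage association: gated combined cost, then greedy IOU.

    Stage A runs over active tracks in groups of increasing consecutive
    misses (fresher tracks get first pick); stage B sweeps the remaining
    tracks and detections by maximal IOU.  Outputs are disjoint and
    exhaustive over both index sets.
    """
    params = params or TrackerParams()
    if predictions is None:
        predictions = [kalman_predict(t) for t in tracks]

    unmatched_d = list(range(len(detections)))
    matches: list[tuple[int, int]] = []
    stage: dict[tuple[int, int], str] = {}

    def _gated_pass(group: list[int], label: str) -> None:
        nonlocal unmatched_d
        if not group or not unmatched_d:
            return
        c = np.zeros((len(group), len(unmatched_d)))
        adm = np.zeros_like(c, dtype=int)
        for gi, ti in enumerate(group):
            for dj, di in enumerate(unmatched_d):
                det = detections[di]
                desc = _descriptor_of(det)
                d2 = mahalanobis_distance(det, predictions[ti])
                if desc is not None and tracks[ti].gallery:
                    d1 = appearance_distance(desc, tracks[ti])
                    b = gate(d1, params.t1) * gate(d2, params.t2)
                    c[gi, dj] = combined_cost(d1, d2, params.lam)
                else:
                    b = gate(d2, params.t2)
                    c[gi, dj] = d2
                adm[gi, dj] = b
        m, _, _ = assign(CostMatrix(c=c, admissible=adm))
        for gi, dj in m:
            pair = (group[gi], unmatched_d[dj])
            matches.append(pair)
            stage[pair] = label
        taken = {unmatched_d[dj] for _, dj in m}
        unmatched_d = [d for d in unmatched_d if d not in taken]

    active = [i for i, t in enumerate(tracks) if t.status == "active"]
    for age in sorted({tracks[i].misses for i in active}):
        _gated_pass([i for i in active if tracks[i].misses == age], "A")
    # tentative tracks carry descriptors from their first observation, so
    # they too get an appearance-gated pass; without it two near-coincident
    # objects swap owners every frame through the IOU sweep and fragment
    _gated_pass([i for i, t in enumerate(tracks) if t.status == "tentative"],
                "A'")

    matched_t = {t for t, _ in matches}
    rest_t = [i for i in range(len(tracks)) if i not in matched_t]
    if rest_t and unmatched_d:
        t_boxes = [tracks[i].to_box() for i in rest_t]
        d_boxes = [detections[j] for j in unmatched_d]
        m = iou_matrix(t_boxes, d_boxes)
        while True:
            ti, dj = np.unravel_index(np.argmax(m), m.shape)
            if m[ti, dj] < params.iou_min:
                break
            pair = (rest_t[ti], unmatched_d[dj])
            matches.append(pair)
            stage[pair] = "B"
            m[ti, :] = -1.0
            m[:, dj] = -1.0
    matched_t = {t for t, _ in matches}
    matched_d = {d for _, d in matches}
    return AssociationResult(
        matches=sorted(matches),
        unmatched_tracks=[i for i in range(len(tracks)) if i not in matched_t],
        unmatched_detections=[j for j in range(len(detections)) if j not in matched_d],
        stage=stage)


@dataclass
class StepResult:
    """Outcome of one tracker step, including lifecycle events."""

    matches: list[tuple[int, int]]          # (track id, detection index)
    new_track_ids: list[int]
    confirmed: list[Track] = field(default_factory=list)
    deactivated: list[Track] = field(default_factory=list)


class Tracker:
    """Frame-to-frame multi-object tracker over pre-filtered detections."""

    def __init__(self, params: TrackerParams | None = None):
        self.params = params or TrackerParams()
        self.tracks: list[Track] = []
        self._next_id = 1
        self.frame = 0

    def _spawn(self, det: BoundingBox, frame: int) -> Track:
        t = Track(id=self._next_id, state=initiate_state(det),
                  registered_at=frame, last_box=det)
        self._next_id += 1
        desc = _descriptor_of(det)
        if desc is not None:
            t.gallery.append(desc)
        self.tracks.append(t)
        return t

    def step(self, detections: Sequence[BoundingBox],
             frame: int | None = None) -> StepResult:
        """Advance one frame: predict, associate, update, manage lifecycle."""
        self.frame = self.frame + 1 if frame is None else frame
        p = self.params
        live = [t for t in self.tracks if t.status in ("tentative", "active")]
        for t in live:
            t.state = predict_state(t.state)
        predictions = [project_state(t.state) for t in live]

        res = cascade_match(live, detections, p, predictions)
        confirmed: list[Track] = []
        deactivated: list[Track] = []
        out_matches: list[tuple[int, int]] = []

        for ti, dj in res.matches:
            t, det = live[ti], detections[dj]
            t.state = update_state(t.state, det)
            t.last_box = det
            desc = _descriptor_of(det)
            if desc is not None:
                t.gallery.append(desc)      # deque evicts FIFO beyond 100
            t.hits += 1
            t.misses = 0
            if t.status == "tentative" and t.hits >= p.n_init:
                t.status = "active"
                confirmed.append(t)
            if t.status == "active" and t.hits >= p.confirm_unique_hits:
                t.confirmed_unique = True
            out_matches.append((t.id, dj))

        drop: list[Track] = []
        for ti in res.unmatched_tracks:
            t = live[ti]
            t.misses += 1
            t.hits = 0
            if t.status == "tentative":
                drop.append(t)              # never confirmed: discard silently
            elif t.status == "active" and t.misses > p.max_age:
                t.status = "inactive"
                deactivated.append(t)
        for t in drop:
            self.tracks.remove(t)

        new_ids = [self._spawn(detections[dj], self.frame).id
                   for dj in res.unmatched_detections]
        return StepResult(matches=out_matches, new_track_ids=new_ids,
                          confirmed=confirmed, deactivated=deactivated)

    def finish(self) -> list[Track]:
        """End of sequence: deactivate all remaining active tracks."""
        out = []
        for t in self.tracks:
            if t.status == "active":
                t.status = "inactive"
                out.append(t)
        return out


# --------------------------------------------------------------------------
# default appearance descriptor

def hsv_histogram_descriptor(image: np.ndarray, box: BoundingBox,
                             bins: tuple[int, int, int] = (8, 8, 4)
                             ) -> AppearanceDescriptor:
    """L2-normalized 3-D HSV colour histogram of the box crop (256-dim).

    The default appearance model; any unit-norm embedding can be plugged in
    instead by attaching it to a detection's ``descriptor`` attribute.
    """
    from skimage.color import rgb2hsv
    h_img, w_img = image.shape[:2]
    l = int(np.clip(np.floor(box.left), 0, w_img - 1))
    r = int(np.clip(np.ceil(box.right), l + 1, w_img))
    t = int(np.clip(np.floor(box.top), 0, h_img - 1))
    b = int(np.clip(np.ceil(box.bottom), t + 1, h_img))
    crop = np.asarray(image)[t:b, l:r]
    if crop.ndim == 2:
        crop = np.stack([crop] * 3, axis=-1)
    hsv = rgb2hsv(crop / 255.0 if crop.dtype != float else crop)
    hist, _ = np.histogramdd(hsv.reshape(-1, 3), bins=bins,
                             range=((0, 1), (0, 1), (0, 1)))
    flat = hist.ravel()
    n = np.linalg.norm(flat)
    if n == 0:
        flat = np.ones_like(flat)
        n = np.linalg.norm(flat)
    return AppearanceDescriptor(flat / n)
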