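"""Kalman prediction, association distances, gating, assignment, lifecycle."""

import itertools

import numpy as np
import pytest

from orchardcount.boxes import BoundingBox
from orchardcount.tracker import (CHI2_95_4DOF, AppearanceDescriptor,
                                  CostMatrix, KalmanPrediction, Track,
                                  Tracker, TrackerParams, TrackState, assign,
                                  appearance_distance, cascade_match,
                                  combined_cost, gate, hsv_histogram_descriptor,
                                  initiate_state, kalman_predict,
                                  mahalanobis_distance, predict_state,
                                  project_state, unit, update_state)


def make_track(x=50.0, y=50.0, h=20.0, vx=0.0, vy=0.0, tid=1,
               status="active", gallery=()):
    box = BoundingBox(x, y, h, h)
    t = Track(id=tid, state=initiate_state(box), registered_at=0,
              status=status, last_box=box)
    t.state.mean[4], t.state.mean[5] = vx, vy
    for g in gallery:
        t.gallery.append(AppearanceDescriptor(unit(g)))
    return t


class TestKalman:
    def test_zero_velocity_zero_noise_prediction_is_identity(self):
        s = initiate_state(BoundingBox(10, 20, 8, 16))
        s2 = predict_state(s, process_noise=False)
        pred = project_state(s2, measurement_noise=False)
        assert pred.y == pytest.approx([10, 20, 0.5, 16])

    def test_linear_propagation_of_position(self):
        s = initiate_state(BoundingBox(10, 5, 10, 10))
        s.mean[4] = 2.0                       # vx
        s2 = predict_state(s)
        assert s2.mean[0] == pytest.approx(12.0)

    def test_innovation_covariance_matches_hand_computation(self):
        s = initiate_state(BoundingBox(0, 0, 10, 20))
        p = np.arange(1.0, 9.0)
        s.covariance = np.diag(p)
        pred = project_state(s, measurement_noise=False)
        # zero measurement noise: S = H P H^T with H selecting the first four
        assert pred.S == pytest.approx(np.diag(p[:4]))

    def test_exact_linear_motion_has_zero_error_at_all_horizons(self):
        x0, vx = 100.0, 3.0
        s = initiate_state(BoundingBox(x0, 50, 10, 10))
        s.mean[4] = vx
        for k in range(1, 15):
            s = predict_state(s, process_noise=False)
            assert s.mean[0] == pytest.approx(x0 + k * vx)
            assert s.mean[1] == pytest.approx(50.0)

    def test_update_pulls_state_toward_measurement(self):
        s = initiate_state(BoundingBox(50, 50, 10, 10))
        s2 = update_state(s, BoundingBox(54, 50, 10, 10))
        assert 50.0 < s2.mean[0] <= 54.0


class TestDistances:
    def test_gallery_member_has_zero_distance(self):
        v = unit(np.ones(8))
        t = make_track(gallery=[v])
        assert appearance_distance(AppearanceDescriptor(v), t) == pytest.approx(0.0)

    def test_orthogonal_descriptor_distance_one(self):
        t = make_track(gallery=[np.eye(8)[0]])
        d = appearance_distance(AppearanceDescriptor(np.eye(8)[1]), t)
        assert d == pytest.approx(1.0)

    def test_minimum_over_gallery(self):
        t = make_track(gallery=[np.eye(8)[0], np.eye(8)[1]])
        d = appearance_distance(AppearanceDescriptor(np.eye(8)[0]), t)
        assert d == pytest.approx(0.0)

    def test_empty_gallery_maximal_with_warning(self):
        t = make_track()
        with pytest.warns(UserWarning):
            assert appearance_distance(AppearanceDescriptor(np.eye(8)[0]), t) == 2.0

    def test_mahalanobis_at_mean_is_zero(self):
        pred = KalmanPrediction(y=np.array([10, 10, 1.0, 20.0]), S=np.eye(4))
        det = BoundingBox(10, 10, 20, 20)
        assert mahalanobis_distance(det, pred) == pytest.approx(0.0)

    def test_unit_covariance_unit_offset(self):
        pred = KalmanPrediction(y=np.array([10, 10, 1.0, 20.0]), S=np.eye(4))
        det = BoundingBox(11, 10, 20, 20)
        assert mahalanobis_distance(det, pred) == pytest.approx(1.0)

    def test_squared_form_with_scaled_covariance(self):
        # S = 4I, offset 2 in one coordinate -> 2^2 / 4 = 1
        pred = KalmanPrediction(y=np.array([10, 10, 1.0, 20.0]), S=4 * np.eye(4))
        det = BoundingBox(12, 10, 20, 20)
        assert mahalanobis_distance(det, pred) == pytest.approx(1.0)


class TestGatesAndCost:
    def test_gate_inclusive_at_threshold(self):
        assert gate(0.2, 0.2) == 1
        assert gate(0.2 + 1e-12, 0.2) == 0

    def test_combined_admissibility_is_product(self):
        b1 = gate(0.1, 0.2)          # passes appearance
        b2 = gate(12.0, CHI2_95_4DOF)  # fails motion
        assert b1 * b2 == 0

    @pytest.mark.parametrize("lam,d1,d2,expected", [
        (1.0, 0.7, 9.9, 0.7),
        (0.0, 0.7, 9.9, 9.9),
        (0.5, 0.2, 0.4, 0.3),
    ])
    def test_convex_combination(self, lam, d1, d2, expected):
        assert combined_cost(d1, d2, lam) == pytest.approx(expected)


def brute_force_assignment(c, adm):
    """Oracle: exhaustive minimum-cost one-to-one matching."""
    n_t, n_d = c.shape
    best, best_pairs = None, []
    idx_t = list(range(n_t))
    k = min(n_t, n_d)
    for rows in itertools.permutations(idx_t, k):
        for cols in itertools.permutations(range(n_d), k):
            pairs = [(r, cc) for r, cc in zip(rows, cols) if adm[r, cc]]
            # every admissible subset of a permutation is a candidate matching
            cost = sum(c[r, cc] for r, cc in pairs)
            score = (-len(pairs), cost)
            if best is None or score < best:
                best, best_pairs = score, sorted(pairs)
    return best_pairs


class TestAssign:
    def test_single_admissible_cell(self):
        m, ut, ud = assign(CostMatrix(c=[[0.3]], admissible=[[1]]))
        assert m == [(0, 0)] and ut == [] and ud == []

    def test_diagonal_matching(self):
        m, _, _ = assign(CostMatrix(c=[[1.0, 2.0], [2.0, 1.0]],
                                    admissible=np.ones((2, 2), int)))
        assert sorted(m) == [(0, 0), (1, 1)]

    def test_all_inadmissible(self):
        m, ut, ud = assign(CostMatrix(c=np.ones((2, 3)),
                                      admissible=np.zeros((2, 3), int)))
        assert m == [] and ut == [0, 1] and ud == [0, 1, 2]

    def test_empty_matrix(self):
        m, ut, ud = assign(CostMatrix(c=np.zeros((0, 4)),
                                      admissible=np.zeros((0, 4), int)))
        assert m == [] and ud == [0, 1, 2, 3]

    def test_never_matches_through_inadmissible_cell(self, rng):
        for _ in range(200):
            n_t, n_d = rng.integers(1, 5, 2)
            c = rng.uniform(0, 1, (n_t, n_d))
            adm = rng.integers(0, 2, (n_t, n_d))
            m, _, _ = assign(CostMatrix(c=c, admissible=adm))
            assert all(adm[r, d] == 1 for r, d in m)

    def test_equals_brute_force_on_small_random_matrices(self, rng):
        for _ in range(300):
            n_t, n_d = rng.integers(1, 5, 2)
            c = np.round(rng.uniform(0, 1, (n_t, n_d)), 6)
            adm = (rng.random((n_t, n_d)) < 0.8).astype(int)
            got, _, _ = assign(CostMatrix(c=c, admissible=adm))
            expect = brute_force_assignment(c, adm)
            got_cost = sum(c[r, d] for r, d in got)
            exp_cost = sum(c[r, d] for r, d in expect)
            assert len(got) == len(expect)
            assert got_cost == pytest.approx(exp_cost, abs=1e-9)


class TestCascade:
    def test_stage_a_matches_prediction_with_identical_descriptor(self):
        v = unit(np.ones(8))
        t = make_track(x=50, y=50, gallery=[v])
        det = BoundingBox(50, 50, 20, 20)
        det.descriptor = AppearanceDescriptor(v)
        res = cascade_match([t], [det])
        assert res.matches == [(0, 0)]
        assert res.stage[(0, 0)] == "A"

    def test_novel_appearance_high_iou_matches_in_stage_b(self):
        t = make_track(x=50, y=50, gallery=[np.eye(8)[0]])
        det = BoundingBox(50.5, 50, 20, 20)          # IOU ~0.95
        det.descriptor = AppearanceDescriptor(unit(np.eye(8)[1]))
        res = cascade_match([t], [det])
        assert res.matches == [(0, 0)]
        assert res.stage[(0, 0)] == "B"

    def test_crossing_objects_keep_identities_by_appearance(self):
        va, vb = unit(np.eye(8)[0]), unit(np.eye(8)[1])
        # two objects converging on the same point with distinct appearance
        ta = make_track(x=40, y=50, vx=+5, tid=1, gallery=[va])
        tb = make_track(x=60, y=50, vx=-5, tid=2, gallery=[vb])
        for t in (ta, tb):
            t.state = predict_state(t.state)   # both predict x=45 / x=55
        da = BoundingBox(45, 50, 20, 20)
        da.descriptor = AppearanceDescriptor(va)
        db = BoundingBox(55, 50, 20, 20)
        db.descriptor = AppearanceDescriptor(vb)
        res = cascade_match([ta, tb], [db, da],
                            predictions=[project_state(t.state) for t in (ta, tb)])
        assert sorted(res.matches) == [(0, 1), (1, 0)]   # a->da, b->db

    def test_outputs_disjoint_and_exhaustive(self, rng):
        tracks = [make_track(x=float(x), tid=i + 1, gallery=[np.eye(8)[i]])
                  for i, x in enumerate((30, 60, 90))]
        dets = [BoundingBox(*rng.uniform(20, 100, 2), 20, 20) for _ in range(4)]
        res = cascade_match(tracks, dets)
        mt = [t for t, _ in res.matches]
        md = [d for _, d in res.matches]
        assert sorted(mt + res.unmatched_tracks) == [0, 1, 2]
        assert sorted(md + res.unmatched_detections) == [0, 1, 2, 3]


class TestStepLifecycle:
    def test_first_frame_spawns_sequential_ids(self):
        tr = Tracker()
        res = tr.step([BoundingBox(20, 20, 10, 10), BoundingBox(60, 60, 10, 10),
                       BoundingBox(100, 100, 10, 10)])
        assert res.new_track_ids == [1, 2, 3]
        assert all(t.status == "tentative" for t in tr.tracks)

    def test_empty_frame_increments_misses_everywhere(self):
        tr = Tracker()
        for i in range(4):
            tr.step([BoundingBox(20 + i, 20, 10, 10)])
        assert [t.status for t in tr.tracks] == ["active"]
        res = tr.step([])
        assert res.new_track_ids == []
        assert tr.tracks[0].misses == 1

    def test_stationary_object_confirms_after_n_init_hits(self):
        tr = Tracker(TrackerParams(n_init=3))
        confirmed = []
        for _ in range(5):
            res = tr.step([BoundingBox(50, 50, 20, 20)])
            confirmed += [t.id for t in res.confirmed]
        assert len(tr.tracks) == 1
        assert tr.tracks[0].status == "active"
        assert confirmed == [1]

    def test_active_track_deactivates_after_max_age(self):
        tr = Tracker(TrackerParams(n_init=2, max_age=3))
        for _ in range(3):
            tr.step([BoundingBox(50, 50, 20, 20)])
        deactivated = []
        for _ in range(5):
            deactivated += tr.step([]).deactivated
        assert [t.id for t in deactivated] == [1]
        assert tr.tracks[0].status == "inactive"

    def test_ids_never_reused(self):
        tr = Tracker(TrackerParams(n_init=2))
        seen = set()
        rng = np.random.default_rng(5)
        for i in range(30):
            dets = [BoundingBox(float(rng.uniform(10, 400)),
                                float(rng.uniform(10, 400)), 15, 15)
                    for _ in range(rng.integers(0, 4))]
            res = tr.step(dets)
            for tid in res.new_track_ids:
                assert tid not in seen
                seen.add(tid)

    def test_gallery_fifo_capped_at_100(self):
        tr = Tracker()
        first = unit(np.arange(1.0, 9.0))
        det0 = BoundingBox(50, 50, 20, 20)
        det0.descriptor = AppearanceDescriptor(first)
        tr.step([det0])
        rng = np.random.default_rng(0)
        for _ in range(120):
            det = BoundingBox(50, 50, 20, 20)
            det.descriptor = AppearanceDescriptor(unit(rng.normal(size=8)))
            tr.step([det])
        track = tr.tracks[0]
        assert len(track.gallery) == 100
        assert not any(np.allclose(g.r, first) for g in track.gallery)

    def test_status_transitions_are_monotone(self):
        tr = Tracker(TrackerParams(n_init=2, max_age=1))
        order = {"tentative": 0, "active": 1, "inactive": 2}
        history = {}
        rng = np.random.default_rng(9)
        for i in range(25):
            dets = ([BoundingBox(50, 50, 20, 20)] if rng.random() < 0.7 else [])
            tr.step(dets)
            for t in tr.tracks:
                prev = history.get(t.id, 0)
                assert order[t.status] >= prev
                history[t.id] = order[t.status]


def test_hsv_histogram_descriptor_is_unit_norm_and_distinctive(rng):
    img = np.zeros((60, 60, 3), dtype=np.uint8)
    img[10:30, 10:30] = (200, 30, 30)      # red patch
    img[35:55, 35:55] = (30, 180, 40)      # green patch
    red = hsv_histogram_descriptor(img, BoundingBox(20, 20, 18, 18))
    green = hsv_histogram_descriptor(img, BoundingBox(45, 45, 18, 18))
    assert np.linalg.norm(red.r) == pytest.approx(1.0)
    assert float(red.r @ green.r) < 0.5
    red2 = hsv_histogram_descriptor(img, BoundingBox(20, 20, 16, 16))
    assert float(red.r @ red2.r) > 0.9
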