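import itertools

import numpy as np
import pytest

from pentrack import (
    Box,
    ByteTracker,
    Detection,
    FrameStream,
    KalmanFilter,
    ObjectClass,
    ScenarioConfig,
    Track,
    TrackStatus,
    TrackerParams,
    byte_associate_frame,
    linear_assignment,
    run_tracker,
    simulate_scenario,
)
from pentrack.io import MotValidationError


def brute_force_assignment(cost):
    """Oracle: exhaustive search over all one-to-one assignments."""
    n_rows, n_cols = cost.shape
    k = min(n_rows, n_cols)
    best, best_total = None, np.inf
    rows_sets = itertools.combinations(range(n_rows), k)
    for rows in rows_sets:
        for cols in itertools.permutations(range(n_cols), k):
            total = sum(cost[r, c] for r, c in zip(rows, cols))
            if total < best_total - 1e-12:
                best_total = total
                best = list(zip(rows, cols))
    return best, best_total


class TestLinearAssignment:
    def test_worked_example(self):
        matches, ur, uc = linear_assignment(np.array([[1.0, 2.0], [2.0, 4.0]]), 10.0)
        assert set(matches) == {(0, 1), (1, 0)}  # total 4 beats 5
        assert ur == [] and uc == []

    def test_zero_diagonal(self):
        matches, _, _ = linear_assignment(np.array([[0.0, 1.0], [1.0, 0.0]]), 10.0)
        assert set(matches) == {(0, 0), (1, 1)}

    def test_threshold_dissolution(self):
        matches, ur, uc = linear_assignment(np.array([[0.9]]), 0.8)
        assert matches == [] and ur == [0] and uc == [0]

    def test_empty_matrix(self):
        matches, ur, uc = linear_assignment(np.zeros((0, 3)), 1.0)
        assert matches == [] and ur == [] and uc == [0, 1, 2]

    def test_matches_brute_force_small(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n, m = rng.integers(1, 5, size=2)
            cost = rng.uniform(0, 1, (n, m))
            matches, _, _ = linear_assignment(cost, max_cost=np.inf)
            _, best_total = brute_force_assignment(cost)
            total = sum(cost[r, c] for r, c in matches)
            assert total == pytest.approx(best_total, abs=1e-6)

    def test_deterministic_on_ties(self):
        cost = np.ones((3, 3))
        first = linear_assignment(cost, 2.0)
        for _ in range(5):
            assert linear_assignment(cost, 2.0) == first
        assert first[0] == [(0, 0), (1, 1), (2, 2)]  # lexicographic preference


def _det(frame, box, score, cls=ObjectClass.PIG):
    return Detection(frame, box, score, cls)


def _active_track(track_id, box, frame=1, kf=None):
    kf = kf or KalmanFilter()
    return Track(track_id, kf.initiate(box), ObjectClass.PIG, 0.9, frame, box, activated=True)


class TestTrackerParams:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(MotValidationError):
            TrackerParams(high_thresh=0.1, low_thresh=0.6)

    def test_retention_minimum(self):
        with pytest.raises(MotValidationError):
            TrackerParams(max_lost_frames=0)


class TestByteAssociateFrame:
    def test_high_score_match(self):
        params = TrackerParams()
        box = Box(0, 0, 20, 20)
        track = _active_track(1, box)
        tracks = byte_associate_frame([track], [_det(2, Box(1, 0, 21, 20), 0.9)], params, frame=2)
        assert tracks[0].frames_since_update == 0
        assert tracks[0].status is TrackStatus.ACTIVE
        assert len(tracks[0].history) == 2

    def test_retention_30_frames(self):
        params = TrackerParams(max_lost_frames=30)
        kf = KalmanFilter()
        track = _active_track(1, Box(0, 0, 20, 20), kf=kf)
        for frame in range(2, 33):  # 31 consecutive unmatched frames
            track.predict(kf)
            byte_associate_frame([track], [], params, frame=frame, kf=kf)
        assert track.frames_since_update == 31
        assert track.status is TrackStatus.REMOVED

    def test_lost_within_retention(self):
        params = TrackerParams(max_lost_frames=30)
        kf = KalmanFilter()
        track = _active_track(1, Box(0, 0, 20, 20), kf=kf)
        for frame in range(2, 32):  # exactly 30 unmatched frames
            track.predict(kf)
            byte_associate_frame([track], [], params, frame=frame, kf=kf)
        assert track.status is TrackStatus.LOST

    def test_new_track_created(self):
        params = TrackerParams()
        tracks = byte_associate_frame([], [_det(1, Box(0, 0, 20, 20), 0.95)], params, frame=1)
        assert len(tracks) == 1
        assert tracks[0].track_id == 1

    def test_low_score_no_new_track(self):
        params = TrackerParams()
        tracks = byte_associate_frame([], [_det(1, Box(0, 0, 20, 20), 0.5)], params, frame=1)
        assert tracks == []

    def test_second_association_occlusion_recovery(self):
        params = TrackerParams()
        box = Box(0, 0, 20, 20)
        track = _active_track(1, box)
        tracks = byte_associate_frame(
            [track], [_det(2, Box(0, 0, 20, 18), 0.3)], params, frame=2
        )
        assert tracks[0].frames_since_update == 0
        assert tracks[0].history.entries[-1][2] == 0.3

    def test_lost_track_skips_second_association(self):
        params = TrackerParams()
        kf = KalmanFilter()
        track = _active_track(1, Box(0, 0, 20, 20), kf=kf)
        track.predict(kf)
        byte_associate_frame([track], [], params, frame=2, kf=kf)
        assert track.status is TrackStatus.LOST
        track.predict(kf)
        byte_associate_frame([track], [_det(3, Box(0, 0, 20, 19), 0.3)], params, frame=3, kf=kf)
        assert track.status is TrackStatus.LOST  # low-score det cannot reclaim it

    def test_lost_track_rematched_by_high_score(self):
        params = TrackerParams()
        kf = KalmanFilter()
        track = _active_track(1, Box(0, 0, 20, 20), kf=kf)
        for frame in (2, 3, 4):
            track.predict(kf)
            byte_associate_frame([track], [], params, frame=frame, kf=kf)
        assert track.status is TrackStatus.LOST
        track.predict(kf)
        byte_associate_frame([track], [_det(5, Box(0, 0, 20, 20), 0.9)], params, frame=5, kf=kf)
        assert track.status is TrackStatus.ACTIVE

    def test_detection_consumed_once(self):
        params = TrackerParams()
        a = _active_track(1, Box(0, 0, 20, 20))
        b = _active_track(2, Box(5, 0, 25, 20))
        det = _det(2, Box(2, 0, 22, 20), 0.9)
        tracks = byte_associate_frame([a, b], [det], params, frame=2)
        updated = [t for t in tracks if t.frames_since_update == 0]
        assert len(updated) == 1


class TestRunTracker:
    def test_empty_stream(self):
        assert run_tracker(FrameStream([], fps=25)) == []

    def test_three_separated_pigs(self):
        truth, stream = simulate_scenario(
            ScenarioConfig(n_pigs=3, n_frames=100, confine_to_cells=True, seed=2)
        )
        records = run_tracker(stream)
        assert len(records) == 3
        assert all(len(r) == 100 for r in records)

    def test_gap_within_retention_spans_single_track(self):
        box = Box(100, 100, 140, 130)
        dets = [
            _det(f, box, 0.9)
            for f in list(range(1, 51)) + list(range(61, 101))  # 10-frame gap
        ]
        records = run_tracker(FrameStream(dets, fps=25))
        assert len(records) == 1
        assert records[0].first_frame() == 1 and records[0].last_frame() == 100

    def test_gap_beyond_retention_splits_track(self):
        box = Box(100, 100, 140, 130)
        dets = [
            _det(f, box, 0.9)
            for f in list(range(1, 51)) + list(range(82, 131))  # 31-frame gap
        ]
        records = run_tracker(FrameStream(dets, fps=25))
        assert len(records) == 2

    def test_ids_unique_and_monotone(self):
        cfg = ScenarioConfig(n_pigs=8, n_frames=200, seed=9, miss_prob=0.05,
                             jitter_sd=1.0, occlusion_miss_boost=0.2)
        _, stream = simulate_scenario(cfg)
        records = run_tracker(stream)
        ids = [r.track_id for r in records]
        assert len(set(ids)) == len(ids)
        assert ids == sorted(ids)
        # creation order follows id order
        first_frames = [r.first_frame() for r in sorted(records, key=lambda r: r.track_id)]
        assert first_frames == sorted(first_frames)

    def test_deterministic_and_order_independent(self):
        cfg = ScenarioConfig(n_pigs=6, n_frames=120, seed=4, jitter_sd=1.0)
        _, stream = simulate_scenario(cfg)
        rec1 = run_tracker(stream)
        shuffled = FrameStream(list(stream.detections())[::-1], fps=stream.fps)
        rec2 = run_tracker(shuffled)
        assert [r.track_id for r in rec1] == [r.track_id for r in rec2]
        for a, b in zip(rec1, rec2):
            assert a.frames == b.frames
            assert all(x.almost_equal(y, 1e-9) for x, y in zip(a.boxes, b.boxes))

    def test_identity_conservation_per_frame(self):
        cfg = ScenarioConfig(n_pigs=8, n_frames=150, seed=13, jitter_sd=1.5)
        _, stream = simulate_scenario(cfg)
        records = run_tracker(stream)
        claims: dict[int, int] = {}
        for rec in records:
            for f in rec.frames:
                claims[f] = claims.get(f, 0) + 1
        for f, n_claimed in claims.items():
            assert n_claimed <= len(stream.at(f))
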