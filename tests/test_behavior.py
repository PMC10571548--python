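import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pentrack import (
    Box,
    FightEvent,
    ObjectClass,
    RFIDRead,
    TrackRecord,
    fight_intervals,
    fight_participants,
    movement_statistics,
    rfid_link,
)
from pentrack.behavior import BindingConflictError
from pentrack.io import MotValidationError


def _track(track_id, centers, size=10.0, start_frame=1, step=1):
    rec = TrackRecord(track_id, ObjectClass.PIG)
    h = size / 2
    for i, (x, y) in enumerate(centers):
        rec.append(start_frame + i * step, Box(x - h, y - h, x + h, y + h), 0.9)
    return rec


class TestMovementStatistics:
    def test_two_345_segments(self):
        rec = _track(1, [(0, 0), (3, 4), (6, 8)])
        mv = movement_statistics(rec, fps=25)
        assert mv.total_distance_px == pytest.approx(10.0)

    def test_unit_conversion(self):
        rec = _track(1, [(0, 0), (5, 0), (10, 0)], start_frame=0)
        mv = movement_statistics(rec, fps=2, px_per_m=100)
        assert mv.total_distance_m == pytest.approx(0.1)
        assert mv.duration_s == pytest.approx(1.0)
        assert mv.mean_speed == pytest.approx(0.1)
        assert mv.speed_units == "m/s"

    def test_stationary(self):
        rec = _track(1, [(50, 50)] * 50)
        assert movement_statistics(rec, fps=25).total_distance_px == 0.0

    def test_single_box_flagged(self):
        mv = movement_statistics(_track(1, [(0, 0)]), fps=25)
        assert mv.total_distance_px == 0.0
        assert mv.duration_s == 0.0
        assert mv.mean_speed == 0.0
        assert not mv.speed_defined

    def test_simulator_bookkeeping_oracle(self):
        from pentrack import ScenarioConfig, simulate_scenario

        cfg = ScenarioConfig(n_pigs=4, n_frames=200, seed=21)
        truth, _ = simulate_scenario(cfg)
        for rec in truth.tracks:
            mv = movement_statistics(rec, cfg.fps)
            assert mv.total_distance_px == pytest.approx(
                truth.distances[rec.track_id], abs=1e-6
            )

    @given(
        st.lists(st.tuples(st.floats(-100, 100), st.floats(-100, 100)), min_size=2, max_size=20),
        st.floats(-50, 50),
        st.floats(0.1, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_translation_and_scale(self, centers, shift, k):
        base = movement_statistics(_track(1, centers), fps=25).total_distance_px
        moved = movement_statistics(
            _track(1, [(x + shift, y + shift) for x, y in centers]), fps=25
        ).total_distance_px
        scaled = movement_statistics(
            _track(1, [(k * x, k * y) for x, y in centers]), fps=25
        ).total_distance_px
        assert moved == pytest.approx(base, abs=1e-6)
        assert scaled == pytest.approx(k * base, rel=1e-9, abs=1e-6)

    def test_distance_at_least_straight_line(self):
        centers = [(0, 0), (10, 3), (4, 9), (20, 20)]
        mv = movement_statistics(_track(1, centers), fps=25)
        straight = math.hypot(20, 20)
        assert mv.total_distance_px >= straight - 1e-12


class TestFightIntervals:
    def test_single_run(self, fight_stream_factory):
        events = fight_intervals(fight_stream_factory(range(5, 10)), 25, 1, 0)
        assert [(e.t1_frame, e.t2_frame) for e in events] == [(5, 9)]
        assert events[0].t1_s == pytest.approx(5 / 25)
        assert events[0].n_frames == 5

    def test_merge_gap(self, fight_stream_factory):
        stream = fight_stream_factory(list(range(10, 21)) + list(range(22, 31)))
        merged = fight_intervals(stream, 25, 1, 2)
        assert [(e.t1_frame, e.t2_frame) for e in merged] == [(10, 30)]
        split = fight_intervals(stream, 25, 1, 0)
        assert [(e.t1_frame, e.t2_frame) for e in split] == [(10, 20), (22, 30)]

    def test_empty(self, fight_stream_factory):
        assert fight_intervals(fight_stream_factory([]), 25, 1, 0) == []

    def test_min_len_drops_flicker(self, fight_stream_factory):
        stream = fight_stream_factory([5, 40, 41, 42, 43])
        events = fight_intervals(stream, 25, 3, 0)
        assert [(e.t1_frame, e.t2_frame) for e in events] == [(40, 43)]

    def test_class_purity_enforced(self, make_detection):
        from pentrack import FrameStream

        stream = FrameStream([make_detection(1, 0, 0, 5, 5, cls=ObjectClass.PIG)], fps=25)
        with pytest.raises(MotValidationError):
            fight_intervals(stream, 25, 1, 0)

    def test_exact_partition_property(self, fight_stream_factory):
        frames = [3, 4, 5, 9, 10, 17, 30, 31, 32]
        events = fight_intervals(fight_stream_factory(frames), 25, 1, 0)
        covered = sorted(
            f
            for e in events
            for f in range(e.t1_frame, e.t2_frame + 1)
        )
        assert covered == frames

    @given(
        st.sets(st.integers(1, 60), min_size=1, max_size=25),
        st.integers(0, 8),
    )
    @settings(max_examples=60, deadline=None)
    def test_merge_gap_monotone(self, frames, gap):
        from pentrack import Detection, FrameStream

        stream = FrameStream(
            [
                Detection(f, Box(0, 0, 10, 10), 0.9, ObjectClass.PIG_FIGHTING)
                for f in sorted(frames)
            ],
            fps=25,
        )
        n_small = len(fight_intervals(stream, 25, 1, gap))
        n_large = len(fight_intervals(stream, 25, 1, gap + 3))
        assert n_large <= n_small


class TestFightParticipants:
    def test_union_box_attributes_pair(self):
        a = _track(1, [(10, 10)] * 5, size=20)
        b = _track(2, [(28, 10)] * 5, size=20)
        c = _track(3, [(300, 300)] * 5, size=20)
        fight_boxes = {
            f: a.box_at(f).union(b.box_at(f)) for f in range(1, 6)
        }
        event = FightEvent(1, 5)
        assert fight_participants(event, fight_boxes, [a, b, c]) == {1, 2}

    def test_no_overlap_empty(self):
        far = _track(7, [(500, 500)] * 3, size=10)
        fight_boxes = {f: Box(0, 0, 30, 30) for f in range(1, 4)}
        assert fight_participants(FightEvent(1, 3), fight_boxes, [far]) == frozenset()

    def test_single_overlapping(self):
        a = _track(1, [(10, 10)] * 3, size=20)
        fight_boxes = {f: Box(0, 0, 30, 30) for f in range(1, 4)}
        assert fight_participants(FightEvent(1, 3), fight_boxes, [a]) == {1}

    def test_uncovered_event_raises(self):
        with pytest.raises(MotValidationError):
            fight_participants(FightEvent(1, 3), {}, [])


ZONE = Box(0, 0, 100, 100)


class TestRfidLink:
    def test_simple_binding(self):
        inside = _track(1, [(50, 50)] * 10)
        outside = _track(2, [(500, 500)] * 10)
        result = rfid_link([inside, outside], [RFIDRead(0.2, "tagA")], ZONE, fps=25)
        assert result.mapping == {1: "tagA"}

    def test_no_track_in_zone(self):
        outside = _track(2, [(500, 500)] * 10)
        result = rfid_link([outside], [RFIDRead(0.2, "tagA")], ZONE, fps=25)
        assert result.mapping == {}
        assert len(result.skipped) == 1

    def test_ambiguous_read_skipped(self):
        a = _track(1, [(50, 50)] * 10)
        b = _track(2, [(60, 60)] * 10)
        result = rfid_link([a, b], [RFIDRead(0.2, "tagA")], ZONE, fps=25)
        assert result.mapping == {}
        assert "ambiguous" in result.skipped[0][1]

    def test_transfer_after_target_loss(self):
        # track 1 visits the feeder early, then is lost at frame 500;
        # track 9 appears later and visits the feeder at ~frame 900
        early = _track(1, [(50, 50)] * 500)
        late = _track(9, [(50, 50)] * 100, start_frame=850)
        result = rfid_link(
            [early, late],
            [RFIDRead(1.0, "tagA"), RFIDRead(36.0, "tagA")],
            ZONE,
            fps=25,
        )
        assert result.mapping == {9: "tagA"}
        assert result.tracks_for_tag("tagA") == [1, 9]
        assert result.bindings[-1].transferred_from == 1

    def test_live_conflict_raises(self):
        # both tracks span the whole video; tag read on each in turn
        a = _track(1, [(50, 50)] * 10 + [(500, 500)] * 990)
        b = _track(2, [(500, 500)] * 500 + [(50, 50)] * 500)
        reads = [RFIDRead(0.2, "tagA"), RFIDRead(25.0, "tagA")]
        with pytest.raises(BindingConflictError):
            rfid_link([a, b], reads, ZONE, fps=25)
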