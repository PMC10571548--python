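"""Phenotypes from track records: movement, aggression intervals, RFID identity.

Movement: centroids of same-id boxes are joined frame to frame and the
segment lengths accumulated into a total distance (pixels, optionally
meters), with duration and mean speed.

Aggression: an event opens (T1) on the frame where a fighting-class
detection appears and closes (T2) on the frame where it disappears; nearby
runs can be merged and short flickers dropped.  Participants are attributed
to the two pig tracks with the highest mean IoU against the fight box.

RFID: ear-tag reads at a feeder zone bind tag ids to the track currently in
the zone; a read for a tag whose holder has since been lost transfers the
tag to the new track (re-identification after target loss).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io import Box, FrameStream, MotValidationError, ObjectClass, TrackRecord
from .metrics import box_iou

__all__ = [
    "MovementRecord",
    "FightEvent",
    "RFIDRead",
    "IdentityMap",
    "BindingConflictError",
    "movement_statistics",
    "fight_intervals",
    "fight_participants",
    "rfid_link",
]


class BindingConflictError(RuntimeError):
    """An ear tag would be bound to two simultaneously live tracks."""


@dataclass
class MovementRecord:
    """Per-identity centroid polyline with cumulative distance statistics."""

    track_id: int
    polyline: list[tuple[int, float, float]]
    total_distance_px: float
    duration_s: float
    mean_speed: float
    speed_units: str
    total_distance_m: float | None = None
    speed_defined: bool = True


@dataclass
class FightEvent:
    """A [T1, T2] aggression interval, in frames and in seconds."""

    t1_frame: int
    t2_frame: int
    t1_s: float | None = None
    t2_s: float | None = None
    participants: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.t2_frame < self.t1_frame:
            raise MotValidationError("fight event must have T2 >= T1")

    @property
    def n_frames(self) -> int:
        return self.t2_frame - self.t1_frame + 1


@dataclass(frozen=True)
class RFIDRead:
    timestamp: float
    tag_id: str

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise MotValidationError("RFID timestamps must be non-negative")


@dataclass
class Binding:
    tag_id: str
    track_id: int
    time_s: float
    transferred_from: int | None = None


@dataclass
class IdentityMap:
    """track_id -> tag_id binding with its audit log."""

    mapping: dict[int, str]
    zone: Box
    bindings: list[Binding]
    skipped: list[tuple[RFIDRead, str]]

    def tracks_for_tag(self, tag_id: str) -> list[int]:
        """Track ids bound to a tag over time, in binding order."""
        out: list[int] = []
        for b in self.bindings:
            if b.tag_id == tag_id and b.track_id not in out:
                out.append(b.track_id)
        return out


def movement_statistics(
    track: TrackRecord,
    fps: float,
    px_per_m: float | None = None,
) -> MovementRecord:
    """Cumulative centroid path length, duration, and mean speed of a track.

    A single-box track has distance 0 and undefined speed, reported as 0
    with ``speed_defined=False``.
    """
    if not fps > 0:
        raise MotValidationError(f"fps must be positive, got {fps}")
    if px_per_m is not None and not px_per_m > 0:
        raise MotValidationError(f"px_per_m must be positive, got {px_per_m}")
    if len(track) == 0:
        raise MotValidationError("track has no boxes")
    poly = track.centroids()
    total_px = sum(
        math.hypot(x1 - x0, y1 - y0)
        for (_, x0, y0), (_, x1, y1) in zip(poly, poly[1:])
    )
    duration = (track.last_frame() - track.first_frame()) / fps
    total_m = total_px / px_per_m if px_per_m is not None else None
    distance = total_m if total_m is not None else total_px
    units = "m/s" if px_per_m is not None else "px/s"
    if duration > 0:
        return MovementRecord(
            track.track_id, poly, total_px, duration, distance / duration,
            units, total_m,
        )
    return MovementRecord(
        track.track_id, poly, total_px, 0.0, 0.0, units, total_m,
        speed_defined=False,
    )


def fight_intervals(
    stream: FrameStream,
    fps: float | None = None,
    min_len_frames: int = 3,
    merge_gap_frames: int = 12,
) -> list[FightEvent]:
    """Aggression intervals from the fighting-class detection stream.

    T1 is the first frame of a maximal run of frames containing at least
    one fighting detection, T2 the last.  Runs separated by at most
    ``merge_gap_frames`` empty frames are merged; runs shorter than
    ``min_len_frames`` are dropped.  Defaults debounce single-frame
    detector flicker and are fully configurable.
    """
    if min_len_frames < 1:
        raise MotValidationError("min_len_frames must be >= 1")
    if merge_gap_frames < 0:
        raise MotValidationError("merge_gap_frames must be >= 0")
    for det in stream.detections():
        if det.cls is not ObjectClass.PIG_FIGHTING:
            raise MotValidationError(
                "fight_intervals requires a class-pure fighting stream"
            )
    frames = sorted(f for f, dets in stream if dets)
    if not frames:
        return []
    runs: list[list[int]] = [[frames[0], frames[0]]]
    for f in frames[1:]:
        if f - runs[-1][1] - 1 <= merge_gap_frames:
            runs[-1][1] = f
        else:
            runs.append([f, f])
    fps = fps if fps is not None else stream.fps
    events = []
    for t1, t2 in runs:
        if t2 - t1 + 1 < min_len_frames:
            continue
        events.append(
            FightEvent(
                t1,
                t2,
                t1 / fps if fps else None,
                t2 / fps if fps else None,
            )
        )
    return events


def fight_participants(
    event: FightEvent,
    fight_boxes: Mapping[int, Box],
    pig_tracks: Sequence[TrackRecord],
) -> frozenset[int]:
    """The <= 2 pig tracks best explained by the fight box.

    Ranks tracks by mean IoU between their boxes and the fight box over the
    event's frames; the top two with positive mean IoU are returned (ties
    broken by lower track id).  Returns a smaller set when fewer qualify.
    """
    ev_frames = [
        f for f in range(event.t1_frame, event.t2_frame + 1) if f in fight_boxes
    ]
    if not ev_frames:
        raise MotValidationError("event frames not covered by fight boxes")
    scored: list[tuple[float, int]] = []
    for track in pig_tracks:
        total = 0.0
        for f in ev_frames:
            b = track.box_at(f)
            if b is not None:
                total += box_iou(b, fight_boxes[f])
        mean_iou = total / len(ev_frames)
        if mean_iou > 0.0:
            scored.append((mean_iou, track.track_id))
    scored.sort(key=lambda s: (-s[0], s[1]))
    return frozenset(tid for _, tid in scored[:2])


def _in_zone_frames(track: TrackRecord, zone: Box) -> list[int]:
    return [(f) for f, x, y in track.centroids() if zone.contains_point(x, y)]


def rfid_link(
    tracks: Sequence[TrackRecord],
    reads: Sequence[RFIDRead],
    zone: Box,
    fps: float,
    tol_s: float = 0.5,
) -> IdentityMap:
    """Bind ear-tag ids to video track ids via feeder-zone co-occurrence.

    At each read, the unique track whose centroid lies inside ``zone``
    within ``+- tol_s`` seconds is bound to the tag.  Ambiguous reads (two
    tracks in the zone) and empty reads are skipped and logged.  A read for
    a tag held by a track that has since ended transfers the tag — the
    re-identification path after target loss.  Binding a tag to a second
    still-live track raises :class:`BindingConflictError`.
    """
    if not fps > 0:
        raise MotValidationError(f"fps must be positive, got {fps}")
    mapping: dict[int, str] = {}
    bindings: list[Binding] = []
    skipped: list[tuple[RFIDRead, str]] = []
    by_id = {t.track_id: t for t in tracks}
    zone_frames = {t.track_id: set(_in_zone_frames(t, zone)) for t in tracks}

    for read in sorted(reads, key=lambda r: r.timestamp):
        lo = math.floor((read.timestamp - tol_s) * fps)
        hi = math.ceil((read.timestamp + tol_s) * fps)
        window = set(range(lo, hi + 1))
        candidates = sorted(
            tid for tid, zf in zone_frames.items() if zf & window
        )
        if not candidates:
            skipped.append((read, "no track in zone"))
            continue
        if len(candidates) > 1:
            skipped.append((read, f"ambiguous: tracks {candidates} in zone"))
            continue
        tid = candidates[0]
        if mapping.get(tid) == read.tag_id:
            continue  # already bound to this tag
        if tid in mapping:
            skipped.append(
                (read, f"track {tid} already bound to tag {mapping[tid]}")
            )
            continue
        holder = next((t for t, tag in mapping.items() if tag == read.tag_id), None)
        transferred_from = None
        if holder is not None:
            read_frame = read.timestamp * fps
            if by_id[holder].last_frame() >= read_frame - tol_s * fps:
                raise BindingConflictError(
                    f"tag {read.tag_id} bound to live tracks {holder} and {tid}"
                )
            del mapping[holder]
            transferred_from = holder
        mapping[tid] = read.tag_id
        bindings.append(Binding(read.tag_id, tid, read.timestamp, transferred_from))
    return IdentityMap(mapping, zone, bindings, skipped)
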