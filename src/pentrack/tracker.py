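"""Two-stage (BYTE-style) data association over Kalman-predicted tracks.

Per frame: detections are split at a score threshold; high-score detections
are matched first against all live tracks (including recently lost ones) by
IoU distance; low-score detections are then matched against the tracks left
over from the first stage — recovering targets whose score dropped under
occlusion.  Unmatched high-score detections above a creation threshold start
new tracks; tracks unmatched for more than the retention window are removed.

Matching solves a minimum-cost one-to-one assignment (Hungarian algorithm)
on ``1 - IoU`` costs, with pairs beyond a maximum cost dissolved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import Box, Detection, FrameStream, MotValidationError, ObjectClass, TrackRecord
from .kalman import KalmanFilter, KalmanState
from .metrics import iou_matrix

__all__ = [
    "TrackStatus",
    "Track",
    "TrackerParams",
    "ByteTracker",
    "linear_assignment",
    "byte_associate_frame",
    "run_tracker",
]


class TrackStatus(Enum):
    TENTATIVE = "tentative"
    ACTIVE = "active"
    LOST = "lost"
    REMOVED = "removed"


@dataclass
class TrackerParams:
    """Association thresholds; defaults follow the published BYTE settings."""

    high_thresh: float = 0.6
    low_thresh: float = 0.1
    first_match_min_iou: float = 0.2
    second_match_min_iou: float = 0.5
    new_track_thresh: float = 0.7
    max_lost_frames: int = 30

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_thresh < self.high_thresh <= 1.0:
            raise MotValidationError(
                f"need 0 <= low ({self.low_thresh}) < high ({self.high_thresh}) <= 1"
            )
        if self.max_lost_frames < 1:
            raise MotValidationError("max_lost_frames must be >= 1")


class Track:
    """A persistent identity with Kalman state, history, and lifecycle status."""

    def __init__(
        self,
        track_id: int,
        state: KalmanState,
        cls: ObjectClass,
        score: float,
        frame: int,
        box: Box,
        activated: bool = False,
    ) -> None:
        if track_id <= 0:
            raise MotValidationError(f"track_id must be positive, got {track_id}")
        self.track_id = track_id
        self.state = state
        self.cls = cls
        self.score = score
        self.status = TrackStatus.ACTIVE if activated else TrackStatus.TENTATIVE
        self.was_active = activated
        self.frames_since_update = 0
        self.history = TrackRecord(track_id, cls, [(frame, box, score)])

    @property
    def predicted_box(self) -> Box:
        return self.state.to_box()

    def predict(self, kf: KalmanFilter) -> None:
        self.state = kf.predict(self.state)

    def update(self, kf: KalmanFilter, det: Detection, frame: int) -> None:
        self.state = kf.update(self.state, det.box)
        self.score = det.score
        self.status = TrackStatus.ACTIVE
        self.was_active = True
        self.frames_since_update = 0
        self.history.append(frame, det.box, det.score)

    def mark_missed(self, max_lost_frames: int) -> None:
        self.frames_since_update += 1
        if self.status is TrackStatus.TENTATIVE:
            # unconfirmed single-observation tracks are dropped immediately
            self.status = TrackStatus.REMOVED
        elif self.frames_since_update > max_lost_frames:
            self.status = TrackStatus.REMOVED
        else:
            self.status = TrackStatus.LOST

    @property
    def is_live(self) -> bool:
        return self.status is not TrackStatus.REMOVED


def linear_assignment(
    cost: np.ndarray, max_cost: float
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-total-cost one-to-one assignment with threshold dissolution.

    Pairs whose cost exceeds ``max_cost`` are dissolved into the unmatched
    sets.  Among equal-cost optima the lowest (row, col) lexicographic
    assignment is preferred, for determinism.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.size == 0:
        return [], list(range(cost.shape[0])), list(range(cost.shape[1]))
    n_rows, n_cols = cost.shape
    # infinitesimal lexicographic tie-break; too small to alter true optima
    tie = np.arange(n_rows * n_cols, dtype=float).reshape(n_rows, n_cols)
    scale = max(np.max(np.abs(cost)), 1.0)
    rows, cols = linear_sum_assignment(cost + tie * (1e-12 * scale))
    matches, um_rows, um_cols = [], set(range(n_rows)), set(range(n_cols))
    for r, c in zip(rows, cols):
        if cost[r, c] <= max_cost:
            matches.append((int(r), int(c)))
            um_rows.discard(int(r))
            um_cols.discard(int(c))
    return matches, sorted(um_rows), sorted(um_cols)


def _match(
    tracks: Sequence[Track],
    dets: Sequence[Detection],
    min_iou: float,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    ious = iou_matrix([t.predicted_box for t in tracks], [d.box for d in dets])
    return linear_assignment(1.0 - ious, max_cost=1.0 - min_iou)


def byte_associate_frame(
    tracks: list[Track],
    detections: Sequence[Detection],
    params: TrackerParams,
    frame: int,
    next_id: Callable[[], int] | None = None,
    kf: KalmanFilter | None = None,
    first_frame: bool = False,
) -> list[Track]:
    """One BYTE association step.  ``tracks`` must already be predicted.

    Returns the updated track list (new tracks appended; removed tracks
    retained in the list with status REMOVED so callers can collect them).
    """
    kf = kf or _DEFAULT_KF
    if next_id is None:
        counter = itertools.count(max((t.track_id for t in tracks), default=0) + 1)
        next_id = lambda: next(counter)  # noqa: E731

    dets = sorted(detections, key=lambda d: -d.score)
    high = [d for d in dets if d.score >= params.high_thresh]
    low = [d for d in dets if params.low_thresh <= d.score < params.high_thresh]

    pool1 = [t for t in tracks if t.is_live]
    matches, um_tracks, um_high = _match(pool1, high, params.first_match_min_iou)
    for ti, di in matches:
        pool1[ti].update(kf, high[di], frame)

    # second stage: low-score detections vs tracks still unmatched;
    # lost tracks take part in the first association only
    pool2 = [pool1[i] for i in um_tracks if pool1[i].status is not TrackStatus.LOST]
    still_lost = [pool1[i] for i in um_tracks if pool1[i].status is TrackStatus.LOST]
    matches2, um2_tracks, _um_low = _match(pool2, low, params.second_match_min_iou)
    for ti, di in matches2:
        pool2[ti].update(kf, low[di], frame)

    for t in [pool2[i] for i in um2_tracks] + still_lost:
        t.mark_missed(params.max_lost_frames)

    for di in um_high:
        det = high[di]
        if det.score >= params.new_track_thresh:
            tracks.append(
                Track(
                    next_id(),
                    kf.initiate(det.box),
                    det.cls,
                    det.score,
                    frame,
                    det.box,
                    activated=first_frame,
                )
            )
    return tracks


_DEFAULT_KF = KalmanFilter()


class ByteTracker:
    """Stateful frame-by-frame tracker for one detection class."""

    def __init__(
        self,
        params: TrackerParams | None = None,
        kf: KalmanFilter | None = None,
    ) -> None:
        self.params = params or TrackerParams()
        self.kf = kf or KalmanFilter()
        self.tracks: list[Track] = []
        self.finished: list[Track] = []
        self._ids = itertools.count(1)
        self._started = False

    def step(self, frame: int, detections: Sequence[Detection]) -> list[Track]:
        """Advance one video frame; returns currently active tracks."""
        for t in self.tracks:
            t.predict(self.kf)
        byte_associate_frame(
            self.tracks,
            detections,
            self.params,
            frame,
            next_id=lambda: next(self._ids),
            kf=self.kf,
            first_frame=not self._started,
        )
        if detections or self.tracks:
            self._started = True
        self.finished.extend(t for t in self.tracks if not t.is_live)
        self.tracks = [t for t in self.tracks if t.is_live]
        return [t for t in self.tracks if t.status is TrackStatus.ACTIVE]

    def all_confirmed(self) -> list[Track]:
        every = self.finished + self.tracks
        return sorted(
            (t for t in every if t.was_active), key=lambda t: t.track_id
        )


def run_tracker(
    stream: FrameStream,
    params: TrackerParams | None = None,
    cls: ObjectClass = ObjectClass.PIG,
) -> list[TrackRecord]:
    """Track one class through a detection stream.

    Iterates every video frame between the stream's first and last index
    (empty frames age the tracks), running predict -> associate -> update.
    Returns the histories of all tracks that were ever confirmed, with
    unique, never-reused, monotonically increasing ids.
    """
    sub = stream.restrict(cls)
    if not sub:
        return []
    tracker = ByteTracker(params)
    first, last = sub.frame_range()
    for frame in range(first, last + 1):
        tracker.step(frame, sub.at(frame))
    return [t.history for t in tracker.all_confirmed()]
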