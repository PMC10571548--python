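"""Domain types and MOT-Challenge-style CSV readers/writers.

Boxes are continuous corner rectangles ``(x1, y1, x2, y2)`` with the origin
at the top-left of the frame, x growing rightward and y downward.  Frame
indices are 1-based on disk (MOT convention) and kept 1-based at every
public interface; wall-clock timestamps are ``frame / fps`` seconds.

The on-disk dialect is the 9-column MOT CSV::

    frame, id, bb_left, bb_top, bb_width, bb_height, conf, class, visibility

with ``id == -1`` for raw detections and a real positive id for tracker
output.  Class codes are ``0 -> pig`` and ``1 -> pig_fighting``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "ObjectClass",
    "Box",
    "Detection",
    "FrameStream",
    "TrackRecord",
    "MotParseError",
    "MotValidationError",
    "read_mot_detections",
    "read_mot_tracks",
    "write_mot_detections",
    "write_mot_tracks",
]


class MotParseError(ValueError):
    """A CSV row could not be parsed; the message names the 1-based line."""


class MotValidationError(ValueError):
    """Parsed content violates a domain invariant (class code, duplicate id...)."""


class ObjectClass(Enum):
    """Closed two-class vocabulary of the detector."""

    PIG = "pig"
    PIG_FIGHTING = "pig_fighting"

    @property
    def code(self) -> int:
        return _CLASS_TO_CODE[self]

    @classmethod
    def from_code(cls, code: int) -> "ObjectClass":
        try:
            return _CODE_TO_CLASS[code]
        except KeyError:
            raise MotValidationError(f"unknown class code {code!r}") from None


_CODE_TO_CLASS = {0: ObjectClass.PIG, 1: ObjectClass.PIG_FIGHTING}
_CLASS_TO_CODE = {v: k for k, v in _CODE_TO_CLASS.items()}


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in pixel coordinates with positive area."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise MotValidationError(
                f"degenerate box ({self.x1}, {self.y1}, {self.x2}, {self.y2})"
            )

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    @classmethod
    def from_ltwh(cls, left: float, top: float, width: float, height: float) -> "Box":
        return cls(left, top, left + width, top + height)

    def to_ltwh(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.width, self.height)

    def union(self, other: "Box") -> "Box":
        return Box(
            min(self.x1, other.x1),
            min(self.y1, other.y1),
            max(self.x2, other.x2),
            max(self.y2, other.y2),
        )

    def contains_point(self, x: float, y: float) -> bool:
        return self.x1 <= x <= self.x2 and self.y1 <= y <= self.y2

    def shifted(self, dx: float, dy: float) -> "Box":
        return Box(self.x1 + dx, self.y1 + dy, self.x2 + dx, self.y2 + dy)

    def almost_equal(self, other: "Box", tol: float = 1e-2) -> bool:
        return (
            abs(self.x1 - other.x1) <= tol
            and abs(self.y1 - other.y1) <= tol
            and abs(self.x2 - other.x2) <= tol
            and abs(self.y2 - other.y2) <= tol
        )


@dataclass(frozen=True)
class Detection:
    """One scored, classed bounding box in one frame."""

    frame: int
    box: Box
    score: float
    cls: ObjectClass

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise MotValidationError(f"negative frame index {self.frame}")
        if not 0.0 <= self.score <= 1.0:
            raise MotValidationError(f"score {self.score} outside [0, 1]")


class FrameStream:
    """Ordered map frame-index -> detections, with an optional fps.

    ``fps`` is never defaulted: it must be supplied by the caller whenever
    wall-clock quantities are derived.  ``None`` restricts the stream to
    frame-unit outputs.
    """

    def __init__(
        self,
        detections: Iterable[Detection] = (),
        fps: float | None = None,
    ) -> None:
        if fps is not None and not fps > 0:
            raise MotValidationError(f"fps must be positive, got {fps}")
        self.fps = fps
        self._frames: dict[int, list[Detection]] = {}
        for det in detections:
            self._frames.setdefault(det.frame, []).append(det)
        self._frames = dict(sorted(self._frames.items()))

    @property
    def frames(self) -> Mapping[int, Sequence[Detection]]:
        return self._frames

    @property
    def frame_indices(self) -> list[int]:
        return list(self._frames)

    @property
    def n_detections(self) -> int:
        return sum(len(v) for v in self._frames.values())

    def __len__(self) -> int:
        return len(self._frames)

    def __bool__(self) -> bool:
        return bool(self._frames)

    def __iter__(self) -> Iterator[tuple[int, Sequence[Detection]]]:
        return iter(self._frames.items())

    def detections(self) -> Iterator[Detection]:
        for dets in self._frames.values():
            yield from dets

    def at(self, frame: int) -> Sequence[Detection]:
        return self._frames.get(frame, ())

    def frame_range(self) -> tuple[int, int]:
        if not self._frames:
            raise MotValidationError("empty stream has no frame range")
        keys = self._frames.keys()
        return min(keys), max(keys)

    def restrict(self, cls: ObjectClass) -> "FrameStream":
        """Class-pure substream (same fps)."""
        return FrameStream(
            (d for d in self.detections() if d.cls is cls), fps=self.fps
        )

    def time_of(self, frame: int) -> float:
        if self.fps is None:
            raise MotValidationError("stream has no fps; timestamps unavailable")
        return frame / self.fps


@dataclass
class TrackRecord:
    """A persistent identity: per-frame (frame, box, score) of one object."""

    track_id: int
    cls: ObjectClass
    entries: list[tuple[int, Box, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.track_id <= 0:
            raise MotValidationError(f"track_id must be positive, got {self.track_id}")
        frames = [f for f, _, _ in self.entries]
        if any(b >= a for a, b in zip(frames[1:], frames)):
            raise MotValidationError(
                f"track {self.track_id}: frames not strictly increasing"
            )

    def append(self, frame: int, box: Box, score: float) -> None:
        if self.entries and frame <= self.entries[-1][0]:
            raise MotValidationError(
                f"track {self.track_id}: frame {frame} not after {self.entries[-1][0]}"
            )
        self.entries.append((frame, box, score))

    @property
    def frames(self) -> list[int]:
        return [f for f, _, _ in self.entries]

    @property
    def boxes(self) -> list[Box]:
        return [b for _, b, _ in self.entries]

    def centroids(self) -> list[tuple[int, float, float]]:
        return [(f, *b.center) for f, b, _ in self.entries]

    def first_frame(self) -> int:
        return self.entries[0][0]

    def last_frame(self) -> int:
        return self.entries[-1][0]

    def box_at(self, frame: int) -> Box | None:
        for f, b, _ in self.entries:
            if f == frame:
                return b
        return None

    def __len__(self) -> int:
        return len(self.entries)


_N_COLUMNS = 9


def _parse_row(row: list[str], lineno: int) -> tuple[int, int, Box, float, ObjectClass]:
    if len(row) != _N_COLUMNS:
        raise MotParseError(
            f"line {lineno}: expected {_N_COLUMNS} columns, got {len(row)}"
        )
    try:
        frame = int(row[0])
        obj_id = int(row[1])
        left, top, w, h = (float(v) for v in row[2:6])
        conf = float(row[6])
        code = int(row[7])
    except ValueError as exc:
        raise MotParseError(f"line {lineno}: {exc}") from None
    if w <= 0 or h <= 0:
        raise MotParseError(
            f"line {lineno}: non-positive box size ({w} x {h})"
        )
    if not math.isfinite(left + top + w + h + conf):
        raise MotParseError(f"line {lineno}: non-finite value")
    cls = ObjectClass.from_code(code)
    return frame, obj_id, Box.from_ltwh(left, top, w, h), conf, cls


def _iter_rows(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            yield lineno, [c.strip() for c in row]


def read_mot_detections(path: str | Path, fps: float | None = None) -> FrameStream:
    """Read a MOT det-dialect CSV into a FrameStream.

    Rows with non-positive width/height raise :class:`MotParseError` naming
    the offending line; unknown class codes raise :class:`MotValidationError`.
    An empty file yields an empty stream.
    """
    dets = []
    for lineno, row in _iter_rows(path):
        frame, _obj_id, box, conf, cls = _parse_row(row, lineno)
        if not 0.0 <= conf <= 1.0:
            raise MotParseError(f"line {lineno}: confidence {conf} outside [0, 1]")
        dets.append(Detection(frame, box, conf, cls))
    return FrameStream(dets, fps=fps)


def read_mot_tracks(path: str | Path) -> list[TrackRecord]:
    """Read a MOT track-dialect CSV (real positive ids) into TrackRecords."""
    rows: dict[int, list[tuple[int, Box, float, ObjectClass]]] = {}
    for lineno, raw in _iter_rows(path):
        frame, obj_id, box, conf, cls = _parse_row(raw, lineno)
        if obj_id <= 0:
            raise MotParseError(f"line {lineno}: track id must be positive, got {obj_id}")
        rows.setdefault(obj_id, []).append((frame, box, conf, cls))
    records = []
    for obj_id in sorted(rows):
        entries = sorted(rows[obj_id], key=lambda e: e[0])
        seen = set()
        for f, _, _, _ in entries:
            if f in seen:
                raise MotValidationError(
                    f"track {obj_id}: duplicate entry for frame {f}"
                )
            seen.add(f)
        cls = entries[0][3]
        rec = TrackRecord(obj_id, cls)
        for f, b, s, _ in entries:
            rec.append(f, b, s)
        records.append(rec)
    return records


def _format_row(frame: int, obj_id: int, box: Box, score: float, cls: ObjectClass) -> str:
    left, top, w, h = box.to_ltwh()
    return (
        f"{frame},{obj_id},{left:.2f},{top:.2f},{w:.2f},{h:.2f},"
        f"{score:.6f},{cls.code},1"
    )


def write_mot_detections(stream: FrameStream, path: str | Path) -> None:
    """Write a FrameStream as a det-dialect CSV (id column -1)."""
    lines = [
        _format_row(d.frame, -1, d.box, d.score, d.cls)
        for _, dets in stream
        for d in dets
    ]
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


def write_mot_tracks(tracks: Sequence[TrackRecord], path: str | Path) -> None:
    """Write TrackRecords as a track-dialect CSV, rows sorted by (frame, id).

    Coordinates round-trip through :func:`read_mot_tracks` to 2 decimals.
    Duplicate (frame, id) pairs raise :class:`MotValidationError`.
    """
    rows: list[tuple[int, int, Box, float, ObjectClass]] = []
    seen: set[tuple[int, int]] = set()
    for rec in tracks:
        if rec.track_id <= 0:
            raise MotValidationError(f"track id must be positive, got {rec.track_id}")
        for frame, box, score in rec.entries:
            key = (frame, rec.track_id)
            if key in seen:
                raise MotValidationError(f"duplicate (frame, id) pair {key}")
            seen.add(key)
            rows.append((frame, rec.track_id, box, score, rec.cls))
    rows.sort(key=lambda r: (r[0], r[1]))
    lines = [_format_row(f, i, b, s, c) for f, i, b, s, c in rows]
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")
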