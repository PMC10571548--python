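"""Seeded pen-scenario simulator and tracking-quality scoring.

Generates ground-truth trajectories (waypoint-seeking random walks inside a
1920x1080-style pen, 8-20 animals typical), scripted fight episodes during
which a pair converges and a fighting-class detection equal to the pair's
union box is emitted, and a degraded detection stream (corner jitter, score
draws, random misses with an occlusion boost).  Occluded animals draw low
scores below the usual BYTE split so the second association stage is
genuinely exercised.

A single integer seed drives one ``numpy`` generator; draw order is fixed,
so identical configs produce byte-identical streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .behavior import FightEvent
from .io import Box, Detection, FrameStream, MotValidationError, ObjectClass, TrackRecord
from .metrics import iou_matrix

__all__ = [
    "FightEpisode",
    "ScenarioConfig",
    "GroundTruth",
    "TrackingReport",
    "simulate_scenario",
    "evaluate_tracking",
]


@dataclass(frozen=True)
class FightEpisode:
    """Scripted aggression window between a pair of animals."""

    start_frame: int
    end_frame: int
    pig_a: int
    pig_b: int

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise MotValidationError("episode end before start")
        if self.pig_a == self.pig_b:
            raise MotValidationError("episode needs two distinct pigs")


@dataclass(frozen=True)
class ScenarioConfig:
    n_pigs: int = 12
    pen: Box = field(default_factory=lambda: Box(0, 0, 1920, 1080))
    n_frames: int = 500
    fps: float = 25.0
    # motion
    speed_mean: float = 3.0
    speed_sd: float = 1.0
    heading_noise_sd: float = 0.3
    # body size
    width_mean: float = 140.0
    width_sd: float = 12.0
    height_mean: float = 90.0
    height_sd: float = 8.0
    fight_episodes: tuple[FightEpisode, ...] = ()
    # detection degradation
    jitter_sd: float = 0.0
    miss_prob: float = 0.0
    occlusion_iou: float = 0.3
    occlusion_miss_boost: float = 0.0
    score_high_mean: float = 0.88
    score_high_sd: float = 0.05
    score_low_mean: float = 0.35
    score_low_sd: float = 0.08
    #: confine each animal to its own grid cell -> boxes never overlap
    confine_to_cells: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pigs < 1:
            raise MotValidationError("n_pigs must be >= 1")
        if self.n_frames < 1:
            raise MotValidationError("n_frames must be >= 1")
        if not self.fps > 0:
            raise MotValidationError("fps must be positive")
        for sd in (self.speed_sd, self.heading_noise_sd, self.width_sd,
                   self.height_sd, self.jitter_sd):
            if sd < 0:
                raise MotValidationError("standard deviations must be >= 0")
        if not 0 <= self.miss_prob <= 1:
            raise MotValidationError("miss_prob must be in [0, 1]")
        if self.width_mean >= self.pen.width or self.height_mean >= self.pen.height:
            raise MotValidationError("pig size exceeds pen: infeasible scenario")
        for ep in self.fight_episodes:
            if not (1 <= ep.start_frame and ep.end_frame <= self.n_frames):
                raise MotValidationError(
                    f"episode [{ep.start_frame}, {ep.end_frame}] outside 1..{self.n_frames}"
                )
            if not (0 <= ep.pig_a < self.n_pigs and 0 <= ep.pig_b < self.n_pigs):
                raise MotValidationError("episode references unknown pig")


@dataclass
class GroundTruth:
    """True per-animal tracks, scripted fight events, and the generator's
    own accumulated per-animal path lengths (pixels)."""

    tracks: list[TrackRecord]
    fight_events: list[FightEvent]
    distances: dict[int, float]
    fight_boxes: dict[int, Box] = field(default_factory=dict)
    config: ScenarioConfig | None = None


def _grid(n: int, pen: Box) -> list[Box]:
    cols = math.ceil(math.sqrt(n * pen.width / pen.height))
    cols = max(cols, 1)
    rows = math.ceil(n / cols)
    cw, ch = pen.width / cols, pen.height / rows
    cells = []
    for k in range(n):
        r, c = divmod(k, cols)
        cells.append(
            Box(
                pen.x1 + c * cw,
                pen.y1 + r * ch,
                pen.x1 + (c + 1) * cw,
                pen.y1 + (r + 1) * ch,
            )
        )
    return cells


def simulate_scenario(config: ScenarioConfig) -> tuple[GroundTruth, FrameStream]:
    """Run the scenario; returns ground truth and the degraded detections."""
    rng = np.random.default_rng(config.seed)
    n = config.n_pigs
    pen = config.pen

    widths = np.clip(
        rng.normal(config.width_mean, config.width_sd, n), 10.0, pen.width - 2
    )
    heights = np.clip(
        rng.normal(config.height_mean, config.height_sd, n), 10.0, pen.height - 2
    )

    regions = _grid(n, pen) if config.confine_to_cells else [pen] * n
    for i, reg in enumerate(regions):
        if widths[i] >= reg.width or heights[i] >= reg.height:
            raise MotValidationError(
                "pig size exceeds its movement region: infeasible scenario"
            )

    def clamp(i: int, x: float, y: float) -> tuple[float, float]:
        reg = regions[i]
        hx, hy = widths[i] / 2, heights[i] / 2
        inset = 1.0 if config.confine_to_cells else 0.0
        return (
            float(np.clip(x, reg.x1 + hx + inset, reg.x2 - hx - inset)),
            float(np.clip(y, reg.y1 + hy + inset, reg.y2 - hy - inset)),
        )

    def draw_point(i: int) -> tuple[float, float]:
        reg = regions[i]
        return clamp(
            i,
            rng.uniform(reg.x1, reg.x2),
            rng.uniform(reg.y1, reg.y2),
        )

    pos = [draw_point(i) for i in range(n)]
    waypoints = [draw_point(i) for i in range(n)]
    headings = rng.uniform(0, 2 * math.pi, n)

    episodes_at: dict[int, list[FightEpisode]] = {}
    for ep in config.fight_episodes:
        for f in range(ep.start_frame, ep.end_frame + 1):
            episodes_at.setdefault(f, []).append(ep)

    tracks = [TrackRecord(i + 1, ObjectClass.PIG) for i in range(n)]
    distances = {i + 1: 0.0 for i in range(n)}
    fight_boxes: dict[int, Box] = {}
    detections: list[Detection] = []

    def true_box(i: int) -> Box:
        x, y = pos[i]
        return Box(x - widths[i] / 2, y - heights[i] / 2,
                   x + widths[i] / 2, y + heights[i] / 2)

    def jittered(box: Box) -> Box:
        if config.jitter_sd == 0:
            return box
        j = rng.normal(0.0, config.jitter_sd, 4)
        x1, y1 = box.x1 + j[0], box.y1 + j[1]
        x2, y2 = box.x2 + j[2], box.y2 + j[3]
        if x2 <= x1 + 1:
            x1, x2 = box.x1, box.x1 + max(box.width + j[2] - j[0], 1.0)
        if y2 <= y1 + 1:
            y1, y2 = box.y1, box.y1 + max(box.height + j[3] - j[1], 1.0)
        return Box(x1, y1, x2, y2)

    def score(low_mode: bool) -> float:
        if low_mode:
            s = rng.normal(config.score_low_mean, config.score_low_sd)
            return float(np.clip(s, 0.12, 0.55))
        s = rng.normal(config.score_high_mean, config.score_high_sd)
        return float(np.clip(s, 0.62, 0.999))

    for frame in range(1, config.n_frames + 1):
        fighters: set[int] = set()
        for ep in episodes_at.get(frame, ()):
            fighters.update((ep.pig_a, ep.pig_b))

        # advance motion
        for i in range(n):
            if i in fighters:
                continue  # fight motion handled pairwise below
            wx, wy = waypoints[i]
            dx, dy = wx - pos[i][0], wy - pos[i][1]
            dist_wp = math.hypot(dx, dy)
            if dist_wp < 5.0:
                waypoints[i] = draw_point(i)
                wx, wy = waypoints[i]
                dx, dy = wx - pos[i][0], wy - pos[i][1]
                dist_wp = math.hypot(dx, dy)
            headings[i] = math.atan2(dy, dx) + rng.normal(0.0, config.heading_noise_sd)
            step = max(rng.normal(config.speed_mean, config.speed_sd), 0.0)
            step = min(step, dist_wp)
            pos[i] = clamp(
                i,
                pos[i][0] + step * math.cos(headings[i]),
                pos[i][1] + step * math.sin(headings[i]),
            )

        for ep in episodes_at.get(frame, ()):
            a, b = ep.pig_a, ep.pig_b
            overlap = iou_matrix([true_box(a)], [true_box(b)])[0, 0]
            # lock the pair together deeply enough that each reads as occluded
            if overlap < max(1.2 * config.occlusion_iou, 0.1):
                # converge: both move toward the midpoint
                mx = 0.5 * (pos[a][0] + pos[b][0])
                my = 0.5 * (pos[a][1] + pos[b][1])
                for i in (a, b):
                    dx, dy = mx - pos[i][0], my - pos[i][1]
                    d = math.hypot(dx, dy)
                    step = min(max(config.speed_mean * 2.5, 6.0), d)
                    if d > 0:
                        pos[i] = clamp(i, pos[i][0] + step * dx / d,
                                       pos[i][1] + step * dy / d)
            else:
                # jostle: abrupt small displacements of the locked pair
                for i in (a, b):
                    jx, jy = rng.normal(0.0, 2.0, 2)
                    pos[i] = clamp(i, pos[i][0] + jx, pos[i][1] + jy)

        boxes = [true_box(i) for i in range(n)]
        for i in range(n):
            prev = tracks[i].boxes[-1].center if tracks[i].entries else None
            tracks[i].append(frame, boxes[i], 1.0)
            if prev is not None:
                cx, cy = boxes[i].center
                distances[i + 1] += math.hypot(cx - prev[0], cy - prev[1])

        # degraded per-animal detections
        ious = iou_matrix(boxes, boxes)
        np.fill_diagonal(ious, 0.0)
        for i in range(n):
            occluded = bool(ious[i].max(initial=0.0) > config.occlusion_iou)
            p_miss = config.miss_prob + (config.occlusion_miss_boost if occluded else 0.0)
            if rng.uniform() < p_miss:
                continue
            detections.append(
                Detection(frame, jittered(boxes[i]), score(occluded), ObjectClass.PIG)
            )

        # fighting-class detection: the pair's union box
        for ep in episodes_at.get(frame, ()):
            union = boxes[ep.pig_a].union(boxes[ep.pig_b])
            fight_boxes[frame] = union
            if rng.uniform() < config.miss_prob:
                continue
            detections.append(
                Detection(frame, jittered(union), score(False), ObjectClass.PIG_FIGHTING)
            )

    events = [
        FightEvent(
            ep.start_frame,
            ep.end_frame,
            ep.start_frame / config.fps,
            ep.end_frame / config.fps,
            frozenset({ep.pig_a + 1, ep.pig_b + 1}),
        )
        for ep in config.fight_episodes
    ]
    truth = GroundTruth(tracks, events, distances, fight_boxes, config)
    return truth, FrameStream(detections, fps=config.fps)


@dataclass
class TrackingReport:
    """Tracking quality against ground truth."""

    id_switches: int
    fragmentation: int
    recall: float
    frame_agreement: float
    n_frames_evaluated: int


def evaluate_tracking(
    pred: Sequence[TrackRecord],
    truth: GroundTruth,
    iou_match: float = 0.5,
) -> TrackingReport:
    """Frame-wise IoU matching of predicted to true boxes.

    Counts identity switches (a truth identity's matched predicted id
    changes between its matched frames), fragmentation (a truth track loses
    coverage and regains it), per-box detection recall, and the fraction of
    frames whose matched-animal count equals the truth count.  Frames where
    the tracker emits no boxes at all are skipped, so deleting whole frames
    of detections upstream does not count as fragmentation.
    """
    truth_by_frame: dict[int, list[tuple[int, Box]]] = {}
    for t in truth.tracks:
        for f, b, _ in t.entries:
            truth_by_frame.setdefault(f, []).append((t.track_id, b))
    pred_by_frame: dict[int, list[tuple[int, Box]]] = {}
    for t in pred:
        for f, b, _ in t.entries:
            pred_by_frame.setdefault(f, []).append((t.track_id, b))

    last_pid: dict[int, int] = {}
    covered: dict[int, bool] = {}
    had_gap: dict[int, bool] = {}
    switches = frag = matched_total = truth_total = agree = n_eval = 0

    for f in sorted(truth_by_frame):
        preds = pred_by_frame.get(f, [])
        if not preds:
            continue
        n_eval += 1
        gts = truth_by_frame[f]
        ious = iou_matrix([b for _, b in gts], [b for _, b in preds])
        cost = 1.0 - ious
        rows, cols = linear_sum_assignment(cost)
        match: dict[int, int] = {}
        for r, c in zip(rows, cols):
            if ious[r, c] >= iou_match:
                match[gts[r][0]] = preds[c][0]
        truth_total += len(gts)
        matched_total += len(match)
        agree += int(len(match) == len(gts))
        for tid, _ in gts:
            if tid in match:
                pid = match[tid]
                if tid in last_pid and last_pid[tid] != pid:
                    switches += 1
                if had_gap.get(tid):
                    frag += 1
                    had_gap[tid] = False
                last_pid[tid] = pid
                covered[tid] = True
            elif covered.get(tid):
                had_gap[tid] = True

    recall = matched_total / truth_total if truth_total else 0.0
    agreement = agree / n_eval if n_eval else 0.0
    return TrackingReport(switches, frag, recall, agreement, n_eval)
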