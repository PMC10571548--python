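# pentrack

Detector-agnostic toolkit that turns per-frame animal detections into stable
individual identities, movement statistics, and aggression-event logs — built
around livestock pen monitoring (groups of ~8–20 animals filmed at
1920×1080), but applicable to any MOT-style detection stream with the two
classes `pig` / `pig_fighting`.

What it does:

- **Tracking** (`pentrack.tracker`) — two-stage BYTE-style data association
  over a constant-velocity Kalman filter: high-score detections are matched
  first (Hungarian assignment on `1 − IoU` costs), low-score detections then
  recover occluded targets; unmatched tracks are retained for 30 frames and
  re-matched when they reappear.
- **Behavior** (`pentrack.behavior`) — per-identity centroid polylines with
  cumulative movement distance, duration and mean speed; aggression-event
  intervals `[T1, T2]` from the appearance/disappearance of fighting-class
  boxes, with participant attribution; RFID ear-tag ↔ track-id binding at a
  feeder zone, including tag transfer after target loss.
- **Metrics** (`pentrack.metrics`) — IoU, greedy confidence-ordered matching,
  precision/recall curves, all-point-interpolated AP and mAP@0.5.
- **Architecture accounting** (`pentrack.arch`) — untrained numpy definitions
  of the YOLOv8-style n/s/m detector variants (CSP backbone, PAN neck,
  decoupled anchor-free head) and a grouped multi-scale attention (EMA) block
  inserted at the backbone top, with exact parameter totals and 2×MAC FLOP
  accounting. Parameter headlines are reported on the fused (Conv+BN merged)
  convention that published per-variant tables use; raw totals are exposed
  alongside. **All builds default to `num_classes=2`.**
- **Synthetic scenarios** (`pentrack.synthetic`) — seeded pen simulator
  (waypoint-seeking walks, scripted fights emitting union-box fighting
  detections, corner jitter / score draws / misses with occlusion boost) plus
  tracking-quality scoring (id switches, fragmentation, recall, frame
  agreement). This is the fixture engine for the test suite; no external
  data is needed anywhere.

## CLI

All functionality is reachable through one entry point:

```sh
# simulate a scenario (YAML config optional; see ScenarioConfig fields)
pentrack simulate --config scenario.yaml --seed 42 --out-det det.csv --out-gt gt.csv

# track one class through a MOT det CSV (frame,id,l,t,w,h,conf,class,vis)
pentrack track --det det.csv --out tracks.csv --class pig --high 0.6 --low 0.1 --max-lost 30 --fps 25

# movement + fight report (optionally RFID binding)
pentrack analyze --tracks tracks.csv --fights fights.csv --fps 25 --px-per-m 96 \
    --rfid reads.csv --zone 100,100,400,400 --out report.json

# detection evaluation (per-class AP, mAP@0.5)
pentrack eval-det --pred det.csv --gt gt.csv --iou 0.5

# architecture accounting
pentrack arch --variant n --classes 2 --attention ema --input 640 --json

# full pipeline: track both classes, log fights, report movement
pentrack run --det det.csv --fps 25 --out-tracks t.csv --out-report r.json
```

Exit codes: `2` missing input file, `3` invalid configuration.

Frame indices are 1-based (MOT convention); fps is always an explicit input,
never defaulted. Report JSON is schema-versioned (`"schema": 1`) with times
in both frames and seconds.

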