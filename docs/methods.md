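# Methods

## Data model

A session is exactly two flies — a focal "male" and an "other" fly (the
opponent male in aggression assays, the female in courtship assays) —
tracked in a circular arena. Conventions, chosen once and used everywhere:

- coordinates in millimetres, origin at the arena center, y-axis up;
- frames 0-based and contiguous; a gap is a validation error, not something
  we repair (identity switches and tracking dropouts are assumed corrected
  upstream, e.g. with the tracker's own visualizer tools);
- behavior intervals half-open `[start, end)`, so `n_frames = end - start`
  with no off-by-one;
- body orientation in radians (direction of the head), wing angles in
  degrees in `[0, 180)` — the angle between the body axis and the wing-tip
  line. Converting real tracker exports into this schema is the caller's
  responsibility;
- `T = 0` sessions are rejected everywhere; feature extraction additionally
  needs `T >= 2` (velocities are undefined on a single frame).

CSV is the only interchange format (UTF-8, header row): a long-format
tracks table (`frame,fly,x_mm,y_mm,theta,wing_left_deg,wing_right_deg,
body_len_mm`), a bouts table (`behavior,fly,start,end`), and a 0/1 ethogram
table. Native tracker binary formats are deliberately not parsed; the
package stays dependency-light and every file it touches is diffable.

## Features

Velocities use central differences scaled by fps, one-sided at the two
session endpoints. Central differences are unbiased for smooth motion and
exact for straight-line constant-velocity segments; no differentiation
scheme is canonical in this literature, so the unbiased choice wins.
Optional moving-average position smoothing (odd window, default off) exists
for jittery real tracks; the simulator produces clean tracks, so the
default is no smoothing.

Dyadic features come from exact vector geometry: inter-centroid distance;
facing angle (male heading vs. male-to-partner vector, `[0, 180]`°); the
"behind" angle (partner heading vs. partner-to-male vector, 180° = male
directly behind); the male's angular position in a partner-centered frame,
unwrapped over time so its derivative has no ±π artifacts; and a sideways
fraction `|v_perp| / (|v_perp| + |v_par| + eps)` of the male's velocity
relative to his body axis, with `eps = 1e-9` so a stationary fly reads 0
rather than NaN. All scalar features are invariant under rigid rotation of
the scene, which the test suite verifies directly.

One feature deserves its own paragraph. The classical lunge definition is a
snap onto the opponent at ~200 mm/s. At 30 fps inside a 13 mm arena the
central-difference speed can never reach that value: it is bounded by
(arena diameter) × fps / 2 ≈ 195 mm/s, because the symmetric estimate
averages the frame before and after a one-frame strike. The feature table
therefore carries a `step_speed_mm_s` column — the backward per-frame
displacement times fps, i.e. the arrival speed into each frame — and the
lunge detector thresholds that. A one-frame 6.7 mm strike registers its
full 200 mm/s there while the central estimate halves it.

## Detectors

Every detector is "predicate, then persistence": threshold the features
into per-frame candidate frames, take maximal runs, keep runs meeting the
behavior's minimum duration. Consequences the tests rely on: emitted frames
are always a subset of the predicate (checked by brute-force re-evaluation),
and raising any persistence threshold can only remove bouts.

Thresholds live in `ClassifierParams`, serializable to YAML and overridable
per-flag on the CLI. Defaults follow the published rule definitions:

- **wing extension**: wing angle strictly `> 30°` ("exceeds" is read
  literally: exactly 30° never fires). Persistence is stored in *seconds*
  (0.5 s) and converted with `round(s × fps)` — the classical definition
  says 13 frames at 25 fps; at the 30 fps these assays record, that is 15
  frames. (At exactly 25 fps the banker's rounding of 12.5 gives 12, one
  frame laxer than the literal 13; set `wing_persist_s = 13/25` to match
  the historical count exactly.)
- **following** and **circling** keep their definitions' literal frame
  counts (25 and 13) rather than seconds, because those sources state frame
  counts without a reference duration.
- **lunge**: step speed ≥ 200 mm/s toward an opponent within 5 mm faced
  within 45°. The 45° body-pitch cue in the classical definition is
  unobservable in 2-D centroid data and is dropped; proximity + facing +
  speed spike substitute. Qualifying frames chained closer than the 3-frame
  refractory collapse to the peak-speed frame (earliest frame on exact
  ties), and every emitted bout is exactly one frame.
- **mounting**: inter-centroid distance below 0.5 × the pair's mean body
  length with both flies ≤ 2 mm/s — occlusion/near-coincidence is how an
  overhead tracker sees a mounted pair. Maximal mounted runs ≥ 1350 frames
  (45 s at 30 fps) are copulation; runs of 10–1349 frames are attempted
  copulation; shorter runs are noise and discarded. A run of exactly 45 s
  is copulation (the "≥ 45 s" duration rule wins over frame-count phrasings
  that are self-contradictory at the boundary). The "abdominal curling
  without mounting" component of attempted copulation has no centroid-level
  signature and is not detected.
- **duration floor**: an optional post-filter drops predicted bouts shorter
  than the (1 − coverage) quantile (lower interpolation) of manually
  annotated reference durations, with coverage defaulting to 0.98 — i.e.
  the floor is set so 98% of reference bouts meet it. The underlying prose
  ("exclude bouts shorter than 98% of those observed") is ambiguous between
  this reading and a per-bout 0.98 scale factor; the quantile reading is
  implemented and configurable. Lunges are exempt (single-frame by
  definition).

`classify_all` composes all six detectors and applies one interaction rule:
copulation frames suppress simultaneous wing-extension/following/circling
labels, so a merged pair is never double-counted as active courtship.

## Evaluation

Bout-level matching uses ≥ 1 shared frame on half-open intervals (touching
bouts do not overlap). The scheme is the field's asymmetric one: TP is the
number of *truth* bouts overlapped, FP the number of *predicted* bouts
overlapping nothing, so `tp + fn == n_truth` always, while `tp + fp` mixes
units. That literal scheme is the default; a symmetric mode (TP counted
over predictions) is available behind a flag for users who want matched
denominators. An optional `boundary_tolerance` dilates intervals before
testing overlap, forgiving small boundary disagreements.

Zero-denominator metrics (empty predictions, empty sessions) are defined as
0 rather than NaN. Percentages render with one decimal. The behavioral
index divides by the full recording length `T`, not a post-acclimation
subset. Frame/second conversion rounds to nearest with ties to even.
Regression (used e.g. for classifier-vs-manual count comparisons) is
ordinary least squares with intercept via `scipy.stats.linregress`;
constant predictors are rejected.

## The simulator

The generator's job is to be the ground-truth oracle for every other
module, so its guarantees are structural, not statistical:

- **Baseline**: each fly performs a persistent random walk (AR heading
  noise, speed drawn from 0.4–1.0 mm/s) tethered to an anchor pocket;
  the two pockets are placed so inter-fly distance always exceeds the
  5 mm following/circling reach, speeds stay below the 2 mm/s walking
  threshold, and wing angles stay under 14°. Baseline frames therefore
  violate every detector predicate by construction, and an empty schedule
  yields an empty ethogram at any seed.
- **Injection**: scheduled bouts override kinematics with explicit margins
  rather than simulating physics — wing extension draws 45–70°, lunges
  strike at 230–272 mm/s through a chord near the arena center, following
  runs along a 2.5 mm-radius arc at 5 mm/s with a 2.8–4.2 mm gap
  (rear-angle 132–148°), circling orbits at 3 mm and 1.8–2.2 rad/s with
  the body axis pointing at the partner, mounting holds a 0.6 mm gap with
  a 0.5 mm/s drift. Ten-frame linear ramps connect baseline and bout
  segments (per-frame steps ≈ 1 mm, far below the lunge threshold), and
  the kinematic pattern extends two pad frames beyond each scheduled
  interval so derivative edge effects fall outside the truth bout.
- **Validation**: scheduled durations must exceed their persistence
  thresholds by ≥ 20%, windows (including ramps) must fit inside the
  session and not touch each other, and unknown behaviors are rejected.
- **Determinism**: one `numpy` generator seeded from the config drives
  every draw; identical configs give bit-identical sessions.

Arena presets: aggression 13 mm × 20 min, courtship 11 mm × 15 min, and a
desk preset (11 mm × 60 s, 1800 frames) sized so the full test suite and
the acceptance script run in seconds. Body lengths are fixed at 2.5 mm
(male) and 3.0 mm (partner). Positional noise is available
(`noise_sd_mm`) but defaults to 0: the recovery guarantees are stated for
clean sessions.

The corrupter (`corrupt_bouts`) degrades a truth table while keeping exact
books: deletions become FN, insertions in behavior-free regions become FP
(kept clear of other predictions so normalization cannot merge them away),
splits leave one TP under the many-to-one rule, and boundary jitter is
clamped to preserve ≥ 1 frame of overlap with its own truth bout and to
never reach a neighboring one. `match_bouts` must reproduce those counts
exactly — the central oracle test for the evaluation module.

## What passing tests do and do not show

The simulator demonstrates *rule consistency*: the detectors recover
precisely the intervals whose kinematics satisfy their printed definitions,
with no false positives from the baseline motion model. It does not emulate
tracker noise, identity switches, occlusion artifacts, wall-climbing, or
the ambiguity of real behavioral boundaries — so perfect recovery on
simulated sessions is a statement about the implementation, not a
performance claim for real videos. On real data the detectors are rigid
rules, with the known failure modes of rule-based scoring (the motivation
for learned classifiers); the evaluation half of the package is exactly the
instrument for quantifying that gap against manual annotation.

## Problem sizes

The test suite and acceptance script use the 60 s desk preset (1800
frames) for per-behavior recovery (20 seeds × 6 behaviors in the suite,
5 × 6 in the acceptance script), one full 36,000-frame aggression session,
1000 random interval sets for the matching oracle, and 100 seeded
corruptions. Full suite ≈ 10 s, acceptance script ≈ 4 s on one CPU.
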