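"""Rule-based detectors for the six male behaviors.

Each detector thresholds the feature table into per-frame candidate
predicates, then applies the behavior's persistence filter. The rules
implement the classical published definitions:

* lunge — a snap onto a nearby, faced opponent at ~200 mm/s (single-frame
  event with refractory collapse);
* wing extension — wing angle strictly above 30 deg, persisting 0.5 s;
* following — male 2-5 mm behind the partner while both walk at
  >= 2 mm/s, persisting >= 25 frames;
* circling — sideways drift around the partner at >= 1 rad/s within
  5 mm, persisting >= 13 frames;
* attempted copulation / copulation — sustained mounting (near-zero
  inter-centroid distance at low speed) split by duration at 45 s.

The lunge rule uses the backward per-frame step speed rather than the
central-difference speed: a lunge is a one-frame displacement spike, and
the symmetric central estimate both halves the spike and is bounded by
(arena diameter) * fps / 2, which sits below 200 mm/s in a 13 mm arena
at 30 fps. The 45 deg body-pitch component of the classical definition is
unobservable in 2-D centroid data and is replaced by the proximity and
facing conditions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .features import FeatureParams, FeatureTable, compute_features
from .trackdata import (
    BEHAVIORS,
    ArenaConfig,
    Bout,
    BoutTable,
    Ethogram,
    TrajectorySet,
    ValidationError,
    _runs,
    bouts_from_ethogram,
    ethogram_from_bouts,
    normalize_bouts,
)

AGGRESSION_CATEGORIES = ("low", "moderate", "high", "hyper")


@dataclass(frozen=True)
class ClassifierParams:
    """All detector thresholds, config-file serializable.

    Persistence is stored in seconds where the source definition is a
    duration (wing extension: 0.5 s, i.e. 13 frames at 25 fps, 15 at
    30 fps) and in frames where the definition is a literal frame count
    (following 25, circling 13).
    """

    wing_angle_deg: float = 30.0
    wing_persist_s: float = 0.5
    lunge_speed_mm_s: float = 200.0
    lunge_max_dist_mm: float = 5.0
    lunge_facing_deg: float = 45.0
    lunge_refractory_frames: int = 3
    follow_min_mm: float = 2.0
    follow_max_mm: float = 5.0
    follow_speed_mm_s: float = 2.0
    follow_persist_frames: int = 25
    follow_behind_deg: float = 120.0
    circle_max_dist_mm: float = 5.0
    circle_min_ang_vel_rad_s: float = 1.0
    circle_min_sideways: float = 0.5
    circle_persist_frames: int = 13
    mount_dist_frac_bodylen: float = 0.5
    mount_max_speed_mm_s: float = 2.0
    attempt_min_frames: int = 10
    copul_min_frames: int = 1350
    duration_floor_coverage: float = 0.98

    def __post_init__(self) -> None:
        numeric = {k: v for k, v in asdict(self).items()}
        for k, v in numeric.items():
            if v <= 0:
                raise ValidationError(f"{k} must be > 0, got {v}")
        if self.attempt_min_frames >= self.copul_min_frames:
            raise ValidationError("attempt_min_frames must be < copul_min_frames")
        if self.duration_floor_coverage > 1:
            raise ValidationError("duration_floor_coverage must be in (0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassifierParams":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def persistence_frames(self, behavior: str, fps: float) -> int:
        """Minimum run length (frames) for a behavior at a given fps."""
        if behavior == "wing_extension":
            return int(round(self.wing_persist_s * fps))
        if behavior == "following":
            return self.follow_persist_frames
        if behavior == "circling":
            return self.circle_persist_frames
        if behavior == "attempted_copulation":
            return self.attempt_min_frames
        if behavior == "copulation":
            return self.copul_min_frames
        return 1  # lunge: single-frame events


def _bouts_from_runs(
    runs: list[tuple[int, int]], behavior: str, fps: float, T: int
) -> BoutTable:
    return BoutTable(
        [Bout(behavior, "male", s, e) for s, e in runs], fps=fps, T=T
    )


def detect_wing_extension(
    feat: FeatureTable, p: ClassifierParams, fps: float | None = None
) -> BoutTable:
    """Wing angle strictly exceeding the threshold, with persistence.

    The comparison is strict (> 30 deg), so a wing held at exactly the
    threshold never fires.
    """
    fps = fps or feat.fps
    persist = p.persistence_frames("wing_extension", fps)
    mask = feat.wing_max_deg > p.wing_angle_deg
    runs = [(s, e) for s, e in _runs(mask) if e - s >= persist]
    return _bouts_from_runs(runs, "wing_extension", fps, feat.n_frames)


def detect_lunge(feat: FeatureTable, p: ClassifierParams) -> BoutTable:
    """Single-frame lunge events with refractory collapse.

    Qualifying frames (step speed >= threshold, opponent within reach and
    faced) closer together than the refractory window collapse to the
    peak-speed frame; the earliest frame wins exact ties.
    """
    mask = (
        (feat.step_speed_mm_s >= p.lunge_speed_mm_s)
        & (feat.dist_mm <= p.lunge_max_dist_mm)
        & (feat.facing_deg <= p.lunge_facing_deg)
    )
    frames = np.flatnonzero(mask)
    events: list[int] = []
    group: list[int] = []
    for f in frames:
        if group and f - group[-1] > p.lunge_refractory_frames:
            events.append(_peak_frame(group, feat.step_speed_mm_s))
            group = []
        group.append(int(f))
    if group:
        events.append(_peak_frame(group, feat.step_speed_mm_s))
    return _bouts_from_runs(
        [(f, f + 1) for f in events], "lunge", feat.fps, feat.n_frames
    )


def _peak_frame(group: list[int], speed: np.ndarray) -> int:
    speeds = speed[group]
    return group[int(np.argmax(speeds))]  # argmax returns the first maximum


def detect_following(feat: FeatureTable, p: ClassifierParams) -> BoutTable:
    """Male in the 2-5 mm band behind the partner while both walk."""
    mask = (
        (feat.dist_mm >= p.follow_min_mm)
        & (feat.dist_mm <= p.follow_max_mm)
        & (feat.behind_deg >= p.follow_behind_deg)
        & (feat.speed_mm_s >= p.follow_speed_mm_s)
        & (feat.speed_other_mm_s >= p.follow_speed_mm_s)
    )
    runs = [(s, e) for s, e in _runs(mask) if e - s >= p.follow_persist_frames]
    return _bouts_from_runs(runs, "following", feat.fps, feat.n_frames)


def detect_circling(feat: FeatureTable, p: ClassifierParams) -> BoutTable:
    """Sideways orbit around the partner at sustained angular velocity."""
    mask = (
        (feat.dist_mm <= p.circle_max_dist_mm)
        & (np.abs(feat.ang_vel_rad_s) >= p.circle_min_ang_vel_rad_s)
        & (feat.sideways_frac >= p.circle_min_sideways)
    )
    runs = [(s, e) for s, e in _runs(mask) if e - s >= p.circle_persist_frames]
    return _bouts_from_runs(runs, "circling", feat.fps, feat.n_frames)


def detect_mounting(
    feat: FeatureTable, p: ClassifierParams, fps: float | None = None
) -> BoutTable:
    """Sustained mounting, split into attempted copulation vs copulation.

    Mounting is proxied by an inter-centroid distance below a fraction of
    the pair's mean body length while both flies are nearly stationary
    (this is how an overhead tracker sees a mounted pair). Maximal runs of
    at least ``copul_min_frames`` are copulation; runs in
    ``[attempt_min_frames, copul_min_frames)`` are attempted copulation;
    shorter runs are discarded.
    """
    fps = fps or feat.fps
    thresh = p.mount_dist_frac_bodylen * feat.pair_body_len_mm
    mask = (
        (feat.dist_mm <= thresh)
        & (feat.speed_mm_s <= p.mount_max_speed_mm_s)
        & (feat.speed_other_mm_s <= p.mount_max_speed_mm_s)
    )
    bouts: list[Bout] = []
    for s, e in _runs(mask):
        n = e - s
        if n >= p.copul_min_frames:
            bouts.append(Bout("copulation", "male", s, e))
        elif n >= p.attempt_min_frames:
            bouts.append(Bout("attempted_copulation", "male", s, e))
    return BoutTable(bouts, fps=fps, T=feat.n_frames)


def apply_duration_floor(
    bouts: BoutTable,
    reference_durations: list[int],
    coverage: float = 0.98,
) -> BoutTable:
    """Drop predicted bouts shorter than the duration floor.

    The floor is the (1 - coverage) empirical quantile (lower
    interpolation) of manually annotated bout durations, so a fraction
    ``coverage`` of the reference bouts meet the floor. Lunges are exempt
    (single-frame by definition).
    """
    if not len(reference_durations):
        raise ValidationError("reference_durations must be non-empty")
    if not (0 < coverage <= 1):
        raise ValidationError("coverage must be in (0, 1]")
    floor = int(np.quantile(np.asarray(reference_durations), 1 - coverage, method="lower"))
    kept = [
        b for b in bouts if b.behavior == "lunge" or b.n_frames >= floor
    ]
    return BoutTable(kept, fps=bouts.fps, T=bouts.T)


def classify_all(
    traj: TrajectorySet,
    arena: ArenaConfig,
    p: ClassifierParams | None = None,
    feature_params: FeatureParams | None = None,
) -> tuple[Ethogram, BoutTable]:
    """Run feature extraction and all six detectors on a session.

    Copulation dominates: frames labeled copulation are cleared of
    simultaneous wing-extension/following/circling labels, so a merged
    pair is never double-counted as active courtship.
    """
    p = p or ClassifierParams()
    feat = compute_features(traj, arena, feature_params)
    fps = arena.fps
    all_bouts: list[Bout] = []
    for table in (
        detect_lunge(feat, p),
        detect_wing_extension(feat, p, fps),
        detect_following(feat, p),
        detect_circling(feat, p),
        detect_mounting(feat, p, fps),
    ):
        all_bouts.extend(table.bouts)
    raw = BoutTable(all_bouts, fps=fps, T=traj.n_frames)
    eth = ethogram_from_bouts(raw, T=traj.n_frames)
    cop = eth.column("copulation")
    if cop.any():
        for behavior in ("wing_extension", "following", "circling"):
            eth.mask[:, eth.behaviors.index(behavior)] &= ~cop
    bouts = bouts_from_ethogram(eth)
    return eth, bouts


def aggression_category(lunge_count: int) -> str:
    """Map a session lunge count to its aggression-intensity category.

    0-70 low, 71-160 moderate, 161-300 high, >300 hyper.
    """
    if lunge_count < 0:
        raise ValidationError("lunge_count must be >= 0")
    if lunge_count <= 70:
        return "low"
    if lunge_count <= 160:
        return "moderate"
    if lunge_count <= 300:
        return "high"
    return "hyper"
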