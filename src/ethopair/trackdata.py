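"""Domain types and I/O for two-fly trajectory sessions.

A session is a pair of flies ("male" focal, "other" partner or opponent)
tracked in a circular arena. Frames are 0-based and contiguous; behavior
intervals are half-open ``[start, end)`` so that ``n_frames = end - start``.
Coordinates are millimetres with the origin at the arena center.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical behavior set, in ethogram column order.
BEHAVIORS: tuple[str, ...] = (
    "lunge",
    "wing_extension",
    "following",
    "circling",
    "attempted_copulation",
    "copulation",
)

#: Fly roles. The first role is the focal (male) fly.
ROLES: tuple[str, str] = ("male", "other")

TRACK_COLUMNS: tuple[str, ...] = (
    "frame",
    "fly",
    "x_mm",
    "y_mm",
    "theta",
    "wing_left_deg",
    "wing_right_deg",
    "body_len_mm",
)

BOUT_COLUMNS: tuple[str, ...] = ("behavior", "fly", "start", "end")


class FormatError(ValueError):
    """A file does not conform to the documented CSV schema."""


class ValidationError(ValueError):
    """Data violates a structural invariant (gaps, ranges, bounds)."""


@dataclass(frozen=True)
class ArenaConfig:
    """Recording geometry and timing.

    Parameters
    ----------
    fps
        Recording frame rate in Hz (30 for the standard assays).
    arena_diameter_mm
        Diameter of the circular arena floor (13 mm aggression,
        11 mm courtship).
    duration_frames
        Nominal session length in frames.
    arena_center_mm
        Arena center in track coordinates; (0, 0) by convention.
    """

    fps: float = 30.0
    arena_diameter_mm: float = 13.0
    duration_frames: int = 36_000
    arena_center_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError("fps must be > 0")
        if self.arena_diameter_mm <= 0:
            raise ValidationError("arena_diameter_mm must be > 0")
        if self.duration_frames < 1:
            raise ValidationError("duration_frames must be >= 1")

    @property
    def radius_mm(self) -> float:
        return self.arena_diameter_mm / 2.0


@dataclass
class TrajectorySet:
    """Per-frame pose of both flies.

    Each array has shape ``(T, 2)``; column 0 is the focal "male" fly and
    column 1 the "other" fly, matching :data:`ROLES`.
    """

    x_mm: np.ndarray
    y_mm: np.ndarray
    theta: np.ndarray
    wing_left_deg: np.ndarray
    wing_right_deg: np.ndarray
    body_len_mm: np.ndarray

    _ARRAYS = ("x_mm", "y_mm", "theta", "wing_left_deg", "wing_right_deg", "body_len_mm")

    def __post_init__(self) -> None:
        for name in self._ARRAYS:
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        self.validate()

    @property
    def n_frames(self) -> int:
        return int(self.x_mm.shape[0])

    def validate(self, arena: ArenaConfig | None = None) -> None:
        shapes = {getattr(self, n).shape for n in self._ARRAYS}
        if len(shapes) != 1:
            raise ValidationError(f"inconsistent array shapes: {shapes}")
        (shape,) = shapes
        if len(shape) != 2 or shape[1] != 2:
            raise ValidationError(f"arrays must have shape (T, 2), got {shape}")
        if shape[0] < 1:
            raise ValidationError("a session needs at least one frame (T >= 1)")
        for name in self._ARRAYS:
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"non-finite values in {name}")
        for name in ("wing_left_deg", "wing_right_deg"):
            w = getattr(self, name)
            if np.any(w < 0) or np.any(w >= 180):
                raise ValidationError(f"{name} must lie in [0, 180) degrees")
        if np.any(self.body_len_mm <= 0):
            raise ValidationError("body_len_mm must be > 0")
        if arena is not None:
            cx, cy = arena.arena_center_mm
            r = np.hypot(self.x_mm - cx, self.y_mm - cy)
            if np.any(r > arena.radius_mm + 1e-6):
                bad = int(np.argwhere(r > arena.radius_mm + 1e-6)[0][0])
                raise ValidationError(f"position outside arena disc at frame {bad}")

    def to_dataframe(self) -> pd.DataFrame:
        T = self.n_frames
        frames = np.repeat(np.arange(T), 2)
        flies = np.tile(np.array(ROLES), T)
        data = {"frame": frames, "fly": flies}
        for name in self._ARRAYS:
            data[name] = getattr(self, name).reshape(-1)
        return pd.DataFrame(data, columns=list(TRACK_COLUMNS))

    def allclose(self, other: "TrajectorySet", rtol: float = 1e-9) -> bool:
        return all(
            np.allclose(getattr(self, n), getattr(other, n), rtol=rtol, atol=1e-12)
            for n in self._ARRAYS
        )


@dataclass(frozen=True)
class Bout:
    """One labeled behavior interval, half-open ``[start, end)``."""

    behavior: str
    fly: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValidationError(f"unknown behavior {self.behavior!r}")
        if self.fly not in ROLES:
            raise ValidationError(f"unknown fly role {self.fly!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"bout must satisfy 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def n_frames(self) -> int:
        return self.end - self.start

    def duration_s(self, fps: float) -> float:
        return self.n_frames / fps

    def overlaps(self, other: "Bout") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class BoutTable:
    """Ordered collection of bouts plus session metadata."""

    bouts: list[Bout]
    fps: float
    T: int

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValidationError("T must be >= 1")
        if self.fps <= 0:
            raise ValidationError("fps must be > 0")
        self.bouts = list(self.bouts)
        for b in self.bouts:
            if b.end > self.T:
                raise ValidationError(
                    f"bout [{b.start}, {b.end}) exceeds session length T={self.T}"
                )

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)

    def select(self, behavior: str, fly: str | None = None) -> list[Bout]:
        return [
            b
            for b in self.bouts
            if b.behavior == behavior and (fly is None or b.fly == fly)
        ]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(b.behavior, b.fly, b.start, b.end) for b in self.bouts],
            columns=list(BOUT_COLUMNS),
        )


@dataclass
class Ethogram:
    """Per-frame boolean behavior matrix for the focal (male) fly."""

    mask: np.ndarray  # (T, B) bool
    behaviors: tuple[str, ...] = BEHAVIORS
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or self.mask.shape[1] != len(self.behaviors):
            raise ValidationError(
                f"mask must be (T, {len(self.behaviors)}), got {self.mask.shape}"
            )
        if self.mask.shape[0] < 1:
            raise ValidationError("ethogram needs T >= 1")

    @property
    def n_frames(self) -> int:
        return int(self.mask.shape[0])

    def column(self, behavior: str) -> np.ndarray:
        return self.mask[:, self.behaviors.index(behavior)]


# ---------------------------------------------------------------------------
# bout <-> ethogram conversions


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean vector, as half-open intervals."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def bouts_from_ethogram(eth: Ethogram, fly: str = "male") -> BoutTable:
    """Run-length encode an ethogram into a normalized bout table."""
    bouts = [
        Bout(behavior, fly, s, e)
        for behavior in eth.behaviors
        for s, e in _runs(eth.column(behavior))
    ]
    return normalize_bouts(BoutTable(bouts, fps=eth.fps, T=eth.n_frames))


def ethogram_from_bouts(
    bouts: BoutTable,
    T: int | None = None,
    behaviors: Sequence[str] = BEHAVIORS,
) -> Ethogram:
    """Paint bouts into a per-frame boolean matrix (union semantics)."""
    T = bouts.T if T is None else T
    mask = np.zeros((T, len(behaviors)), dtype=bool)
    for b in bouts:
        if b.end > T:
            raise ValidationError(f"bout [{b.start}, {b.end}) exceeds T={T}")
        if b.behavior in behaviors:
            mask[b.start : b.end, list(behaviors).index(b.behavior)] = True
    return Ethogram(mask, behaviors=tuple(behaviors), fps=bouts.fps)


def normalize_bouts(table: BoutTable) -> BoutTable:
    """Sort and merge overlapping or frame-adjacent same-behavior bouts.

    Merging is per (behavior, fly); ``[5, 10)`` and ``[10, 14)`` become
    ``[5, 14)``. The operation is idempotent and preserves the per-frame
    indicator set.
    """
    groups: dict[tuple[str, str], list[Bout]] = {}
    for b in table:
        groups.setdefault((b.behavior, b.fly), []).append(b)
    merged: list[Bout] = []
    for (behavior, fly), group in groups.items():
        group.sort(key=lambda b: (b.start, b.end))
        cur_s, cur_e = group[0].start, group[0].end
        for b in group[1:]:
            if b.start <= cur_e:  # overlap or adjacency
                cur_e = max(cur_e, b.end)
            else:
                merged.append(Bout(behavior, fly, cur_s, cur_e))
                cur_s, cur_e = b.start, b.end
        merged.append(Bout(behavior, fly, cur_s, cur_e))
    order = {b: i for i, b in enumerate(BEHAVIORS)}
    merged.sort(key=lambda b: (order[b.behavior], b.fly, b.start))
    return BoutTable(merged, fps=table.fps, T=table.T)


# ---------------------------------------------------------------------------
# CSV readers / writers

_FLOAT_FMT = "%.12g"


def read_tracks(path: str | Path, arena: ArenaConfig | None = None) -> TrajectorySet:
    """Read a tracks CSV (one row per frame per fly) into a TrajectorySet.

    Frames are re-indexed to a 0-based contiguous range. Raises
    :class:`FormatError` for schema problems and :class:`ValidationError`
    for frame gaps, missing flies, or out-of-range values.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    flies = sorted(df["fly"].astype(str).unique())
    if len(flies) > 2:
        raise FormatError(f"unsupported: more than two flies ({flies})")
    if set(flies) != set(ROLES):
        raise FormatError(f"fly roles must be {set(ROLES)}, got {set(flies)}")

    frames = np.sort(df["frame"].unique())
    gaps = np.flatnonzero(np.diff(frames) != 1)
    if gaps.size:
        first_missing = int(frames[gaps[0]]) + 1
        raise ValidationError(f"gap at frame {first_missing}")
    T = len(frames)

    arrays = {}
    per_fly = {}
    for fly in ROLES:
        sub = df[df["fly"] == fly].sort_values("frame")
        if len(sub) != T or not np.array_equal(sub["frame"].to_numpy(), frames):
            fly_frames = set(sub["frame"].tolist())
            missing_frames = [int(f) for f in frames if f not in fly_frames]
            if missing_frames:
                raise ValidationError(f"gap at frame {missing_frames[0]} (fly {fly!r})")
            raise ValidationError(f"duplicate frames for fly {fly!r}")
        per_fly[fly] = sub
    for name in TrajectorySet._ARRAYS:
        arrays[name] = np.column_stack(
            [per_fly[fly][name].to_numpy(dtype=float) for fly in ROLES]
        )
    traj = TrajectorySet(**arrays)
    if arena is not None:
        traj.validate(arena)
    return traj


def write_tracks(traj: TrajectorySet, path: str | Path) -> None:
    """Write a TrajectorySet to CSV; round-trips through read_tracks."""
    traj.validate()
    traj.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_bouts(path: str | Path, fps: float, T: int) -> BoutTable:
    df = pd.read_csv(path)
    missing = [c for c in BOUT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    bouts = [
        Bout(str(r.behavior), str(r.fly), int(r.start), int(r.end))
        for r in df.itertuples()
    ]
    return BoutTable(bouts, fps=fps, T=T)


def write_bouts(table: BoutTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def read_ethogram(path: str | Path, fps: float) -> Ethogram:
    df = pd.read_csv(path)
    if "frame" not in df.columns:
        raise FormatError("missing column(s): frame")
    behaviors = tuple(c for c in df.columns if c != "frame")
    mask = df[list(behaviors)].to_numpy(dtype=bool)
    return Ethogram(mask, behaviors=behaviors, fps=fps)


def write_ethogram(eth: Ethogram, path: str | Path) -> None:
    df = pd.DataFrame(
        eth.mask.astype(int), columns=list(eth.behaviors)
    )
    df.insert(0, "frame", np.arange(eth.n_frames))
    df.to_csv(path, index=False)
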