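"""Synthetic two-fly session generator and annotation corrupter.

The generator produces trajectory sessions in which every scheduled
behavior bout satisfies the corresponding detection rule with explicit
kinematic margins, while baseline frames violate every rule by
construction: outside scheduled bouts the two flies wander in separate
pockets (inter-fly distance above the following/circling reach) at speeds
below the walking threshold, with wing angles well under the song
threshold. Detector recall on clean sessions is therefore a deterministic
expectation, not a statistical one.

Behaviors are injected by overriding kinematics, not by physics
simulation; short linear ramps connect baseline and bout segments so no
transition frame can masquerade as a lunge-speed spike, and every
scheduled window is validated to exceed its persistence threshold by at
least 20%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .classify import ClassifierParams
from .evaluate import MatchCounts
from .trackdata import (
    BEHAVIORS,
    ArenaConfig,
    Bout,
    BoutTable,
    TrajectorySet,
    ValidationError,
    normalize_bouts,
)

#: Body lengths (mm) used for simulated flies: male ~2.5, partner ~3.0.
BODY_LEN_MM = (2.5, 3.0)

PRESET_ARENAS = {
    "aggression": ArenaConfig(fps=30.0, arena_diameter_mm=13.0, duration_frames=36_000),
    "courtship": ArenaConfig(fps=30.0, arena_diameter_mm=11.0, duration_frames=27_000),
    "desk": ArenaConfig(fps=30.0, arena_diameter_mm=11.0, duration_frames=1_800),
}


@dataclass(frozen=True)
class BaselineParams:
    """Baseline locomotion: a persistent random walk inside a pocket.

    Speeds stay below the 2 mm/s walking threshold and each fly is tied
    to an anchor so the pair never closes within following/circling
    reach outside scheduled bouts.
    """

    mean_speed_mm_s: float = 1.0
    heading_noise: float = 0.5
    pocket_radius_mm: float = 1.2
    wing_max_jitter_deg: float = 14.0


@dataclass
class SimConfig:
    """Full session recipe: arena preset, schedule, kinematic margins."""

    arena: ArenaConfig
    schedule: list[tuple[str, float, float]] = field(default_factory=list)
    baseline: BaselineParams = field(default_factory=BaselineParams)
    wing_angle_range: tuple[float, float] = (45.0, 70.0)
    lunge_speed_range: tuple[float, float] = (230.0, 272.0)
    follow_gap_range: tuple[float, float] = (2.8, 4.2)
    follow_speed_mm_s: float = 5.0
    follow_path_radius_mm: float = 2.5
    circle_radius_mm: float = 3.0
    circle_ang_vel_range: tuple[float, float] = (1.8, 2.2)
    mount_gap_mm: float = 0.6
    noise_sd_mm: float = 0.0
    ramp_frames: int = 10
    pad_frames: int = 2
    seed: int = 0


@dataclass(frozen=True)
class Corruption:
    """Controlled degradation of a truth bout table with exact bookkeeping."""

    p_delete: float = 0.0
    n_insert: int = 0
    p_split: float = 0.0
    boundary_jitter_frames: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_delete", "p_split"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.n_insert < 0 or self.boundary_jitter_frames < 0:
            raise ValidationError("n_insert and boundary_jitter_frames must be >= 0")


def preset(name: str, seed: int = 0, schedule: list | None = None) -> SimConfig:
    """Build a SimConfig for a named arena preset.

    ``aggression``: 13 mm arena, 20 min; ``courtship``: 11 mm, 15 min;
    ``desk``: 11 mm, 60 s (small sessions for fast end-to-end runs).
    """
    if name not in PRESET_ARENAS:
        raise ValidationError(
            f"unknown preset {name!r}; choose from {sorted(PRESET_ARENAS)}"
        )
    cfg = SimConfig(arena=PRESET_ARENAS[name], seed=seed)
    cfg.schedule = demo_schedule(name) if schedule is None else list(schedule)
    return cfg


def demo_schedule(name: str) -> list[tuple[str, float, float]]:
    """A standard demonstration schedule for each preset."""
    if name == "aggression":
        # 85 lunges, ~14 s apart -> "moderate" aggression category
        return [("lunge", 10.0 + 14.0 * i, 0.0) for i in range(85)]
    if name == "courtship":
        block = [
            ("wing_extension", 0.0, 1.5),
            ("following", 4.0, 1.5),
            ("circling", 8.0, 1.0),
            ("attempted_copulation", 11.5, 2.0),
        ]
        out = []
        t = 5.0
        while t + 16.0 < 880.0:
            out.extend((b, t + off, d) for b, off, d in block)
            t += 18.0
        return out
    if name == "desk":
        return [
            ("wing_extension", 3.0, 1.0),
            ("following", 7.0, 1.2),
            ("circling", 11.0, 0.8),
            ("attempted_copulation", 14.5, 2.0),
            ("lunge", 20.0, 0.0),
            ("lunge", 25.0, 0.0),
        ]
    raise ValidationError(f"unknown preset {name!r}")


def spaced_schedule(
    behavior: str,
    n_bouts: int,
    duration_s: float,
    session_s: float,
    start_s: float = 2.0,
) -> list[tuple[str, float, float]]:
    """Evenly spaced bouts of one behavior across a session."""
    spacing = (session_s - start_s - 2.0) / n_bouts
    if spacing < duration_s + 1.5:
        raise ValidationError("schedule exceeds session length")
    return [(behavior, start_s + i * spacing, duration_s) for i in range(n_bouts)]


# ---------------------------------------------------------------------------
# schedule validation


def _validate_schedule(cfg: SimConfig) -> list[tuple[str, int, int]]:
    fps = cfg.arena.fps
    T = cfg.arena.duration_frames
    p = ClassifierParams()
    margin = cfg.ramp_frames + cfg.pad_frames
    items: list[tuple[str, int, int]] = []
    for behavior, start_s, duration_s in cfg.schedule:
        if behavior not in BEHAVIORS:
            raise ValidationError(f"unknown behavior {behavior!r} in schedule")
        s = int(round(start_s * fps))
        n = 1 if behavior == "lunge" else int(round(duration_s * fps))
        if behavior != "lunge":
            need = math.ceil(1.2 * p.persistence_frames(behavior, fps))
            if n < need:
                raise ValidationError(
                    f"{behavior} bout of {n} frames is below the 20% persistence "
                    f"margin ({need} frames at {fps} fps)"
                )
            if behavior == "attempted_copulation" and n + 2 * cfg.pad_frames + 2 >= p.copul_min_frames:
                raise ValidationError(
                    "attempted_copulation bout too close to the copulation threshold"
                )
        e = s + n
        if s - margin < 1 or e + margin > T - 1:
            raise ValidationError(
                f"schedule exceeds session length: {behavior} at frames [{s}, {e}) "
                f"needs {margin} margin frames inside [1, {T - 1})"
            )
        items.append((behavior, s, e))
    items.sort(key=lambda it: it[1])
    for (b1, s1, e1), (b2, s2, e2) in zip(items, items[1:]):
        if s2 - margin < e1 + margin + 2:
            raise ValidationError(
                f"overlapping scheduled bouts: {b1} [{s1}, {e1}) and {b2} [{s2}, {e2}) "
                "(windows including ramps must not touch)"
            )
    return items


# ---------------------------------------------------------------------------
# baseline locomotion


def _baseline_walk(
    rng: np.random.Generator,
    anchor: np.ndarray,
    bp: BaselineParams,
    T: int,
    fps: float,
) -> tuple[np.ndarray, np.ndarray]:
    pos = np.empty((T, 2))
    theta = np.empty(T)
    p = anchor + rng.uniform(-0.3, 0.3, 2)
    heading = rng.uniform(-np.pi, np.pi)
    speeds = rng.uniform(0.4, 1.0, T) * bp.mean_speed_mm_s
    turn = rng.normal(0.0, bp.heading_noise, T)
    for t in range(T):
        pos[t] = p
        theta[t] = heading
        heading += turn[t]
        step = (speeds[t] / fps) * np.array([np.cos(heading), np.sin(heading)])
        q = p + step
        if np.hypot(*(q - anchor)) > bp.pocket_radius_mm:
            heading = math.atan2(*(anchor - p)[::-1]) + rng.normal(0.0, 0.3)
            q = p + (speeds[t] / fps) * np.array([np.cos(heading), np.sin(heading)])
        p = q
    return pos, theta


# ---------------------------------------------------------------------------
# behavior injection


def _unit(angle: float) -> np.ndarray:
    return np.array([math.cos(angle), math.sin(angle)])


def _ramp(x, y, theta, col, t0, t1, p_from, p_to):
    """Linear position blend over frames [t0, t1), heading along motion."""
    n = t1 - t0 + 1
    for j in range(t0, t1):
        a = (j - t0 + 1) / n
        px = p_from[0] + a * (p_to[0] - p_from[0])
        py = p_from[1] + a * (p_to[1] - p_from[1])
        x[j, col], y[j, col] = px, py
    if not np.allclose(p_to, p_from):
        theta[t0:t1, col] = math.atan2(p_to[1] - p_from[1], p_to[0] - p_from[0])


def _inject_positions(x, y, theta, w0, w1, R, male_xy, other_xy, male_th, other_th):
    """Write pattern kinematics for the window and ramp both flies in/out."""
    for col, pxy, pth in ((0, male_xy, male_th), (1, other_xy, other_th)):
        if pxy is None:
            continue
        pre_from = np.array([x[w0 - R - 1, col], y[w0 - R - 1, col]])
        post_to = np.array([x[w1 + R, col], y[w1 + R, col]])
        x[w0:w1, col] = pxy[:, 0]
        y[w0:w1, col] = pxy[:, 1]
        theta[w0:w1, col] = pth
        _ramp(x, y, theta, col, w0 - R, w0, pre_from, pxy[0])
        _ramp(x, y, theta, col, w1, w1 + R, pxy[-1], post_to)


def simulate_session(cfg: SimConfig) -> tuple[TrajectorySet, BoutTable]:
    """Generate a session; returns trajectories and the scheduled truth.

    Deterministic given ``cfg.seed``: identical configs produce
    bit-identical trajectories.
    """
    arena = cfg.arena
    T, fps = arena.duration_frames, arena.fps
    if T < 2:
        raise ValidationError("simulated sessions need T >= 2")
    items = _validate_schedule(cfg)
    rng = np.random.default_rng(cfg.seed)
    bp = cfg.baseline
    R, pad = cfg.ramp_frames, cfg.pad_frames

    off = arena.radius_mm - bp.pocket_radius_mm - 0.3
    if 2 * (off - bp.pocket_radius_mm) <= 5.2:
        raise ValidationError("arena too small to keep baseline flies out of reach")
    anchors = (np.array([-off, 0.0]), np.array([off, 0.0]))

    x = np.empty((T, 2))
    y = np.empty((T, 2))
    theta = np.empty((T, 2))
    for col in (0, 1):
        pos, th = _baseline_walk(rng, anchors[col], bp, T, fps)
        x[:, col], y[:, col] = pos[:, 0], pos[:, 1]
        theta[:, col] = th
    wing_left = rng.uniform(1.0, bp.wing_max_jitter_deg, (T, 2))
    wing_right = rng.uniform(1.0, bp.wing_max_jitter_deg, (T, 2))
    body_len = np.tile(np.array(BODY_LEN_MM), (T, 1))

    bouts = []
    for behavior, s, e in items:
        w0, w1 = s - pad, e + pad
        L = w1 - w0
        t_rel = np.arange(L)
        if behavior == "wing_extension":
            ang = rng.uniform(*cfg.wing_angle_range)
            target = wing_left if rng.integers(2) == 0 else wing_right
            target[w0:w1, 0] = ang + rng.uniform(-1.5, 1.5, L)
        elif behavior == "lunge":
            c = rng.uniform(-0.2, 0.2, 2)
            u = _unit(rng.uniform(0, 2 * np.pi))
            nvec = np.array([-u[1], u[0]])
            v = rng.uniform(*cfg.lunge_speed_range)
            d1 = 4.2
            d2 = v / fps - d1
            male_xy = np.empty((L, 2))
            male_xy[: s - w0] = c - u * d1 + nvec * 0.4
            male_xy[s - w0 :] = c + u * d2 + nvec * 0.4
            other_xy = np.tile(c, (L, 1))
            vec = other_xy - male_xy
            male_th = np.arctan2(vec[:, 1], vec[:, 0])
            _inject_positions(
                x, y, theta, w0, w1, R, male_xy, other_xy, male_th, rng.uniform(0, 2 * np.pi)
            )
        elif behavior == "following":
            r = cfg.follow_path_radius_mm
            v = cfg.follow_speed_mm_s
            sign = 1 if rng.integers(2) == 0 else -1
            phi = rng.uniform(0, 2 * np.pi) + sign * (v / (r * fps)) * t_rel
            delta = rng.uniform(*cfg.follow_gap_range) / r
            psi = phi - sign * delta
            other_xy = r * np.column_stack([np.cos(phi), np.sin(phi)])
            male_xy = r * np.column_stack([np.cos(psi), np.sin(psi)])
            _inject_positions(
                x, y, theta, w0, w1, R,
                male_xy, other_xy,
                psi + sign * np.pi / 2, phi + sign * np.pi / 2,
            )
        elif behavior == "circling":
            q = rng.uniform(-0.5, 0.5, 2)
            omega = (1 if rng.integers(2) == 0 else -1) * rng.uniform(*cfg.circle_ang_vel_range)
            psi = rng.uniform(0, 2 * np.pi) + omega * t_rel / fps
            male_xy = q + cfg.circle_radius_mm * np.column_stack([np.cos(psi), np.sin(psi)])
            other_xy = np.tile(q, (L, 1))
            _inject_positions(
                x, y, theta, w0, w1, R,
                male_xy, other_xy, psi + np.pi, rng.uniform(0, 2 * np.pi),
            )
        else:  # attempted_copulation / copulation: mounted pair drifting slowly
            q = rng.uniform(-0.8, 0.8, 2)
            u = _unit(rng.uniform(0, 2 * np.pi))
            phi = rng.uniform(0, 2 * np.pi) + 1.0 * t_rel / fps  # 0.5 mm/s drift
            base = q + 0.5 * np.column_stack([np.cos(phi), np.sin(phi)])
            male_xy = base + u * (cfg.mount_gap_mm / 2)
            other_xy = base - u * (cfg.mount_gap_mm / 2)
            _inject_positions(
                x, y, theta, w0, w1, R, male_xy, other_xy, phi + np.pi / 2, phi + np.pi / 2
            )
        bouts.append(Bout(behavior, "male", s, e))

    if cfg.noise_sd_mm > 0:
        x += rng.normal(0.0, cfg.noise_sd_mm, x.shape)
        y += rng.normal(0.0, cfg.noise_sd_mm, y.shape)
        rr = np.hypot(x, y)
        lim = arena.radius_mm - 0.01
        scale = np.where(rr > lim, lim / np.maximum(rr, 1e-12), 1.0)
        x *= scale
        y *= scale

    traj = TrajectorySet(
        x_mm=x, y_mm=y, theta=theta,
        wing_left_deg=wing_left, wing_right_deg=wing_right, body_len_mm=body_len,
    )
    traj.validate(arena)
    truth = normalize_bouts(BoutTable(bouts, fps=fps, T=T))
    return traj, truth


# ---------------------------------------------------------------------------
# annotation corruption


def corrupt_bouts(
    truth: BoutTable, c: Corruption, T: int | None = None
) -> tuple[BoutTable, dict[str, MatchCounts]]:
    """Degrade a truth table and return the exact expected match counts.

    Per behavior: each truth bout is deleted (-> FN) with ``p_delete``;
    surviving bouts are split in two with ``p_split`` (still one TP under
    the many-to-one rule) or boundary-jittered while preserving >= 1 frame
    of overlap (TP kept); ``n_insert`` spurious bouts are placed in
    behavior-free regions (-> FP each). ``match_bouts`` on the returned
    prediction must equal the returned counts, behavior by behavior.
    """
    T = truth.T if T is None else T
    rng = np.random.default_rng(c.seed)
    truth = normalize_bouts(truth)
    pred: list[Bout] = []
    expected: dict[str, MatchCounts] = {}

    for behavior in BEHAVIORS:
        group = sorted(truth.select(behavior), key=lambda b: b.start)
        if not group:
            continue
        fly = group[0].fly
        tp = fn = 0
        pb: list[tuple[int, int]] = []
        for i, b in enumerate(group):
            if rng.random() < c.p_delete:
                fn += 1
                continue
            tp += 1
            prev_end = group[i - 1].end if i > 0 else 0
            next_start = group[i + 1].start if i + 1 < len(group) else T
            if rng.random() < c.p_split and b.n_frames >= 3:
                cut = int(rng.integers(b.start + 1, b.end - 1))
                pb.append((b.start, cut))
                pb.append((cut + 1, b.end))
            elif c.boundary_jitter_frames > 0:
                j = c.boundary_jitter_frames
                ns = int(np.clip(b.start + rng.integers(-j, j + 1), prev_end, b.end - 1))
                ne = int(np.clip(b.end + rng.integers(-j, j + 1),
                                 max(ns + 1, b.start + 1), next_start))
                pb.append((ns, ne))
            else:
                pb.append((b.start, b.end))

        # spurious insertions in regions free of this behavior, kept clear
        # of existing predictions so normalization cannot merge them away
        occupied = sorted(
            [(s - 1, e + 1) for s, e in pb] + [(b.start, b.end) for b in group]
        )
        fp = 0
        for _ in range(c.n_insert):
            gaps = _free_gaps(occupied, T)
            gaps = [(gs, ge) for gs, ge in gaps if ge - gs >= 3]
            if not gaps:
                raise ValidationError(
                    f"no room to insert spurious {behavior} bouts"
                )
            gs, ge = gaps[int(rng.integers(len(gaps)))]
            max_len = min(ge - gs - 2, 20)
            length = int(rng.integers(1, max_len + 1))
            start = int(rng.integers(gs + 1, ge - length))
            pb.append((start, start + length))
            occupied.append((start - 1, start + length + 1))
            occupied.sort()
            fp += 1

        pred.extend(Bout(behavior, fly, s, e) for s, e in pb)
        expected[behavior] = MatchCounts(
            "bout", tp=tp, fp=fp, fn=fn, n_truth=len(group), n_pred=0
        )

    table = normalize_bouts(BoutTable(pred, fps=truth.fps, T=T))
    for behavior, counts in expected.items():
        expected[behavior] = MatchCounts(
            counts.level, counts.tp, counts.fp, counts.fn,
            counts.n_truth, n_pred=len(table.select(behavior)),
        )
    return table, expected


def _free_gaps(occupied: list[tuple[int, int]], T: int) -> list[tuple[int, int]]:
    """Complement of a sorted interval union within [0, T)."""
    gaps = []
    cursor = 0
    for s, e in sorted(occupied):
        if s > cursor:
            gaps.append((cursor, min(s, T)))
        cursor = max(cursor, e)
    if cursor < T:
        gaps.append((cursor, T))
    return [(max(s, 0), e) for s, e in gaps if e - max(s, 0) > 0]
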