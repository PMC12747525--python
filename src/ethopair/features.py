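"""Per-frame kinematic and dyadic features derived from trajectories.

These are the only quantities the behavior detectors consume. Velocities
use central differences (one-sided at the session endpoints), so for
straight-line constant-velocity motion the speed estimate is exact at
interior frames. All angular features come from exact vector geometry and
are invariant under rigid rotation of the scene about the arena center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .trackdata import ArenaConfig, TrajectorySet, ValidationError


@dataclass(frozen=True)
class FeatureParams:
    """Feature-extraction knobs.

    smoothing_window_frames : odd moving-average window applied to
        positions before differentiation; 1 disables smoothing (default,
        since the simulator produces jitter-free tracks).
    eps : guard for the sideways-fraction denominator so that a
        stationary fly yields 0, not NaN.
    """

    smoothing_window_frames: int = 1
    eps: float = 1e-9

    def __post_init__(self) -> None:
        if self.smoothing_window_frames < 1 or self.smoothing_window_frames % 2 == 0:
            raise ValidationError("smoothing_window_frames must be odd and >= 1")
        if self.eps <= 0:
            raise ValidationError("eps must be > 0")


@dataclass
class FeatureTable:
    """Per-frame features with the focal male fly as reference.

    speed_mm_s / speed_other_mm_s
        Central-difference translational speed of each fly.
    step_speed_mm_s
        Backward per-frame displacement of the male times fps — the
        arrival speed into each frame. This is the quantity the lunge
        detector thresholds: a lunge is a one-to-two-frame snap, and the
        symmetric central estimate halves single-frame spikes.
    approach_speed_mm_s
        Rate of decrease of inter-fly distance (positive = approaching).
    dist_mm
        Inter-centroid distance (symmetric).
    facing_deg
        Angle in [0, 180] between the male's heading and the male->other
        vector (0 = looking straight at the partner).
    behind_deg
        Angle in [0, 180] between the partner's heading and the
        partner->male vector (180 = male directly behind the partner).
    ang_pos_rad / ang_vel_rad_s
        Unwrapped angular position of the male in the partner-centered
        frame and its time derivative.
    sideways_frac
        |v_perp| / (|v_perp| + |v_par| + eps) of the male's velocity
        relative to his body axis; ~1 for pure sideways drift.
    wing_max_deg
        max(left, right) wing angle of the male.
    pair_body_len_mm
        Per-frame mean body length of the two flies (mounting proximity
        is expressed as a fraction of this).
    """

    speed_mm_s: np.ndarray
    speed_other_mm_s: np.ndarray
    step_speed_mm_s: np.ndarray
    approach_speed_mm_s: np.ndarray
    dist_mm: np.ndarray
    facing_deg: np.ndarray
    behind_deg: np.ndarray
    ang_pos_rad: np.ndarray
    ang_vel_rad_s: np.ndarray
    sideways_frac: np.ndarray
    wing_max_deg: np.ndarray
    pair_body_len_mm: np.ndarray
    fps: float

    @property
    def n_frames(self) -> int:
        return int(self.dist_mm.shape[0])

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            name: getattr(self, name)
            for name in (
                "speed_mm_s",
                "speed_other_mm_s",
                "step_speed_mm_s",
                "approach_speed_mm_s",
                "dist_mm",
                "facing_deg",
                "behind_deg",
                "ang_pos_rad",
                "ang_vel_rad_s",
                "sideways_frac",
                "wing_max_deg",
                "pair_body_len_mm",
            )
        }
        df = pd.DataFrame(cols)
        df.insert(0, "frame", np.arange(self.n_frames))
        return df


def _ddt(x: np.ndarray, fps: float) -> np.ndarray:
    """Central-difference time derivative, one-sided at endpoints."""
    v = np.empty_like(x, dtype=float)
    v[1:-1] = (x[2:] - x[:-2]) * (fps / 2.0)
    v[0] = (x[1] - x[0]) * fps
    v[-1] = (x[-1] - x[-2]) * fps
    return v


def _angle_between(ux: np.ndarray, uy: np.ndarray, vx: np.ndarray, vy: np.ndarray) -> np.ndarray:
    """Angle in degrees [0, 180] between vectors u and v; 0 where v vanishes."""
    dot = ux * vx + uy * vy
    cross = ux * vy - uy * vx
    ang = np.degrees(np.abs(np.arctan2(cross, dot)))
    norm = np.hypot(vx, vy) * np.hypot(ux, uy)
    return np.where(norm > 0, ang, 0.0)


def compute_features(
    traj: TrajectorySet,
    arena: ArenaConfig,
    params: FeatureParams | None = None,
) -> FeatureTable:
    """Derive the full feature table from a validated trajectory set."""
    params = params or FeatureParams()
    T = traj.n_frames
    if T < 2:
        raise ValidationError("need T >= 2 frames to compute velocities")
    fps = arena.fps

    x = traj.x_mm.copy()
    y = traj.y_mm.copy()
    w = params.smoothing_window_frames
    if w > 1:
        x = uniform_filter1d(x, size=w, axis=0, mode="nearest")
        y = uniform_filter1d(y, size=w, axis=0, mode="nearest")

    xm, xo = x[:, 0], x[:, 1]
    ym, yo = y[:, 0], y[:, 1]
    th_m, th_o = traj.theta[:, 0], traj.theta[:, 1]

    vx_m, vy_m = _ddt(xm, fps), _ddt(ym, fps)
    vx_o, vy_o = _ddt(xo, fps), _ddt(yo, fps)
    speed_m = np.hypot(vx_m, vy_m)
    speed_o = np.hypot(vx_o, vy_o)

    step = np.empty(T, dtype=float)
    step[1:] = np.hypot(np.diff(xm), np.diff(ym)) * fps
    step[0] = step[1]

    dx, dy = xo - xm, yo - ym
    dist = np.hypot(dx, dy)
    approach = -_ddt(dist, fps)

    facing = _angle_between(np.cos(th_m), np.sin(th_m), dx, dy)
    behind = _angle_between(np.cos(th_o), np.sin(th_o), -dx, -dy)

    ang_pos = np.unwrap(np.arctan2(ym - yo, xm - xo))
    ang_vel = _ddt(ang_pos, fps)

    v_par = vx_m * np.cos(th_m) + vy_m * np.sin(th_m)
    v_perp = -vx_m * np.sin(th_m) + vy_m * np.cos(th_m)
    sideways = np.abs(v_perp) / (np.abs(v_perp) + np.abs(v_par) + params.eps)

    wing_max = np.maximum(traj.wing_left_deg[:, 0], traj.wing_right_deg[:, 0])
    pair_len = traj.body_len_mm.mean(axis=1)

    return FeatureTable(
        speed_mm_s=speed_m,
        speed_other_mm_s=speed_o,
        step_speed_mm_s=step,
        approach_speed_mm_s=approach,
        dist_mm=dist,
        facing_deg=facing,
        behind_deg=behind,
        ang_pos_rad=ang_pos,
        ang_vel_rad_s=ang_vel,
        sideways_frac=sideways,
        wing_max_deg=wing_max,
        pair_body_len_mm=pair_len,
        fps=fps,
    )
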