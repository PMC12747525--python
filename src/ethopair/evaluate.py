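"""Bout- and frame-level evaluation of predicted annotations.

Bout matching follows the event-matching scheme standard in fly behavior
benchmarking: a ground-truth bout overlapped (>= 1 shared frame on the
half-open intervals) by any prediction is one TP regardless of how many
predictions touch it; a single prediction spanning several truth bouts
yields one TP per truth bout; unmatched predictions are FP and unmatched
truth bouts FN. The scheme is asymmetric by construction: TP is counted
over truth bouts while FP is counted over predicted bouts, so
``tp + fn == n_truth`` always holds while ``tp + fp`` need not equal
``n_pred``. A symmetric mode (TP counted over predictions for the
precision denominator) is available but off by default.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .trackdata import (
    BEHAVIORS,
    BoutTable,
    Ethogram,
    ValidationError,
    ethogram_from_bouts,
    normalize_bouts,
)


@dataclass(frozen=True)
class MatchCounts:
    level: str  # "bout" | "frame"
    tp: int
    fp: int
    fn: int
    n_truth: int
    n_pred: int


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float


def match_bouts(
    pred: BoutTable,
    truth: BoutTable,
    behavior: str,
    boundary_tolerance: int = 0,
    symmetric: bool = False,
) -> MatchCounts:
    """Bout-level TP/FP/FN for one behavior.

    ``boundary_tolerance`` dilates every interval by that many frames on
    each side before testing overlap, which forgives small boundary
    disagreements between annotators and detectors.
    """
    if pred.T != truth.T:
        raise ValidationError(f"session lengths differ: pred T={pred.T}, truth T={truth.T}")
    tol = int(boundary_tolerance)
    p_iv = sorted((b.start, b.end) for b in normalize_bouts(pred).select(behavior))
    t_iv = sorted((b.start, b.end) for b in normalize_bouts(truth).select(behavior))

    def _matched(queries: list[tuple[int, int]], others: list[tuple[int, int]]) -> int:
        """Count query intervals overlapping (with tolerance) any other interval."""
        if not others:
            return 0
        starts = np.array([s for s, _ in others])
        run_max_end = np.maximum.accumulate(np.array([e for _, e in others]))
        n = 0
        for qs, qe in queries:
            hi = int(np.searchsorted(starts, qe + tol))  # others with start < qe + tol
            if hi > 0 and run_max_end[hi - 1] + tol > qs:
                n += 1
        return n

    tp = _matched(t_iv, p_iv)
    fn = len(t_iv) - tp
    fp = len(p_iv) - _matched(p_iv, t_iv)
    if symmetric:
        tp = _matched(p_iv, t_iv)
    return MatchCounts("bout", tp, fp, fn, n_truth=len(t_iv), n_pred=len(p_iv))


def match_frames(pred: Ethogram, truth: Ethogram, behavior: str) -> MatchCounts:
    """Frame-level confusion counts for one behavior."""
    if pred.n_frames != truth.n_frames:
        raise ValidationError(
            f"session lengths differ: pred T={pred.n_frames}, truth T={truth.n_frames}"
        )
    p = pred.column(behavior)
    t = truth.column(behavior)
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    return MatchCounts("frame", tp, fp, fn, n_truth=int(t.sum()), n_pred=int(p.sum()))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def metrics(c: MatchCounts) -> Metrics:
    """Precision, recall, F1 with the zero-denominator-gives-0 convention."""
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    return Metrics(precision, recall, f1_score(precision, recall))


def behavior_index(eth: Ethogram, behavior: str) -> float:
    """Fraction of recording frames spent performing a behavior."""
    return float(eth.column(behavior).sum()) / eth.n_frames


def seconds_to_frames(seconds: float, fps: float) -> int:
    """Convert a duration to a frame count (round to nearest, ties to even)."""
    if seconds < 0:
        raise ValidationError("seconds must be >= 0")
    if fps <= 0:
        raise ValidationError("fps must be > 0")
    return int(round(seconds * fps))


def frames_to_seconds(frames: int, fps: float) -> float:
    if fps <= 0:
        raise ValidationError("fps must be > 0")
    return frames / fps


def fit_regression(x, y) -> RegressionFit:
    """Ordinary least squares with intercept; R^2 = 1 - SSres/SStot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("x and y must be equal-length 1-D vectors with n >= 3")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant; regression undefined")
    res = stats.linregress(x, y)
    return RegressionFit(float(res.slope), float(res.intercept), float(res.rvalue**2))


def percent(x: float) -> float:
    """Render a fraction as a percentage with one decimal (report convention)."""
    return round(100.0 * x, 1)


def evaluate_session(
    pred: BoutTable,
    truth: BoutTable,
    behaviors: tuple[str, ...] = BEHAVIORS,
    boundary_tolerance: int = 0,
) -> dict:
    """Per-behavior bout- and frame-level report for one session.

    Returns a JSON-serializable dict with raw counts, fractional metrics,
    percentage renderings, and behavior indices for both annotations.
    """
    if pred.T != truth.T:
        raise ValidationError(f"session lengths differ: pred T={pred.T}, truth T={truth.T}")
    pred_eth = ethogram_from_bouts(normalize_bouts(pred), behaviors=behaviors)
    truth_eth = ethogram_from_bouts(normalize_bouts(truth), behaviors=behaviors)
    report: dict = {
        "session": {"T": truth.T, "fps": truth.fps},
        "behaviors": {},
    }
    for behavior in behaviors:
        entry = {}
        for level, counts in (
            ("bout", match_bouts(pred, truth, behavior, boundary_tolerance)),
            ("frame", match_frames(pred_eth, truth_eth, behavior)),
        ):
            m = metrics(counts)
            entry[level] = {
                **asdict(counts),
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                "precision_pct": percent(m.precision),
                "recall_pct": percent(m.recall),
                "f1_pct": percent(m.f1),
            }
        entry["index_pred"] = behavior_index(pred_eth, behavior)
        entry["index_truth"] = behavior_index(truth_eth, behavior)
        report["behaviors"][behavior] = entry
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
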