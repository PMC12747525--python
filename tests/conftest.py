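import numpy as np
import pytest

from ethopair import ArenaConfig, Bout, BoutTable


@pytest.fixture
def desk_arena() -> ArenaConfig:
    """Small 60 s courtship-geometry arena used throughout the suite."""
    return ArenaConfig(fps=30.0, arena_diameter_mm=11.0, duration_frames=1_800)


def brute_force_match(pred_iv, truth_iv, tol=0):
    """All-pairs interval-overlap oracle for bout matching.

    Intervals are half-open (start, end) tuples; overlap requires at
    least one shared frame after dilating both sides by ``tol``.
    """

    def overlaps(a, b):
        return a[0] < b[1] + tol and b[0] < a[1] + tol

    tp = sum(any(overlaps(t, p) for p in pred_iv) for t in truth_iv)
    fn = len(truth_iv) - tp
    fp = sum(not any(overlaps(p, t) for t in truth_iv) for p in pred_iv)
    return tp, fp, fn


def random_interval_set(rng, T, n_max=8):
    """A sorted list of random non-overlapping half-open intervals in [0, T)."""
    n = int(rng.integers(0, n_max + 1))
    if n == 0:
        return []
    cuts = np.sort(rng.choice(T + 1, size=min(2 * n, T + 1), replace=False))
    return [
        (int(cuts[2 * i]), int(cuts[2 * i + 1]))
        for i in range(len(cuts) // 2)
        if cuts[2 * i] < cuts[2 * i + 1]
    ]


def table_from_intervals(intervals, behavior="following", T=1_000, fps=30.0):
    return BoutTable(
        [Bout(behavior, "male", s, e) for s, e in intervals], fps=fps, T=T
    )
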