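"""Rule-based detectors: boundary semantics, persistence, composition."""

import dataclasses

import numpy as np
import pytest

from ethopair import (
    Bout,
    BoutTable,
    ClassifierParams,
    FeatureTable,
    ValidationError,
    aggression_category,
    apply_duration_floor,
    detect_circling,
    detect_following,
    detect_lunge,
    detect_mounting,
    detect_wing_extension,
)

FPS = 30.0
P = ClassifierParams()


def feat(T=200, **overrides) -> FeatureTable:
    """A quiescent feature table (flies far apart, slow, wings folded)."""
    base = dict(
        speed_mm_s=np.ones(T),
        speed_other_mm_s=np.ones(T),
        step_speed_mm_s=np.ones(T),
        approach_speed_mm_s=np.zeros(T),
        dist_mm=np.full(T, 8.0),
        facing_deg=np.full(T, 90.0),
        behind_deg=np.full(T, 0.0),
        ang_pos_rad=np.zeros(T),
        ang_vel_rad_s=np.zeros(T),
        sideways_frac=np.zeros(T),
        wing_max_deg=np.full(T, 5.0),
        pair_body_len_mm=np.full(T, 2.75),
        fps=FPS,
    )
    base.update(overrides)
    return FeatureTable(**base)


def spans(table: BoutTable, behavior: str):
    return [(b.start, b.end) for b in table.select(behavior)]


class TestWingExtension:
    def test_angle_exactly_at_threshold_never_fires(self):
        f = feat(wing_max_deg=np.full(300, 30.0))
        assert len(detect_wing_extension(f, P, FPS)) == 0

    def test_persistent_extension_detected_as_one_bout(self):
        w = np.full(300, 5.0)
        w[100:130] = 45.0
        bouts = detect_wing_extension(feat(T=300, wing_max_deg=w), P, FPS)
        assert spans(bouts, "wing_extension") == [(100, 130)]

    def test_short_run_below_half_second_discarded(self):
        # persistence at 30 fps is round(0.5 * 30) = 15 frames
        w = np.full(300, 5.0)
        w[100:110] = 45.0  # 10 < 15
        assert len(detect_wing_extension(feat(T=300, wing_max_deg=w), P, FPS)) == 0

    @pytest.mark.parametrize("n,expect", [(14, 0), (15, 1), (16, 1)])
    def test_persistence_boundary_matches_run_scan(self, n, expect):
        w = np.full(300, 5.0)
        w[50 : 50 + n] = 45.0
        f = feat(T=300, wing_max_deg=w)
        bouts = detect_wing_extension(f, P, FPS)
        # brute-force oracle: count runs of >30 frames at least 15 long
        runs, count = 0, 0
        for v in w > 30.0:
            count = count + 1 if v else 0
            if count == 15:
                runs += 1
        assert len(bouts) == runs == expect


class TestLunge:
    def test_no_fast_frame_no_lunge(self):
        assert len(detect_lunge(feat(), P)) == 0

    def test_two_frame_spike_collapses_to_peak_frame(self):
        s = np.ones(100)
        s[50], s[51] = 250.0, 240.0
        f = feat(T=100, step_speed_mm_s=s, dist_mm=np.full(100, 3.0),
                 facing_deg=np.full(100, 10.0))
        assert spans(detect_lunge(f, P), "lunge") == [(50, 51)]

    def test_earliest_frame_wins_exact_speed_tie(self):
        s = np.ones(100)
        s[50], s[51] = 250.0, 250.0
        f = feat(T=100, step_speed_mm_s=s, dist_mm=np.full(100, 3.0),
                 facing_deg=np.full(100, 10.0))
        assert spans(detect_lunge(f, P), "lunge") == [(50, 51)]

    def test_spikes_beyond_refractory_stay_separate(self):
        s = np.ones(100)
        s[[20, 25]] = 260.0  # 5 > refractory 3
        f = feat(T=100, step_speed_mm_s=s, dist_mm=np.full(100, 3.0),
                 facing_deg=np.full(100, 10.0))
        assert spans(detect_lunge(f, P), "lunge") == [(20, 21), (25, 26)]

    def test_fast_frame_far_from_opponent_ignored(self):
        s = np.ones(100)
        s[50] = 260.0
        f = feat(T=100, step_speed_mm_s=s)  # dist 8 mm > 5
        assert len(detect_lunge(f, P)) == 0

    def test_all_lunges_single_frame(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(0, 300, 500)
        f = feat(T=500, step_speed_mm_s=s, dist_mm=np.full(500, 3.0),
                 facing_deg=np.full(500, 10.0))
        assert all(b.n_frames == 1 for b in detect_lunge(f, P))


class TestFollowing:
    def _geometry(self, T=100, dist=3.5, both_speed=5.0, other_speed=None):
        return feat(
            T=T,
            dist_mm=np.full(T, dist),
            behind_deg=np.full(T, 170.0),
            speed_mm_s=np.full(T, both_speed),
            speed_other_mm_s=np.full(T, other_speed if other_speed is not None else both_speed),
        )

    def test_stationary_female_blocks_following(self):
        f = self._geometry(other_speed=0.0)
        assert len(detect_following(f, P)) == 0

    def test_sustained_pursuit_one_bout(self):
        assert spans(detect_following(self._geometry(T=60), P), "following") == [(0, 60)]

    def test_distance_drift_window_matches_frame_scan_oracle(self):
        T = 200
        dist = np.linspace(1.5, 6.0, T)
        f = feat(T=T, dist_mm=dist, behind_deg=np.full(T, 170.0),
                 speed_mm_s=np.full(T, 5.0), speed_other_mm_s=np.full(T, 5.0))
        got = spans(detect_following(f, P), "following")
        ok = (dist >= 2.0) & (dist <= 5.0)
        # brute-force frame scan: the single maximal qualifying run
        idx = np.flatnonzero(ok)
        expected = [(int(idx[0]), int(idx[-1]) + 1)] if len(idx) >= 25 else []
        assert got == expected


class TestCircling:
    def test_straight_walk_past_female_ignored(self):
        f = feat(dist_mm=np.full(200, 3.0), ang_vel_rad_s=np.full(200, 2.0),
                 sideways_frac=np.full(200, 0.1))
        assert len(detect_circling(f, P)) == 0

    def test_sideways_orbit_detected(self):
        T = 45
        f = feat(T=T, dist_mm=np.full(T, 3.0), ang_vel_rad_s=np.full(T, 2.0),
                 sideways_frac=np.full(T, 0.9))
        assert spans(detect_circling(f, P), "circling") == [(0, 45)]

    def test_interrupted_orbit_splits_at_the_dash(self):
        T = 120
        side = np.full(T, 0.9)
        side[40:60] = 0.1  # 20-frame straight dash
        f = feat(T=T, dist_mm=np.full(T, 3.0), ang_vel_rad_s=np.full(T, 2.0),
                 sideways_frac=side)
        got = spans(detect_circling(f, P), "circling")
        assert got == [(0, 40), (60, 120)]
        # oracle: re-scan the predicate frame by frame
        ok = (np.full(T, 3.0) <= 5.0) & (np.abs(np.full(T, 2.0)) >= 1.0) & (side >= 0.5)
        for s, e in got:
            assert ok[s:e].all()


class TestMounting:
    def _mounted(self, T, n, start=10):
        dist = np.full(T, 8.0)
        sp = np.full(T, 5.0)
        dist[start : start + n] = 0.6
        sp[start : start + n] = 0.5
        return feat(T=T, dist_mm=dist, speed_mm_s=sp, speed_other_mm_s=sp)

    def test_45s_run_is_copulation(self):
        f = self._mounted(T=1400, n=1350)
        bouts = detect_mounting(f, P, FPS)
        assert spans(bouts, "copulation") == [(10, 1360)]
        assert len(bouts.select("attempted_copulation")) == 0

    def test_one_frame_short_of_45s_is_attempted(self):
        f = self._mounted(T=1400, n=1349)
        bouts = detect_mounting(f, P, FPS)
        assert spans(bouts, "attempted_copulation") == [(10, 1359)]
        assert len(bouts.select("copulation")) == 0

    def test_sub_third_of_second_run_discarded(self):
        assert len(detect_mounting(self._mounted(T=100, n=9), P, FPS)) == 0

    def test_mount_and_copulation_never_overlap_and_tile_the_runs(self):
        rng = np.random.default_rng(5)
        T = 6000
        dist = np.full(T, 8.0)
        sp = np.zeros(T)
        pos = 0
        while pos < T - 100:
            n = int(rng.integers(1, 2000))
            dist[pos : pos + n] = 0.5
            pos += n + int(rng.integers(5, 50))
        f = feat(T=T, dist_mm=dist, speed_mm_s=sp, speed_other_mm_s=sp)
        bouts = detect_mounting(f, P, FPS)
        ivs = sorted(
            (b.start, b.end) for b in bouts
        )
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2  # no overlap
        mounted_runs = [
            (s, e)
            for s, e in zip(*[iter(np.flatnonzero(np.diff(np.r_[0, dist < 1, 0])))] * 2)
        ]
        expected = [(s, e) for s, e in mounted_runs if e - s >= P.attempt_min_frames]
        assert ivs == expected


class TestDurationFloor:
    def test_uniform_reference_sets_exact_floor(self):
        t = BoutTable(
            [Bout("following", "male", 0, 18), Bout("following", "male", 30, 50)],
            fps=FPS, T=100,
        )
        out = apply_duration_floor(t, [20] * 10, coverage=0.98)
        assert spans(out, "following") == [(30, 50)]

    def test_full_coverage_floor_is_reference_minimum(self):
        t = BoutTable([Bout("following", "male", 0, 5)], fps=FPS, T=100)
        assert len(apply_duration_floor(t, [5, 9, 30], coverage=1.0)) == 1
        assert len(apply_duration_floor(t, [6, 9, 30], coverage=1.0)) == 0

    def test_quantile_floor_matches_sort_and_count_oracle(self):
        ref = list(range(1, 101))
        t = BoutTable(
            [Bout("following", "male", i * 10, i * 10 + n) for i, n in enumerate([1, 2, 3])],
            fps=FPS, T=1_000,
        )
        out = apply_duration_floor(t, ref, coverage=0.98)
        # oracle: sort the reference and take the value at the largest
        # index i with i/(n-1) <= 0.02 (lower interpolation) -> 2
        srt = sorted(ref)
        idx = max(i for i in range(len(srt)) if i / (len(srt) - 1) <= 0.02)
        floor = srt[idx]
        assert floor == 2
        assert sum(d >= floor for d in ref) / len(ref) >= 0.98
        assert [b.n_frames for b in out] == [d for d in (1, 2, 3) if d >= floor]

    def test_lunges_exempt_from_floor(self):
        t = BoutTable([Bout("lunge", "male", 5, 6)], fps=FPS, T=100)
        assert len(apply_duration_floor(t, [20] * 5, coverage=0.98)) == 1

    def test_empty_reference_rejected(self):
        t = BoutTable([], fps=FPS, T=100)
        with pytest.raises(ValidationError):
            apply_duration_floor(t, [], coverage=0.98)


class TestAggressionCategory:
    @pytest.mark.parametrize(
        "count,label",
        [(0, "low"), (70, "low"), (71, "moderate"), (160, "moderate"),
         (161, "high"), (300, "high"), (301, "hyper"), (1000, "hyper")],
    )
    def test_category_boundaries(self, count, label):
        assert aggression_category(count) == label

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            aggression_category(-1)


class TestDetectorProperties:
    def test_emitted_frames_satisfy_their_predicate(self):
        rng = np.random.default_rng(7)
        T = 2_000
        f = feat(
            T=T,
            dist_mm=rng.uniform(0, 10, T),
            behind_deg=rng.uniform(0, 180, T),
            speed_mm_s=rng.uniform(0, 10, T),
            speed_other_mm_s=rng.uniform(0, 10, T),
            ang_vel_rad_s=rng.uniform(-3, 3, T),
            sideways_frac=rng.uniform(0, 1, T),
            wing_max_deg=rng.uniform(0, 90, T),
            step_speed_mm_s=rng.uniform(0, 300, T),
            facing_deg=rng.uniform(0, 180, T),
        )
        checks = [
            (detect_wing_extension(f, P, FPS), f.wing_max_deg > 30.0),
            (detect_following(f, P),
             (f.dist_mm >= 2) & (f.dist_mm <= 5) & (f.behind_deg >= 120)
             & (f.speed_mm_s >= 2) & (f.speed_other_mm_s >= 2)),
            (detect_circling(f, P),
             (f.dist_mm <= 5) & (np.abs(f.ang_vel_rad_s) >= 1)
             & (f.sideways_frac >= 0.5)),
            (detect_lunge(f, P),
             (f.step_speed_mm_s >= 200) & (f.dist_mm <= 5) & (f.facing_deg <= 45)),
        ]
        for bouts, predicate in checks:
            for b in bouts:
                assert predicate[b.start : b.end].all()

    def test_raising_persistence_never_adds_bouts(self):
        rng = np.random.default_rng(8)
        w = np.where(rng.random(3_000) < 0.4, 45.0, 5.0)
        f = feat(T=3_000, wing_max_deg=w)
        counts = []
        for persist_s in (0.1, 0.3, 0.5, 1.0, 2.0):
            p = dataclasses.replace(P, wing_persist_s=persist_s)
            counts.append(len(detect_wing_extension(f, p, FPS)))
        assert counts == sorted(counts, reverse=True)
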