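"""Synthetic-track generator: determinism, geometry and noise calibration."""

import numpy as np
import pytest
from scipy import stats

from gpstops.generate import (
    GeneratorConfig,
    apply_noise,
    build_noiseless_path,
    generate_track,
    generate_track_set,
    sample_stop_plan,
    track_rng,
)
from gpstops.model import TrackTruth, TrueStop


class TestStopPlan:
    def test_has_configured_number_of_stops(self):
        cfg = GeneratorConfig(master_seed=0)
        truth = sample_stop_plan(track_rng(0, 0), cfg)
        assert len(truth.stops) == 3

    def test_durations_fall_in_a_category(self):
        cfg = GeneratorConfig(master_seed=3)
        bounds_s = [(lo * 60, hi * 60) for lo, hi in cfg.duration_bounds]
        for i in range(50):
            truth = sample_stop_plan(track_rng(3, i), cfg)
            for s in truth.stops:
                assert any(lo <= s.duration <= hi for lo, hi in bounds_s)

    def test_same_seed_same_plan(self):
        cfg = GeneratorConfig(master_seed=11)
        a = sample_stop_plan(track_rng(11, 4), cfg)
        b = sample_stop_plan(track_rng(11, 4), cfg)
        assert a.noise_m == b.noise_m
        assert all(
            (p.cx, p.cy, p.t_arrive, p.t_depart) == (q.cx, q.cy, q.t_arrive, q.t_depart)
            for p, q in zip(a.stops, b.stops)
        )

    def test_centers_inside_area(self):
        cfg = GeneratorConfig(master_seed=5, area_side=6000.0)
        for i in range(20):
            truth = sample_stop_plan(track_rng(5, i), cfg)
            for s in truth.stops:
                assert 0 <= s.cx <= 6000 and 0 <= s.cy <= 6000


class TestNoiselessPath:
    def test_trip_leg_arithmetic(self):
        # two stops 3,600 m apart at 10 m/s -> 360 s leg, 36 interior fixes
        truth = TrackTruth(
            stops=(TrueStop(0, 0, 0.0, 600.0), TrueStop(3600, 0, 960.0, 1560.0)),
            noise_m=0.0,
        )
        cfg = GeneratorConfig(master_seed=0)
        tr = build_noiseless_path(truth, cfg)
        interior = np.sum((tr.t > 600) & (tr.t < 960))
        assert interior == 35  # fixes at 610..950 s
        assert np.sum((tr.x > 0) & (tr.x < 3600)) == 35

    def test_dwell_fix_count(self):
        # 600 s dwell sampled at 10 s -> 61 coincident fixes at the center
        truth = TrackTruth(
            stops=(TrueStop(5, 7, 0.0, 600.0), TrueStop(1000, 7, 700.0, 1300.0)),
            noise_m=0.0,
        )
        tr = build_noiseless_path(truth, GeneratorConfig(master_seed=0))
        at_stop = np.sum((tr.x == 5) & (tr.y == 7))
        assert at_stop == 61

    def test_total_duration_matches_hand_summation(self):
        cfg = GeneratorConfig(master_seed=9)
        truth = sample_stop_plan(track_rng(9, 0), cfg)
        tr = build_noiseless_path(truth, cfg)
        legs = sum(
            np.hypot(b.cx - a.cx, b.cy - a.cy)
            for a, b in zip(truth.stops, truth.stops[1:])
        )
        expected = sum(s.duration for s in truth.stops) + legs / cfg.speed
        assert tr.t[-1] - tr.t[0] == pytest.approx(expected, abs=cfg.fix_interval)

    def test_fixes_at_stop_equal_center_exactly(self):
        cfg = GeneratorConfig(master_seed=13)
        truth = sample_stop_plan(track_rng(13, 2), cfg)
        tr = build_noiseless_path(truth, cfg)
        for s in truth.stops:
            win = (tr.t >= s.t_arrive) & (tr.t <= s.t_depart)
            assert np.all(tr.x[win] == s.cx)
            assert np.all(tr.y[win] == s.cy)


class TestNoise:
    def test_zero_noise_is_identity(self, stationary_track):
        out = apply_noise(stationary_track, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out.x, stationary_track.x)
        np.testing.assert_array_equal(out.y, stationary_track.y)

    def test_negative_noise_rejected(self, stationary_track):
        with pytest.raises(ValueError):
            apply_noise(stationary_track, -1.0, np.random.default_rng(0))

    def test_mean_radial_displacement_matches_rayleigh(self):
        # E[r] for bivariate normal with per-axis SD nu is nu * sqrt(pi/2)
        from gpstops.model import Track

        n = 10_000
        tr = Track(id="flat", t=np.arange(float(n)), x=np.zeros(n), y=np.zeros(n))
        out = apply_noise(tr, 50.0, np.random.default_rng(42))
        mean_r = np.hypot(out.x, out.y).mean()
        assert mean_r == pytest.approx(50.0 * np.sqrt(np.pi / 2), abs=2.0)

    def test_fixed_seed_reproducible(self, stationary_track):
        a = apply_noise(stationary_track, 30.0, np.random.default_rng(8))
        b = apply_noise(stationary_track, 30.0, np.random.default_rng(8))
        np.testing.assert_array_equal(a.x, b.x)

    def test_noise_sd_recoverable_from_stop_windows(self):
        cfg = GeneratorConfig(master_seed=21)
        for i in range(8):
            tr = generate_track(cfg, i)
            nu = tr.truth.noise_m
            if nu < 20:
                continue  # relative recovery check meaningless near zero
            for s in tr.truth.stops:
                win = (tr.t >= s.t_arrive) & (tr.t <= s.t_depart)
                if win.sum() < 100:
                    continue
                sd = np.std(np.r_[tr.x[win] - s.cx, tr.y[win] - s.cy], ddof=1)
                assert sd == pytest.approx(nu, rel=0.10)


class TestTrackSet:
    def test_configured_number_of_tracks(self):
        tracks = generate_track_set(GeneratorConfig(n_tracks=12, master_seed=1))
        assert len(tracks) == 12
        assert all(tr.truth is not None and len(tr) >= 2 for tr in tracks)

    def test_noise_levels_uniform_across_bins(self):
        # per-track nu ~ U[0, 200]: the four 50 m bins should be balanced
        cfg = GeneratorConfig(n_tracks=750, master_seed=17)
        nus = [sample_stop_plan(track_rng(17, i), cfg).noise_m for i in range(750)]
        counts = np.histogram(nus, bins=[0, 50, 100, 150, 200.0001])[0]
        assert stats.chisquare(counts).pvalue > 0.01

    def test_close_stop_incidence_near_design_value(self):
        # fraction of tracks with two stops within 800 m in a 6 km square
        cfg = GeneratorConfig(n_tracks=750, master_seed=23)
        frac = np.mean(
            [
                sample_stop_plan(track_rng(23, i), cfg).min_pairwise_distance() <= 800
                for i in range(750)
            ]
        )
        assert frac == pytest.approx(0.12, abs=0.04)

    def test_same_master_seed_same_truth_file(self, tmp_path):
        from gpstops.io import write_truth_csv

        for name in ("a", "b"):
            tracks = generate_track_set(GeneratorConfig(n_tracks=20, master_seed=31))
            write_truth_csv(tracks, tmp_path / f"{name}.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_stops_only_noise_scope_leaves_trips_exact(self):
        cfg = GeneratorConfig(master_seed=3, noise_scope="stops")
        tr = generate_track(cfg, 1)
        clean = build_noiseless_path(tr.truth, cfg, track_id=tr.id)
        stop_win = np.zeros(len(tr), dtype=bool)
        for s in tr.truth.stops:
            stop_win |= (tr.t >= s.t_arrive) & (tr.t <= s.t_depart)
        np.testing.assert_array_equal(tr.x[~stop_win], clean.x[~stop_win])
        if tr.truth.noise_m > 1:
            assert not np.allclose(tr.x[stop_win], clean.x[stop_win])
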