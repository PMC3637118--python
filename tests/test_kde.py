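"""Kernel-density detector: closed forms, oracle equivalence, invariants."""

import numpy as np
import pytest

from gpstops.generate import GeneratorConfig, build_noiseless_path
from gpstops.kde import (
    TRIP,
    DensitySurface,
    KdParams,
    assign_fixes,
    build_visits,
    compute_density_surface,
    compute_density_surface_bruteforce,
    detect_stops_kd,
    extract_peaks,
)
from gpstops.model import Track

from conftest import make_three_stop_truth


class TestDensitySurface:
    def test_single_fix_closed_form_at_center(self):
        # K(0) = 3 / (pi h^2); the grid is anchored so the fix sits on a cell center
        h = 100.0
        p = KdParams(bandwidth=h)
        s = compute_density_surface(np.array([40.0]), np.array([-7.0]), p)
        assert s.values.max() == pytest.approx(3.0 / (np.pi * h * h), rel=1e-12)

    def test_support_is_compact(self):
        p = KdParams(bandwidth=50.0)
        s = compute_density_surface(np.array([0.0, 5.0]), np.array([0.0, 0.0]), p)
        ii, jj = np.nonzero(s.values)
        cx = s.x0 + (jj + 0.5) * s.cell_size
        cy = s.y0 + (ii + 0.5) * s.cell_size
        d = np.minimum(np.hypot(cx - 0, cy - 0), np.hypot(cx - 5, cy - 0))
        assert d.max() <= 50.0

    def test_mass_conservation_within_1pct(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 500, 300)
        y = rng.uniform(0, 500, 300)
        for h in (10.0, 50.0, 200.0):
            s = compute_density_surface(x, y, KdParams(bandwidth=h))
            mass = s.values.sum() * s.cell_size**2
            assert mass == pytest.approx(300.0, rel=0.01)

    @pytest.mark.parametrize("h", [10.0, 50.0, 120.0])
    def test_matches_bruteforce_oracle(self, h):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 400, 500)
        y = rng.uniform(0, 400, 500)
        p = KdParams(bandwidth=h)
        fast = compute_density_surface(x, y, p)
        brute = compute_density_surface_bruteforce(x, y, p)
        err = np.abs(fast.values - brute.values).max()
        assert err <= 1e-9 * brute.values.max()

    def test_empty_fix_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_density_surface(np.array([]), np.array([]), KdParams(bandwidth=50))


class TestPeaks:
    def test_coincident_fixes_give_one_peak_at_location(self):
        p = KdParams(bandwidth=100.0)
        x = np.full(30, 123.0)
        y = np.full(30, -45.0)
        s = compute_density_surface(x, y, p)
        peaks = extract_peaks(s)
        assert len(peaks) == 1
        px, py = peaks[0].cell_center
        assert abs(px - 123.0) <= s.cell_size
        assert abs(py + 45.0) <= s.cell_size

    def test_two_distant_clusters_give_two_peaks(self):
        # clusters separated by 4h: densities are independent bumps
        h = 50.0
        rng = np.random.default_rng(5)
        x = np.r_[rng.normal(0, 5, 50), rng.normal(4 * h, 5, 50)]
        y = np.r_[rng.normal(0, 5, 50), rng.normal(0, 5, 50)]
        peaks = extract_peaks(compute_density_surface(x, y, KdParams(bandwidth=h)))
        assert len(peaks) == 2
        xs = sorted(q.cell_center[0] for q in peaks)
        assert abs(xs[0] - 0) < 3 * 5 and abs(xs[1] - 4 * h) < 3 * 5

    def test_all_zero_surface_has_no_peaks(self):
        s = DensitySurface(x0=0.0, y0=0.0, cell_size=10.0, values=np.zeros((8, 8)))
        assert extract_peaks(s) == []

    def test_plateau_collapses_to_single_peak(self):
        v = np.zeros((9, 9))
        v[4, 3:6] = 2.0  # 3-cell plateau
        s = DensitySurface(x0=0.0, y0=0.0, cell_size=1.0, values=v)
        peaks = extract_peaks(s)
        assert len(peaks) == 1
        assert peaks[0].cell_center == pytest.approx((4.5, 4.5))

    def test_ordering_by_descending_density(self):
        v = np.zeros((12, 12))
        v[3, 3] = 1.0
        v[8, 8] = 5.0
        s = DensitySurface(x0=0.0, y0=0.0, cell_size=1.0, values=v)
        peaks = extract_peaks(s)
        assert [q.density for q in peaks] == [5.0, 1.0]
        assert peaks[0].grid_cell == (8, 8)


class TestAssignment:
    def _peaks(self):
        v = np.zeros((40, 40))
        v[10, 10] = 2.0
        v[10, 30] = 1.0
        s = DensitySurface(x0=0.0, y0=0.0, cell_size=1.0, values=v)
        return extract_peaks(s)  # peak0 at (10.5,10.5), peak1 at (30.5,10.5)

    def test_fix_at_peak_gets_its_id(self):
        p = KdParams(bandwidth=5.0, allocation_radius_factor=1.0)
        labels = assign_fixes(np.array([10.5]), np.array([10.5]), self._peaks(), p)
        assert labels[0] == 0

    def test_far_fix_is_trip(self):
        p = KdParams(bandwidth=5.0, allocation_radius_factor=1.0)
        labels = assign_fixes(np.array([20.5]), np.array([10.5]), self._peaks(), p)
        assert labels[0] == TRIP

    def test_equidistant_tie_breaks_to_lowest_id(self):
        peaks = self._peaks()
        p = KdParams(bandwidth=12.0, allocation_radius_factor=1.0)
        labels = assign_fixes(np.array([20.5]), np.array([10.5]), peaks, p)
        assert labels[0] == 0


class TestVisits:
    def test_run_of_31_fixes_is_a_300s_visit(self):
        labels = np.array([TRIP] * 3 + [0] * 31 + [TRIP] * 3)
        t = 10.0 * np.arange(len(labels))
        visits = build_visits(labels, t, KdParams(bandwidth=100))
        assert len(visits[0]) == 1
        assert visits[0][0].duration == pytest.approx(300.0)
        assert visits[0][0].n_fixes == 31

    def test_short_run_still_emitted(self):
        labels = np.array([0] * 30)  # 290 s: emitted here, filtered later
        visits = build_visits(labels, 10.0 * np.arange(30), KdParams(bandwidth=100))
        assert visits[0][0].duration == pytest.approx(290.0)

    def test_single_trip_fix_gap_merges(self):
        labels = np.array([0] * 10 + [TRIP] + [0] * 10)
        t = 10.0 * np.arange(len(labels))
        visits = build_visits(labels, t, KdParams(bandwidth=100, merge_gap=60.0))
        assert len(visits[0]) == 1
        assert visits[0][0].duration == pytest.approx(200.0)  # spans the gap
        assert visits[0][0].n_fixes == 20

    def test_long_gap_does_not_merge(self):
        labels = np.array([0] * 10 + [TRIP] * 10 + [0] * 10)
        t = 10.0 * np.arange(len(labels))
        visits = build_visits(labels, t, KdParams(bandwidth=100, merge_gap=60.0))
        assert len(visits[0]) == 2


class TestDetection:
    def test_noiseless_three_stop_recovery(self):
        cfg = GeneratorConfig(master_seed=0)
        truth = make_three_stop_truth()
        tr = build_noiseless_path(truth, cfg, track_id="clean")
        p = KdParams(bandwidth=200.0)
        stops = detect_stops_kd(tr, p)
        assert len(stops) == 3
        for s, true in zip(stops, truth.stops):  # chronological order
            assert np.hypot(s.x - true.cx, s.y - true.cy) <= p.resolved_cell_size
            # constant-speed transit through the allocation disk bounds the
            # duration overshoot: radius/speed per adjacent trip leg
            slack = 2 * cfg.fix_interval + 2 * p.allocation_radius / cfg.speed
            assert abs(s.total_duration - true.duration) <= slack

    def test_translation_equivariance_by_whole_cells(self):
        cfg = GeneratorConfig(master_seed=0)
        truth = make_three_stop_truth()
        tr = build_noiseless_path(truth, cfg, track_id="base")
        p = KdParams(bandwidth=100.0)
        shift = 7 * p.resolved_cell_size
        tr2 = Track(id="shifted", t=tr.t.copy(), x=tr.x + shift, y=tr.y - shift)
        a = detect_stops_kd(tr, p)
        b = detect_stops_kd(tr2, p)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert sb.x - sa.x == pytest.approx(shift, abs=1e-6)
            assert sb.y - sa.y == pytest.approx(-shift, abs=1e-6)
            assert sb.total_duration == pytest.approx(sa.total_duration)

    def test_peak_count_monotone_in_bandwidth(self):
        # fixed multi-cluster fixture: stronger smoothing only removes detail
        rng = np.random.default_rng(9)
        centers = [(0, 0), (400, 0), (1500, 1000), (4000, 0), (4000, 350)]
        x = np.concatenate([cx + rng.normal(0, 5, 40) for cx, _ in centers])
        y = np.concatenate([cy + rng.normal(0, 5, 40) for _, cy in centers])
        counts = []
        for h in (50.0, 100.0, 200.0, 500.0, 1000.0):
            s = compute_density_surface(x, y, KdParams(bandwidth=h))
            counts.append(len(extract_peaks(s)))
        assert counts[0] == len(centers)  # well separated at the finest scale
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] < len(centers)  # strong smoothing merges close pairs

    def test_stop_durations_meet_minimum_and_fix_budget(self):
        from gpstops.generate import generate_track

        tr = generate_track(GeneratorConfig(master_seed=6), 0)
        p = KdParams(bandwidth=200.0)
        stops = detect_stops_kd(tr, p)
        assert sum(s.n_fixes for s in stops) <= len(tr)
        for s in stops:
            assert max(v.duration for v in s.visits) >= p.min_stop_duration
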