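"""Tracking, histograms, separation statistics, dwell fits, MSD, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cavity_demix as cd
from cavity_demix.errors import ConfigurationError, DataError, FitError, TrackingError
from cavity_demix.fields import ScalarField, make_grid
from cavity_demix.landscape_dynamics import Trajectory
from cavity_demix.trajectory_analysis import (
    DwellTimeStats,
    MSDResult,
    SeparationSeries,
    average_msd,
)


def make_series(times, projection):
    """SeparationSeries with only the projection populated (swap tests)."""
    n = len(times)
    return SeparationSeries(times=np.asarray(times, float),
                            separation_vectors=np.zeros((n, 2)),
                            theta=np.zeros(n),
                            normalized_projection=np.asarray(projection, float),
                            semi_major=1.0)


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------

class TestBackgroundSubtraction:
    def test_uniform_removed(self):
        img = np.full((32, 32), 7.3)
        assert np.allclose(cd.subtract_background(img), 0.0)

    def test_zero_stays_zero(self):
        assert np.allclose(cd.subtract_background(np.zeros((16, 16))), 0.0)

    def test_blob_mass_preserved(self):
        yy, xx = np.mgrid[:32, :32]
        blob = 100.0 * np.exp(-((xx - 16) ** 2 + (yy - 16) ** 2) / 8.0)
        img = blob + 5.0
        out = cd.subtract_background(img)
        assert out.sum() == pytest.approx(blob.sum(), rel=0.01)

    def test_empty_border_rejected(self):
        with pytest.raises(ConfigurationError):
            cd.subtract_background(np.zeros((4, 4)), border_width=2)


class TestFluorescenceCM:
    def test_single_pixel(self):
        img = np.zeros((8, 8))
        img[3, 5] = 2.0
        cm = cd.fluorescence_cm(img, pixel_size=0.1, origin=(0.0, 0.0))
        assert cm[0] == pytest.approx(0.5)
        assert cm[1] == pytest.approx(0.3)

    def test_weighted_mean(self):
        # intensities 1 at x=0 and 3 at x=4 px: centroid at 3 px
        img = np.zeros((1, 8))
        img[0, 0], img[0, 4] = 1.0, 3.0
        cm = cd.fluorescence_cm(img, pixel_size=1.0, origin=(0.0, 0.0))
        assert cm[0] == pytest.approx(3.0)

    def test_gaussian_blob_recovery(self):
        cfg = cd.RenderConfig(noise_model="none", background_level=0.0, seed=0)
        pos = np.array([[0.31, -0.22], [0.31, -0.22]])
        traj = Trajectory(pos, 0.05)
        stacks, _ = cd.render_movie({"ch": traj}, cfg)
        cm = cd.fluorescence_cm(stacks["ch"][0], cfg.pixel_size, cfg.origin)
        assert np.abs(cm - pos[0]).max() < 0.05 * cfg.pixel_size

    def test_zero_intensity_flagged(self):
        with pytest.raises(TrackingError):
            cd.fluorescence_cm(np.zeros((8, 8)), 0.1, (0.0, 0.0))


class TestTrackMovie:
    def test_rendered_trajectory_recovered(self):
        rng = np.random.default_rng(5)
        pos = 0.4 * rng.standard_normal((20, 2)).cumsum(axis=0) * 0.1
        pos = np.clip(pos, -1.0, 1.0)
        traj = Trajectory(pos, 0.05)
        cfg = cd.RenderConfig(seed=1)
        stacks, _ = cd.render_movie({"g": traj}, cfg)
        out = cd.track_movie(stacks, cfg.pixel_size, 0.05, cfg.origin)
        err = np.linalg.norm(out["g"].positions - pos, axis=1)
        assert np.sqrt((err**2).mean()) < 0.5 * cfg.pixel_size

    def test_two_channels_independent(self):
        p1 = np.tile([[0.5, 0.5]], (5, 1))
        p2 = np.tile([[-0.5, -0.5]], (5, 1))
        cfg = cd.RenderConfig(noise_model="none", background_level=2.0, seed=2)
        stacks, _ = cd.render_movie({"a": Trajectory(p1, 0.05),
                                     "b": Trajectory(p2, 0.05)}, cfg)
        out = cd.track_movie(stacks, cfg.pixel_size, 0.05, cfg.origin)
        assert np.abs(out["a"].positions - p1).max() < 0.01
        assert np.abs(out["b"].positions - p2).max() < 0.01

    def test_static_blob_constant(self):
        pos = np.tile([[0.2, -0.1]], (10, 1))
        cfg = cd.RenderConfig(seed=3)
        stacks, _ = cd.render_movie({"c": Trajectory(pos, 0.05)}, cfg)
        out = cd.track_movie(stacks, cfg.pixel_size, 0.05, cfg.origin)
        assert out["c"].positions.std(axis=0).max() < 0.01  # noise floor


# ---------------------------------------------------------------------------
# histograms and free-energy maps
# ---------------------------------------------------------------------------

class TestPositionHistogram:
    def test_single_position_single_bin(self, circle):
        traj = Trajectory(np.tile([[0.21, 0.11]], (50, 1)), 0.05)
        h = cd.position_histogram(traj, circle, bin_size=0.05)
        mass = h.values * h.grid_spacing**2
        assert mass.max() == pytest.approx(1.0, abs=1e-12)
        assert h.integrate() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_sampling_poisson_consistent(self, circle):
        grid = make_grid(circle, 0.1)
        flat = grid.copy_with(np.zeros(grid.shape), role="potential")
        pts = cd.sample_boltzmann_positions(flat, 100_000, seed=9)
        h = cd.position_histogram(Trajectory(pts, 1.0), circle, bin_size=0.1)
        counts = h.values * h.grid_spacing**2 * len(pts)
        interior = counts[h.mask]
        # interior bins fully inside the ellipse: uniform expectation
        fully_inside = cd.effective_radius(
            circle, np.stack(h.cell_centers(), axis=-1))[h.mask] < 0.9
        exp = interior[fully_inside].mean()
        dev = np.abs(interior[fully_inside] - exp) / np.sqrt(exp)
        assert dev.max() < 5.0

    def test_outside_positions_counted_and_reported(self, circle):
        pts = np.array([[0.0, 0.0], [5.0, 5.0]])
        h = cd.position_histogram(Trajectory(np.repeat(pts, 2, axis=0), 1.0),
                                  circle, bin_size=0.1)
        assert h.meta["n_outside"] == 2


class TestFreeEnergyMap:
    def test_uniform_is_zero(self, circle):
        grid = make_grid(circle, 0.1)
        grid.values[grid.mask] = 1.0
        f = cd.free_energy_map(grid.normalized())
        assert np.allclose(f.values[f.mask], 0.0)
        assert f.values[f.mask].min() == 0.0


# ---------------------------------------------------------------------------
# separation vector and order parameter
# ---------------------------------------------------------------------------

class TestSeparationSeries:
    def make_pair(self, offsets):
        base = np.zeros((len(offsets), 2))
        t1 = Trajectory(base + np.asarray(offsets) / 2, 0.1)
        t2 = Trajectory(base - np.asarray(offsets) / 2, 0.1)
        return t1, t2

    def test_major_axis_angle(self, cavity_e06):
        t1, t2 = self.make_pair([[1.0, 0.0]] * 3)
        ss = cd.separation_series(t1, t2, cavity_e06)
        assert np.allclose(ss.theta, np.pi / 2)

    def test_minor_axis_angle(self, cavity_e06):
        t1, t2 = self.make_pair([[0.0, 1.0]] * 3)
        ss = cd.separation_series(t1, t2, cavity_e06)
        assert np.allclose(ss.theta, 0.0)

    def test_swap_symmetry(self, cavity_e06):
        t1, t2 = self.make_pair([[0.7, 0.3]] * 3)
        a = cd.separation_series(t1, t2, cavity_e06)
        b = cd.separation_series(t2, t1, cavity_e06)
        np.testing.assert_allclose(a.theta, b.theta)
        np.testing.assert_allclose(a.normalized_projection,
                                   -b.normalized_projection)

    def test_time_base_mismatch(self, cavity_e06):
        t1 = Trajectory(np.zeros((3, 2)), 0.1)
        t2 = Trajectory(np.zeros((4, 2)), 0.1)
        with pytest.raises(DataError):
            cd.separation_series(t1, t2, cavity_e06)


class TestOrderParameter:
    def test_isotropic_is_zero(self):
        rng = np.random.default_rng(0)
        s = cd.order_parameter(rng.uniform(0, np.pi, 100_000))
        assert abs(s) < 0.01

    def test_polar_alignment_is_one(self):
        assert cd.order_parameter(np.full(10, np.pi / 2)) == pytest.approx(1.0)

    def test_mixed_cancellation(self):
        assert cd.order_parameter([0.0, np.pi / 2]) == pytest.approx(0.0)

    def test_minor_convention_is_negated(self):
        th = np.random.default_rng(1).uniform(0, np.pi, 1000)
        s_major = cd.order_parameter(th, convention="major")
        s_minor = cd.order_parameter(th, convention="minor")
        assert s_major == pytest.approx(-s_minor, abs=1e-12)

    @given(st.lists(st.floats(0, np.pi - 1e-9), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_bounded(self, thetas):
        assert -1.0 - 1e-9 <= cd.order_parameter(thetas) <= 1.0 + 1e-9


# ---------------------------------------------------------------------------
# swap detection and dwell fitting
# ---------------------------------------------------------------------------

class TestDetectSwaps:
    def test_clean_square_wave(self):
        dt = 0.1
        period_frames = 200  # 10 s per state
        n_cycles = 6
        proj = np.concatenate([
            np.full(period_frames // 2, s)
            for _ in range(n_cycles) for s in (1.0, -1.0)])
        times = dt * np.arange(len(proj))
        stats, swaps = cd.detect_swaps(make_series(times, proj))
        assert swaps == 2 * n_cycles - 1
        np.testing.assert_allclose(stats.dwell_samples, 10.0)

    def test_failed_attempt_not_counted(self):
        dt = 0.1
        half = np.full(100, 1.0)
        spike = half.copy()
        spike[50] = -0.4  # crosses the opposite exit band, not the enter band
        proj = np.concatenate([half, -half, spike, -half, half])
        times = dt * np.arange(len(proj))
        clean = np.concatenate([half, -half, half, -half, half])
        s_spike, n_spike = cd.detect_swaps(make_series(times, proj))
        s_clean, n_clean = cd.detect_swaps(make_series(times, clean))
        assert n_spike == n_clean
        assert s_spike.extra["n_failed_attempts"] >= 1

    def test_constant_series(self):
        times = 0.1 * np.arange(100)
        stats, swaps = cd.detect_swaps(make_series(times, np.ones(100)))
        assert swaps == 0
        assert stats.n_events == 0

    def test_threshold_validation(self):
        times = 0.1 * np.arange(10)
        with pytest.raises(ConfigurationError):
            cd.detect_swaps(make_series(times, np.ones(10)),
                            enter_threshold=0.2, exit_threshold=0.5)


class TestExponentialDwellFit:
    def test_recovers_tau(self):
        rng = np.random.default_rng(42)
        samples = rng.exponential(10.0, 500)
        tau = cd.fit_exponential_dwell(DwellTimeStats(samples, 0))
        assert 9.0 <= tau <= 11.0

    def test_unit_rescaling(self):
        rng = np.random.default_rng(43)
        samples = rng.exponential(10.0, 200)
        tau_s = cd.fit_exponential_dwell(DwellTimeStats(samples, 0))
        tau_ms = cd.fit_exponential_dwell(DwellTimeStats(samples * 1000, 0))
        assert tau_ms == pytest.approx(1000 * tau_s, rel=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(FitError):
            # identical dwells: the survival curve has no usable decay
            cd.fit_exponential_dwell(DwellTimeStats(np.full(50, 5.0), 0))

    def test_near_degenerate_flagged_poor(self):
        stats = DwellTimeStats(np.full(50, 5.0) + np.linspace(0, 0.01, 50), 0)
        cd.fit_exponential_dwell(stats)
        assert stats.extra["poor_fit"]
        assert "r_squared" in stats.extra

    def test_too_few_events(self):
        with pytest.raises(FitError):
            cd.fit_exponential_dwell(DwellTimeStats(np.array([1.0, 2.0]), 0))


class TestPoleDwellTimes:
    def test_deterministic_oscillation(self):
        # 5 frames at +l, 5 at -l, repeated: all interior dwells 5 frames
        l = 1.0
        block = np.concatenate([np.full(5, l), np.full(5, -l)])
        x = np.tile(block, 6)
        traj = Trajectory(np.column_stack([x, np.zeros_like(x)]), 0.1)
        stats = cd.pole_dwell_times(traj, l=l)
        np.testing.assert_allclose(stats.dwell_samples, 0.5)
        assert stats.censored_first == pytest.approx(0.5)

    def test_confined_center_no_events(self):
        x = 0.1 * np.sin(np.linspace(0, 10, 100))
        traj = Trajectory(np.column_stack([x, np.zeros_like(x)]), 0.1)
        stats = cd.pole_dwell_times(traj, l=1.0)
        assert stats.n_events == 0

    def test_cross_pole_run_split_at_sign_change(self):
        l = 1.0
        x = np.concatenate([np.zeros(3), np.full(4, l), np.full(4, -l),
                            np.zeros(3)])
        traj = Trajectory(np.column_stack([x, np.zeros_like(x)]), 1.0)
        stats = cd.pole_dwell_times(traj, l=l)
        np.testing.assert_allclose(np.sort(stats.dwell_samples), [4.0, 4.0])


class TestDoubleExponentialFit:
    def test_recovers_mixture(self):
        rng = np.random.default_rng(7)
        samples = np.concatenate([rng.exponential(10.0, 1000),
                                  rng.exponential(1.0, 1000)])
        stats = DwellTimeStats(samples, 0)
        tau_long, tau_short, w = cd.fit_double_exponential(stats)
        assert tau_long == pytest.approx(10.0, rel=0.15)
        assert tau_short == pytest.approx(1.0, rel=0.15)
        assert w == pytest.approx(0.5, abs=0.1)

    def test_nested_single_exponential(self):
        rng = np.random.default_rng(8)
        samples = rng.exponential(5.0, 1000)
        stats = DwellTimeStats(samples, 0)
        tau_long, tau_short, w = cd.fit_double_exponential(stats)
        tau_single = cd.fit_exponential_dwell(stats)
        # dominant component must agree with the single-exponential fit
        tau_eff = tau_long if w >= 0.5 else tau_short
        assert tau_eff == pytest.approx(tau_single, rel=0.1)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        samples = np.concatenate([rng.exponential(10.0, 500),
                                  rng.exponential(1.0, 500)])
        t1 = cd.fit_double_exponential(DwellTimeStats(samples, 0))
        t2 = cd.fit_double_exponential(DwellTimeStats(samples * 60.0, 0))
        assert t2[0] == pytest.approx(60 * t1[0], rel=1e-6)
        assert t2[1] == pytest.approx(60 * t1[1], rel=1e-6)

    def test_too_few_events(self):
        with pytest.raises(FitError):
            cd.fit_double_exponential(DwellTimeStats(np.ones(5), 0))


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

class TestMSD:
    def test_ballistic_closed_form(self):
        v, dt = 0.3, 0.1
        t = dt * np.arange(100)
        traj = Trajectory(np.column_stack([v * t, np.zeros_like(t)]), dt)
        m = cd.msd_per_axis(traj, 2.0)
        np.testing.assert_allclose(m.msd_parallel, (v * m.lags) ** 2, rtol=1e-12)
        np.testing.assert_allclose(m.msd_perpendicular, 0.0, atol=1e-30)

    def test_static_zero(self):
        traj = Trajectory(np.tile([[0.4, 0.2]], (50, 1)), 0.1)
        m = cd.msd_per_axis(traj, 1.0)
        assert np.all(m.msd_parallel == 0.0)
        assert np.all(m.msd_perpendicular == 0.0)

    def test_exact_power_law_exponent(self):
        lags = 0.01 * np.arange(1, 80)
        m = MSDResult(lags=lags, msd_parallel=2.0 * lags**0.8,
                      msd_perpendicular=0.5 * lags**0.8)
        a_par, a_perp = cd.fit_msd_exponent(m, (0.0, 1.0))
        assert a_par == pytest.approx(0.8, abs=1e-9)
        assert a_perp == pytest.approx(0.8, abs=1e-9)

    def test_window_needs_enough_lags(self):
        lags = np.array([0.5, 2.0, 3.0, 4.0])
        m = MSDResult(lags=lags, msd_parallel=lags, msd_perpendicular=lags)
        with pytest.raises(FitError):
            cd.fit_msd_exponent(m, (0.0, 1.0))


# ---------------------------------------------------------------------------
# density profiles / crowding
# ---------------------------------------------------------------------------

class TestContourProfile:
    def test_uniform_circle_flat(self, circle):
        grid = make_grid(circle, 0.02)
        grid.values[grid.mask] = 1.0
        p = grid.normalized()
        prof = cd.contour_profile(p, circle, mode="radial", n_bins=20)
        inner = prof.density[:18]  # boundary bins feel partial-cell effects
        assert np.nanstd(inner) / np.nanmean(inner) < 0.05

    def test_annular_field_peaks_at_ring(self, circle):
        grid = make_grid(circle, 0.02)
        X, Y = grid.cell_centers()
        r = np.sqrt(X**2 + Y**2)
        grid.values[:] = np.exp(-((r - 0.6) ** 2) / (2 * 0.05**2))
        grid.values[~grid.mask] = 0.0
        prof = cd.contour_profile(grid.normalized(), circle, "radial", 25)
        peak = prof.bin_centers[np.nanargmax(prof.density)]
        assert peak == pytest.approx(0.6, abs=0.05)

    def test_elliptical_equals_radial_on_circle(self, circle, potential_e06):
        grid = make_grid(circle, 0.025)
        X, Y = grid.cell_centers()
        grid.values[:] = np.exp(-(X**2 + Y**2))
        grid.values[~grid.mask] = 0.0
        p = grid.normalized()
        a = cd.contour_profile(p, circle, "radial", 20)
        b = cd.contour_profile(p, circle, "elliptical", 20)
        np.testing.assert_allclose(a.density, b.density, rtol=1e-12)


class TestDistributionEdge:
    def gaussian_profile(self, center, width, n=100):
        x = np.linspace(0, 1, n)
        from cavity_demix.trajectory_analysis import RadialProfile
        return RadialProfile(bin_centers=x,
                             density=np.exp(-((x - center) ** 2) / (2 * width**2)),
                             mode="radial", physical_scale=1.0)

    def test_gaussian_ring_edge(self):
        prof = self.gaussian_profile(0.5, 0.1)
        # density = max/e at center + width*sqrt(2)... no: exp(-w^2/2w^2)?
        # at x = c + w*sqrt(2): exp(-1) of max
        edge = cd.distribution_edge(prof)
        assert edge == pytest.approx(0.5 + 0.1 * np.sqrt(2), abs=0.01)

    def test_monotone_profile_interpolated(self):
        x = np.linspace(0, 1, 20)
        from cavity_demix.trajectory_analysis import RadialProfile
        prof = RadialProfile(x, np.exp(-x / 0.3), "radial", 1.0)
        edge = cd.distribution_edge(prof)
        assert edge == pytest.approx(0.3, abs=0.5 / 19)

    def test_flat_profile_flagged(self):
        from cavity_demix.trajectory_analysis import RadialProfile
        prof = RadialProfile(np.linspace(0, 1, 10), np.ones(10), "radial", 1.0)
        assert cd.distribution_edge(prof) == 1.0
        assert prof.flags["edge_not_reached"]


class TestEdgeShift:
    def test_identical_profiles(self):
        from cavity_demix.trajectory_analysis import RadialProfile
        x = np.linspace(0, 1, 50)
        d = np.exp(-((x - 0.5) ** 2) / 0.02)
        a = RadialProfile(x, d, "radial", 1.0)
        b = RadialProfile(x, d.copy(), "radial", 1.0)
        assert cd.edge_shift(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_one_bin_shift(self):
        from cavity_demix.trajectory_analysis import RadialProfile
        x = np.linspace(0, 1, 50)
        d = np.exp(-((x - 0.5) ** 2) / 0.02)
        shifted = np.roll(d, -1)  # one bin inward
        a = RadialProfile(x, d, "radial", 2.0)
        b = RadialProfile(x, shifted, "radial", 2.0)
        bin_um = (x[1] - x[0]) * 2.0
        assert cd.edge_shift(a, b) == pytest.approx(bin_um, rel=0.2)
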