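import numpy as np
import pytest

from foragescale.fpt import (
    FPTProfile,
    RadiusGrid,
    compute_fpt,
    population_peak,
    variance_log_fpt,
)
from foragescale.synthetic import ForagerConfig, simulate_forager

from conftest import make_track, random_walk_track


def fpt_oracle(track, i, radii, dt_sample=1.0):
    """Independent FPT by dense 1-second resampling of the piecewise-linear path."""
    times = np.arange(track.t[0], track.t[-1] + dt_sample / 2, dt_sample)
    px = np.interp(times, track.t, track.x)
    py = np.interp(times, track.t, track.y)
    d = np.hypot(px - track.x[i], py - track.y[i])
    out = []
    for r in radii:
        outside = d >= r
        after = np.flatnonzero(outside & (times >= track.t[i]))
        before = np.flatnonzero(outside & (times <= track.t[i]))
        if after.size == 0 or before.size == 0:
            out.append(np.nan)
        else:
            out.append(times[after[0]] - times[before[-1]])
    return np.asarray(out)


class TestComputeFPT:
    def test_straight_line_constant_speed_gives_2r_over_v(self):
        v = 10.0  # m/s
        dt = 60.0
        xy = np.column_stack([v * dt * np.arange(41), np.zeros(41)])
        track = make_track(xy, dt=dt)
        grid = RadiusGrid(100, 2000, 100)
        prof = compute_fpt(track, grid)
        # interior fixes far from both ends have exact FPT = 2 r / v
        for i in range(5, 36):
            defined = np.isfinite(prof.fpt[i])
            assert np.allclose(prof.fpt[i][defined], 2 * grid.radii[defined] / v)

    def test_undefined_when_path_never_leaves_circle(self):
        xy = np.array([[0, 0], [10, 0], [0, 10], [-10, 0], [0, -10]], float)
        track = make_track(xy)
        prof = compute_fpt(track, RadiusGrid(100, 200, 100))
        assert np.all(np.isnan(prof.fpt))

    def test_matches_dense_resampling_oracle(self):
        grid = RadiusGrid(50, 500, 150)
        for seed in range(50):
            rng = np.random.default_rng(seed)
            track = random_walk_track(rng, n=30, step=80.0, dt=120.0)
            prof = compute_fpt(track, grid)
            for i in [0, 7, 15, 29]:
                expected = fpt_oracle(track, i, grid.radii)
                got = prof.fpt[i]
                assert np.array_equal(np.isnan(got), np.isnan(expected)), (seed, i)
                ok = np.isfinite(expected)
                assert np.allclose(got[ok], expected[ok], atol=2.0), (seed, i)

    def test_monotone_in_radius(self, rng):
        track = random_walk_track(rng, n=40, step=100.0)
        fpt = compute_fpt(track, RadiusGrid(50, 1000, 50)).fpt
        diffs = np.diff(fpt, axis=1)
        assert np.all(diffs[np.isfinite(diffs)] >= 0)

    def test_rigid_motion_invariance(self, rng):
        track = random_walk_track(rng, n=25, step=100.0)
        grid = RadiusGrid(50, 600, 110)
        base = compute_fpt(track, grid).fpt
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = make_track(track.xy() @ rot.T + [5000.0, -3000.0], dt=60.0)
        assert np.allclose(compute_fpt(moved, grid).fpt, base, equal_nan=True, atol=1e-6)

    def test_time_reversal_symmetry(self, rng):
        track = random_walk_track(rng, n=25, step=100.0)
        grid = RadiusGrid(50, 600, 110)
        fwd = compute_fpt(track, grid).fpt
        rev = make_track(track.xy()[::-1], dt=60.0)
        assert np.allclose(compute_fpt(rev, grid).fpt[::-1], fwd, equal_nan=True, atol=1e-9)

    def test_unprojected_track_rejected(self):
        import pandas as pd

        from foragescale.telemetry import Track

        track = Track(
            "b1",
            np.array([0.0, 60.0]),
            pd.Timestamp("2020-01-01", tz="UTC"),
            lon=np.array([18.0, 18.1]),
            lat=np.array([-34.0, -34.1]),
        )
        with pytest.raises(ValueError):
            compute_fpt(track, RadiusGrid(100, 200, 100))


class TestVarianceLogFPT:
    def test_constant_speed_line_has_zero_variance(self):
        v, dt = 10.0, 60.0
        xy = np.column_stack([v * dt * np.arange(61), np.zeros(61)])
        prof = variance_log_fpt(compute_fpt(make_track(xy, dt=dt), RadiusGrid(100, 1000, 100)))
        defined = np.isfinite(prof.var_log_fpt)
        assert defined.any()
        assert np.allclose(prof.var_log_fpt[defined], 0.0, atol=1e-12)

    def test_hand_arithmetic_variance(self):
        # ln of {e, e, e^2} = {1, 1, 2}: sample variance 1/3
        prof = FPTProfile(
            individual_id="x",
            radii=RadiusGrid(100, 100, 80),
            fpt=np.array([[np.e], [np.e], [np.e**2]]),
        )
        variance_log_fpt(prof)
        assert prof.var_log_fpt[0] == pytest.approx(1.0 / 3.0)

    def test_single_defined_value_gives_nan(self):
        prof = FPTProfile(
            individual_id="x",
            radii=RadiusGrid(100, 180, 80),
            fpt=np.array([[np.e, np.nan], [np.nan, np.nan]]),
        )
        variance_log_fpt(prof)
        assert np.isnan(prof.var_log_fpt).all()

    def test_two_mode_forager_has_interior_variance_peak(self):
        track, _ = simulate_forager(ForagerConfig(patch_radius=500.0, seed=7))
        grid = RadiusGrid(100, 5000, 80)
        prof = variance_log_fpt(compute_fpt(track, grid))
        rr = grid.radii
        assert rr[0] < prof.r_max_individual < rr[-1]


class TestPopulationPeak:
    def _profile(self, curve):
        rr = RadiusGrid(100, 100 + 80 * (len(curve) - 1), 80)
        p = FPTProfile("x", rr, fpt=np.empty((0, len(curve))))
        p.var_log_fpt = np.asarray(curve, float)
        p.r_max_individual = float(rr.radii[int(np.nanargmax(curve))])
        return p

    def test_single_profile_recovers_individual_peak(self):
        p = self._profile([0.1, 0.5, 0.2])
        scale = population_peak([p])
        assert scale.r_pop == p.r_max_individual

    def test_shared_peak_is_population_peak(self):
        a = self._profile([0.1, 0.6, 0.2])
        b = self._profile([0.2, 0.9, 0.1])
        assert population_peak([a, b]).r_pop == 180.0

    def test_tie_breaks_toward_smaller_radius(self):
        p = self._profile([0.5, 0.2, 0.5])
        assert population_peak([p]).r_pop == 100.0

    def test_nan_radii_excluded_per_radius(self):
        a = self._profile([0.1, np.nan, 0.2])
        b = self._profile([0.2, 5.0, 0.1])
        scale = population_peak([a, b])
        assert scale.var_fpt_mean[1] == pytest.approx(5.0)  # only b defined there
        assert scale.r_pop == 180.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            population_peak([])

    def test_mismatched_grids_rejected(self):
        a = self._profile([0.1, 0.2])
        b = FPTProfile("y", RadiusGrid(50, 130, 80), fpt=np.empty((0, 2)))
        b.var_log_fpt = np.array([0.1, 0.2])
        with pytest.raises(ValueError):
            population_peak([a, b])
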