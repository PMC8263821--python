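import math

import numpy as np
import pytest

from bcrwalk.core import BCRParams, Trajectory
from bcrwalk.movement_stats import (
    StatisticProfile,
    _disk_entries,
    _relative_entries,
    compare,
    compute_profile,
    default_configuration_mesh,
    dilation_profile,
    fluctuation_study,
    home_range_profile,
    mobile_transect_profile,
    sensitivity_sweep,
    still_transect_profile,
    turning_angle_profile,
    DEFAULT_SIGHTS,
    DEFAULT_SPEED_MULTIPLIERS,
)
from bcrwalk import simulator
from conftest import DEER5


def track(points, step_duration=10.0):
    return Trajectory.from_positions(points, step_duration)


class TestTurningAngleProfile:
    def test_straight_path_all_mass_at_zero(self):
        t = track([(50 * i, 0.0) for i in range(5)])
        prof = turning_angle_profile(t, d_min=10.0, n_bins=36)
        centers = np.asarray(prof.labels)
        peak = int(prof.values.argmax())
        assert prof.values[peak] == pytest.approx(1.0)
        assert abs(centers[peak]) <= math.pi / 36 + 1e-9  # the bin touching zero
        assert prof.values.sum() == pytest.approx(1.0)

    def test_short_leg_excluded(self):
        # middle leg of 5 m < d_min removes both adjacent triples
        t = track([(0, 0), (50, 0), (55, 0), (105, 0), (155, 0)])
        prof = turning_angle_profile(t, d_min=10.0, n_bins=4)
        # only the triple (55,105,155) survives
        assert prof.values.sum() == pytest.approx(1.0)
        t_all = track([(0, 0), (50, 0), (100, 0), (150, 0), (200, 0)])
        assert turning_angle_profile(t_all, d_min=10.0, n_bins=4).values.sum() == 1.0

    def test_diffusion_is_flat(self, diffusion_track):
        prof = turning_angle_profile(diffusion_track, d_min=0.0, n_bins=36)
        assert prof.values.max() / prof.values.min() < 1.5

    def test_no_eligible_triples_raises(self):
        t = track([(0, 0), (1, 0), (2, 0)])
        with pytest.raises(ValueError):
            turning_angle_profile(t, d_min=10.0)


class TestHomeRangeProfile:
    def test_areas_non_increasing_in_level(self, deer5_track):
        prof = home_range_profile(deer5_track)
        assert (np.diff(prof.values) <= 0).all()  # levels are decreasing

    def test_gaussian_isopleth_matches_analytic(self, rng):
        sigma = 50.0
        pts = rng.normal(0.0, sigma, (10_000, 2))
        t = Trajectory.from_positions(pts)
        prof = home_range_profile(t, levels=(95,))
        analytic = math.pi * sigma**2 * 5.991464547107979  # chi2(2).ppf(0.95)
        assert prof.values[0] == pytest.approx(analytic, rel=0.15)

    def test_quadratic_scaling(self, rng):
        pts = rng.normal(0.0, 30.0, (2_000, 2))
        t1 = Trajectory.from_positions(pts)
        t2 = Trajectory.from_positions(pts * 3.0)
        a1 = home_range_profile(t1, levels=(90, 50)).values
        a2 = home_range_profile(t2, levels=(90, 50)).values
        assert a2 == pytest.approx(9.0 * a1, rel=0.02)

    def test_degenerate_fixes_raise(self):
        t = track([(1.0, 1.0)] * 100)
        with pytest.raises(ValueError):
            home_range_profile(t)


class TestDilationProfile:
    def test_single_point_disk_area(self):
        t = Trajectory(np.array([[0.0, 0.0]]), np.array([0.0]))
        radii = (10, 20, 50)
        prof = dilation_profile(t, radii=radii)
        for r, area in zip(radii, prof.values):
            assert area == pytest.approx(math.pi * r**2, rel=0.05)

    def test_segment_stadium_area(self):
        t = track([(0, 0), (200, 0)])
        prof = dilation_profile(t, radii=(10, 25, 60))
        for r, area in zip((10, 25, 60), prof.values):
            assert area == pytest.approx(2 * 200 * r + math.pi * r**2, rel=0.05)

    def test_strictly_increasing_in_radius(self, deer5_track):
        sub = Trajectory(deer5_track.points[:300], deer5_track.times[:300])
        prof = dilation_profile(sub, radii=tuple(range(5, 55, 5)))
        assert (np.diff(prof.values) > 0).all()

    def test_pixel_size_changes_scale_not_area(self):
        t = track([(0, 0), (150, 0)])
        a1 = dilation_profile(t, radii=(30,), pixel_size=1.0).values[0]
        a2 = dilation_profile(t, radii=(30,), pixel_size=2.0).values[0]
        assert a2 == pytest.approx(a1, rel=0.05)


class TestStillTransects:
    def test_single_pass_counts_once(self):
        pts = np.array([[-500.0, 0.0], [500.0, 0.0]])
        assert _disk_entries(pts, (0.0, 0.0), 200.0) == 1

    def test_enter_leave_enter_counts_twice(self):
        pts = np.array([[-500.0, 0.0], [0.0, 0.0], [-500.0, 0.0], [0.0, 0.0]])
        assert _disk_entries(pts, (0.0, 0.0), 200.0) == 2

    def test_pass_through_between_samples_detected(self):
        # both endpoints outside the disk, chord dips inside
        pts = np.array([[-500.0, 50.0], [500.0, 50.0]])
        assert _disk_entries(pts, (0.0, 0.0), 200.0) == 1

    def test_start_inside_counts(self):
        pts = np.array([[0.0, 0.0], [500.0, 0.0]])
        assert _disk_entries(pts, (0.0, 0.0), 200.0) == 1

    def test_miss_counts_zero(self):
        pts = np.array([[-500.0, 300.0], [500.0, 300.0]])
        assert _disk_entries(pts, (0.0, 0.0), 200.0) == 0

    def test_profile_sorted_and_normalised(self, deer5_track):
        sub = Trajectory(deer5_track.points[:2000], deer5_track.times[:2000])
        prof = still_transect_profile(sub, sight=200.0, n_transects=50, placement_seed=1)
        assert (np.diff(prof.values) <= 0).all()
        assert prof.values.sum() == pytest.approx(1.0)
        raw = still_transect_profile(
            sub, sight=200.0, n_transects=50, placement_seed=1, relative=False
        )
        assert np.allclose(raw.values, np.round(raw.values))

    def test_placement_seed_reproducible(self, deer5_track):
        sub = Trajectory(deer5_track.points[:500], deer5_track.times[:500])
        a = still_transect_profile(sub, placement_seed=3)
        b = still_transect_profile(sub, placement_seed=3)
        assert np.array_equal(a.values, b.values)

    def test_translation_invariance_with_translated_centers(self):
        pts = np.array([[-500.0, 0.0], [500.0, 0.0], [500.0, 500.0]])
        t1 = track(pts)
        t2 = track(pts + [1000.0, -2000.0])
        centers = np.array([[0.0, 0.0], [300.0, 300.0]])
        a = still_transect_profile(t1, centers=centers, relative=False)
        b = still_transect_profile(t2, centers=centers + [1000.0, -2000.0], relative=False)
        assert np.array_equal(a.values, b.values)


class TestMobileTransects:
    def test_stationary_animal_at_origin(self):
        # animal never moves: speed 0, transects never move either; the 16
        # linear transects all sit on the animal, the 2 rotational ones sit
        # 500 m away
        t = track([(0.0, 0.0)] * 20)
        prof = mobile_transect_profile(t, sights=(50, 500), speed_multipliers=(1.0,))
        vals = dict(zip(prof.labels, prof.values))
        assert vals[("linear", 50, 1.0)] == 16
        assert vals[("rotational", 50, 1.0)] == 0
        assert vals[("rotational", 500, 1.0)] == 2

    def test_comoving_transect_counts_once(self):
        # relative position identically zero: a single initial entry
        rel = np.zeros((100, 2))
        assert _relative_entries(rel, 50.0, np.zeros(99, dtype=bool)) == 1

    def test_default_sights_and_speeds(self):
        assert DEFAULT_SIGHTS == (50, 100, 200, 400, 500, 1000)
        assert DEFAULT_SPEED_MULTIPLIERS == (0.25, 0.5, 1.0, 2.0)
        t = track([(0.0, 0.0), (100.0, 0.0), (0.0, 100.0)])
        prof = mobile_transect_profile(t)
        assert len(prof.values) == 2 * 6 * 4

    def test_zero_duration_raises(self):
        t = Trajectory(np.zeros((3, 2)), np.zeros(3))
        with pytest.raises(ValueError):
            mobile_transect_profile(t)


class TestCompare:
    def test_self_comparison(self):
        p = StatisticProfile("turning_angles", np.array([0.2, 0.8]), ("a", "b"))
        pair = compare(p, [p])
        assert pair.e1 == 0.0
        assert pair.e2 == 1.0

    def test_hand_arithmetic(self):
        ref = StatisticProfile("home_range", np.array([2.0]), ("x",))
        sims = [
            StatisticProfile("home_range", np.array([1.0]), ("x",)),
            StatisticProfile("home_range", np.array([3.0]), ("x",)),
        ]
        pair = compare(ref, sims)
        assert pair.e1 == 2.0
        assert pair.e2 == 1.0

    def test_zero_reference_component_skipped(self):
        ref = StatisticProfile("dilation", np.array([0.0, 2.0]), (1, 2))
        sim = StatisticProfile("dilation", np.array([5.0, 2.0]), (1, 2))
        with pytest.warns(UserWarning, match="zero-reference"):
            pair = compare(ref, sim)
        assert pair.e1 == 5.0
        assert pair.e2 == 1.0
        assert pair.skipped_components == 1

    def test_incomparable_profiles_raise(self):
        a = StatisticProfile("dilation", np.array([1.0]), (1,))
        b = StatisticProfile("home_range", np.array([1.0]), (1,))
        with pytest.raises(ValueError):
            compare(a, b)

    def test_empty_simulation_list_raises(self):
        a = StatisticProfile("dilation", np.array([1.0]), (1,))
        with pytest.raises(ValueError):
            compare(a, [])


class TestFluctuationStudy:
    KW = {
        "turning_angles": {"d_min": 10.0},
        "still_transects": {"n_transects": 20, "placement_seed": 0},
    }

    def test_minimal_run_finite(self):
        tab = fluctuation_study(
            DEER5, [500, 1000], replicates=2, rng_seed=1,
            statistics=("turning_angles", "still_transects"), stat_kwargs=self.KW,
        )
        assert np.isfinite(tab.variance).all()
        assert set(tab.n_s) == {500, 1000}

    def test_seed_determinism(self):
        kw = dict(
            n_s_grid=[400], replicates=3, rng_seed=9,
            statistics=("turning_angles",), stat_kwargs=self.KW,
        )
        a = fluctuation_study(DEER5, **kw)
        b = fluctuation_study(DEER5, **kw)
        assert a.equals(b)

    def test_replicates_validation(self):
        with pytest.raises(ValueError):
            fluctuation_study(DEER5, [100], replicates=1)


class TestSensitivitySweep:
    def test_mesh_covers_bounds_with_151_configs(self):
        configs = default_configuration_mesh(DEER5)
        assert len(configs) == 151
        assert max(c.p_i for c in configs) == 3.0
        assert max(c.p_s for c in configs) == 5.0
        assert max(c.p_f for c in configs) == 3.0
        assert configs[0] == DEER5

    def test_single_config_matches_direct_compare(self):
        ref = simulator.simulate(DEER5, 2000, rng_seed=2)
        kw = {"turning_angles": {"d_min": 10.0}}
        tab = sensitivity_sweep(
            ref, [DEER5], n_sim=1, rng_seed=4,
            statistics=("turning_angles",), stat_kwargs=kw, n_steps=2000,
        )
        ref_prof = turning_angle_profile(ref, d_min=10.0)
        sim = simulator.simulate(DEER5, 2000, rng_seed=np.random.default_rng(4))
        sim_prof = turning_angle_profile(sim, d_min=10.0)
        expected_e1 = compare(ref_prof, sim_prof).e1
        assert tab.mean_abs_error.iloc[0] == pytest.approx(expected_e1)

    def test_empty_configs_raise(self):
        ref = simulator.simulate(DEER5, 100, rng_seed=0)
        with pytest.raises(ValueError):
            sensitivity_sweep(ref, [], n_sim=1)


class TestProfileInvariance:
    def test_translation_invariance(self, deer5_track):
        sub = Trajectory(deer5_track.points[:1500], deer5_track.times[:1500])
        moved = sub.with_points(sub.points + [5000.0, -3000.0])
        for name, kw, tol in [
            # binned angles may shift across a bin edge by float rounding
            ("turning_angles", {"d_min": 10.0}, {"abs": 0.005}),
            ("home_range", {"levels": (90, 50)}, {"rel": 1e-6}),
            ("dilation", {"radii": (20, 40)}, {"rel": 1e-6}),
        ]:
            a = compute_profile(name, sub, **kw)
            b = compute_profile(name, moved, **kw)
            assert a.values == pytest.approx(b.values, **tol), name
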