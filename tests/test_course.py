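import numpy as np
import pytest

from artdose import (
    GridSpec,
    Mask,
    RegressionParams,
    estimate_regression_rate,
    make_contraction_dvf,
    mask_volume,
    regression_factor,
    simulate_course,
    warp_mask,
)

GEOMETRIC = RegressionParams(
    weekly_profile=None, prestart_progression_prob=0.0, rate_sd=0.0
)


class TestRegressionFactor:
    def test_thirty_fractions_at_default_rate(self):
        # (0.989)^30 evaluated in extended precision
        assert regression_factor(0.011, 30) == pytest.approx(
            0.7176104393294988, abs=1e-12
        )

    def test_zero_fractions_and_zero_rate(self):
        assert regression_factor(0.011, 0) == 1.0
        assert regression_factor(0.0, 17) == 1.0

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            regression_factor(1.0, 5)
        with pytest.raises(ValueError):
            regression_factor(-0.1, 5)


class TestEstimateRegressionRate:
    def test_noiseless_geometric_series_recovered_exactly(self):
        vols = [200.0 * regression_factor(0.011, k) for k in range(31)]
        assert estimate_regression_rate(vols) == pytest.approx(0.011, abs=1e-6)

    def test_constant_series_gives_zero(self):
        assert estimate_regression_rate([150.0] * 10) == pytest.approx(0.0)

    def test_mean_recovery_under_lognormal_noise(self):
        # 2% multiplicative noise, 30 fractions, 10 seeds
        est = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vols = np.array(
                [200.0 * regression_factor(0.011, k) for k in range(31)]
            ) * rng.lognormal(0.0, 0.02, size=31)
            est.append(estimate_regression_rate(vols))
        assert np.mean(est) == pytest.approx(0.011, abs=0.002)

    def test_invalid_series_rejected(self):
        with pytest.raises(ValueError):
            estimate_regression_rate([100.0, 90.0])
        with pytest.raises(ValueError):
            estimate_regression_rate([100.0, -1.0, 80.0])


def _minimal_structures_1mm(radius_mm=16.0):
    """Bare-bones structure set on a 1 mm grid for quantitative volume checks."""
    from artdose import StructureSet

    g = GridSpec.centered((64, 64, 64), (1.0, 1.0, 1.0))
    x, y, z = g.coords()
    gtv = Mask(g, x**2 + y**2 + z**2 <= radius_mm**2)
    body = Mask(g, np.ones(g.shape, bool))
    corner = np.zeros(g.shape, bool)
    corner[:4, :4, :4] = True
    small = Mask(g, corner)
    return StructureSet({
        "GTV": gtv, "body": body,
        "lung_left": small, "lung_right": small, "heart": small,
        "esophagus": small, "spinal_cord": small,
    })


class TestSimulateCourse:
    def test_same_seed_reproduces_course_exactly(self, small_phantom):
        kw = dict(reg=GEOMETRIC, setup_sd_mm=1.5,
                  prescription_total_gy=60.0, seed=7)
        a = simulate_course(small_phantom, **kw)
        b = simulate_course(small_phantom, **kw)
        for ra, rb in zip(a.fractions, b.fractions):
            assert np.array_equal(ra.structures["GTV"].values,
                                  rb.structures["GTV"].values)
            assert np.array_equal(ra.setup_shift_mm, rb.setup_shift_mm)
            assert np.array_equal(ra.dvf_to_planning.displacement,
                                  rb.dvf_to_planning.displacement)

    def test_prescription_sets_fraction_count(self, small_phantom):
        course = simulate_course(small_phantom, GEOMETRIC, 0.0, 66.0, seed=1)
        assert course.n_fractions == 33
        assert [r.index for r in course.fractions] == list(range(1, 34))

    def test_volumes_non_increasing_and_match_geometric_decay(self):
        planning = _minimal_structures_1mm()
        course = simulate_course(planning, GEOMETRIC, 0.0, 60.0, seed=3)
        vols = [mask_volume(r.structures["GTV"]) for r in course.fractions]
        assert all(b <= a for a, b in zip(vols, vols[1:]))
        v_plan = mask_volume(planning["GTV"])
        # 29 inter-fraction steps after the (growth-free) first fraction
        expected = regression_factor(0.011, 29)
        assert vols[-1] / v_plan == pytest.approx(expected, rel=0.03)

    def test_prestart_progression_grows_first_fraction_gtv(self):
        planning = _minimal_structures_1mm()
        reg = RegressionParams(weekly_profile=None, rate_sd=0.0,
                               prestart_progression_prob=1.0)
        course = simulate_course(planning, reg, 0.0, 60.0, seed=5)
        v1 = mask_volume(course.fractions[0].structures["GTV"])
        assert v1 > mask_volume(planning["GTV"])

    def test_weekly_profile_controls_residual_volume(self):
        planning = _minimal_structures_1mm()
        reg = RegressionParams(rate_sd=0.0, prestart_progression_prob=0.0)
        course = simulate_course(planning, reg, 0.0, 60.0, seed=2)
        v_plan = mask_volume(planning["GTV"])
        v_final = mask_volume(course.fractions[-1].structures["GTV"])
        # compounded weekly pattern reaches ≈0.65 after six weeks
        assert v_final / v_plan == pytest.approx(0.66, abs=0.05)

    def test_non_integer_fraction_number_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            simulate_course(small_phantom, GEOMETRIC, 0.0, 61.0, seed=1)


def _sphere_mask(grid, radius, center=(0.0, 0.0, 0.0)):
    x, y, z = grid.coords()
    return Mask(grid, (x - center[0]) ** 2 + (y - center[1]) ** 2
                + (z - center[2]) ** 2 <= radius**2)


class TestContractionDVF:
    def test_identical_masks_give_zero_field(self):
        g = GridSpec.centered((24, 24, 24), (2.0, 2.0, 2.0))
        m = _sphere_mask(g, 12.0)
        dvf = make_contraction_dvf(m, m)
        assert not dvf.displacement.any()

    def test_displacement_vanishes_at_centroid(self):
        g = GridSpec.centered((33, 33, 33), (1.5, 1.5, 1.5))
        plan = _sphere_mask(g, 15.0)
        frac = _sphere_mask(g, 12.0)
        dvf = make_contraction_dvf(plan, frac, support_mm=12.0)
        center = np.array(g.shape) // 2
        assert np.allclose(dvf.displacement[tuple(center)], 0.0, atol=1e-9)

    def test_points_inside_gtv_pull_toward_centroid(self):
        g = GridSpec.centered((33, 33, 33), (1.5, 1.5, 1.5))
        plan = _sphere_mask(g, 15.0)
        frac = _sphere_mask(g, 12.0)
        dvf = make_contraction_dvf(plan, frac, support_mm=12.0)
        x, _, _ = g.coords()
        inside = plan.values & (np.broadcast_to(x, g.shape) > 0)
        assert np.all(dvf.displacement[inside, 0] < 0)

    def test_warp_recovers_planning_gtv_with_high_dice(self):
        g = GridSpec.centered((56, 56, 56), (1.0, 1.0, 1.0))
        plan = _sphere_mask(g, 16.0)
        frac = _sphere_mask(g, 12.8)  # linear scale 0.8, volume ratio 0.512
        dvf = make_contraction_dvf(plan, frac, support_mm=10.0)
        warped = warp_mask(frac, dvf)
        inter = (warped & plan).voxel_count
        dice = 2 * inter / (warped.voxel_count + plan.voxel_count)
        assert dice >= 0.95

    def test_empty_fraction_gtv_rejected(self):
        g = GridSpec.centered((16, 16, 16), (2.0, 2.0, 2.0))
        plan = _sphere_mask(g, 10.0)
        with pytest.raises(ValueError):
            make_contraction_dvf(Mask(g, np.zeros(g.shape, bool)), plan)
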