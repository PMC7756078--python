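import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from artdose import (
    DEFAULT_RADIOBIO_PARAMS,
    DoseGrid,
    GridSpec,
    Mask,
    conformity_index,
    cumulative_dvh,
    dose_at_volume,
    eud_from_dvh,
    geud,
    homogeneity_index,
    ntcp,
    tcp,
    volume_at_dose,
)

from .oracles import (
    dose_at_volume_bruteforce,
    geud_bruteforce,
    volume_at_dose_bruteforce,
)

doses_strategy = st.lists(
    st.floats(min_value=0.01, max_value=80.0), min_size=1, max_size=60
)


class TestDoseAtVolume:
    def test_hottest_five_percent_of_ramp(self):
        assert dose_at_volume(np.arange(1.0, 101.0), 5.0) == 96.0

    def test_x_100_is_minimum_and_single_voxel_trivial(self):
        d = np.array([3.0, 7.0, 1.0])
        assert dose_at_volume(d, 100.0) == 1.0
        assert dose_at_volume(np.array([5.5]), 37.0) == 5.5

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dose_at_volume(np.array([1.0]), 0.0)
        with pytest.raises(ValueError):
            dose_at_volume(np.array([]), 50.0)

    @settings(deadline=None, max_examples=40)
    @given(doses=doses_strategy, x=st.floats(min_value=0.5, max_value=100.0))
    def test_matches_bruteforce_selection(self, doses, x):
        assert dose_at_volume(doses, x) == dose_at_volume_bruteforce(doses, x)


class TestVolumeAtDose:
    def test_boundary_voxels_count_as_covered(self):
        assert volume_at_dose([10.0, 15.0, 20.0, 25.0], 20.0) == 50.0

    def test_extremes(self):
        d = [5.0, 6.0]
        assert volume_at_dose(d, 0.0) == 100.0
        assert volume_at_dose(d, 7.0) == 0.0

    @settings(deadline=None, max_examples=40)
    @given(doses=doses_strategy, level=st.floats(min_value=0, max_value=90))
    def test_matches_bruteforce_count(self, doses, level):
        assert volume_at_dose(doses, level) == volume_at_dose_bruteforce(
            doses, level
        )

    @settings(deadline=None, max_examples=40)
    @given(doses=doses_strategy, x=st.floats(min_value=0.5, max_value=100.0))
    def test_galois_consistency_with_dose_at_volume(self, doses, x):
        assert volume_at_dose(doses, dose_at_volume(doses, x)) >= min(x, 100.0) - 1e-9


class TestConformityIndex:
    def _grid(self, n=6):
        return GridSpec((n, n, n), (1, 1, 1))

    def test_identical_masks_give_one(self):
        g = self._grid()
        v = np.zeros(g.shape, bool)
        v[1:4, 1:4, 1:4] = True
        dose = DoseGrid(g, np.where(v, 60.0, 0.0))
        assert conformity_index(Mask(g, v), dose, 57.0) == 1.0

    def test_disjoint_isodose_gives_zero(self):
        g = self._grid()
        ptv = np.zeros(g.shape, bool)
        ptv[0:2] = True
        dose_values = np.zeros(g.shape)
        dose_values[4:6] = 60.0
        assert conformity_index(Mask(g, ptv), DoseGrid(g, dose_values), 57.0) == 0.0

    def test_partial_overlap_value(self):
        # |PTV| = 100, |PIV| = 200, overlap 80 -> 80²/(100·200) = 0.32
        g = GridSpec((10, 10, 10), (1, 1, 1))
        ptv = np.zeros(g.shape, bool)
        ptv.ravel()[:100] = True
        dose_values = np.zeros(g.shape)
        dose_values.ravel()[20:220] = 60.0  # 200 hot voxels, 80 inside PTV
        ci = conformity_index(Mask(g, ptv), DoseGrid(g, dose_values), 57.0)
        assert ci == pytest.approx(0.32)

    def test_bounded_and_empty_ptv_rejected(self, rng):
        g = self._grid(8)
        ptv = rng.random(g.shape) < 0.3
        ptv[0, 0, 0] = True
        dose = DoseGrid(g, 70 * rng.random(g.shape))
        ci = conformity_index(Mask(g, ptv), dose, 40.0)
        assert 0.0 <= ci <= 1.0
        with pytest.raises(ValueError):
            conformity_index(Mask(g, np.zeros(g.shape, bool)), dose, 40.0)


class TestHomogeneityIndex:
    def test_uniform_dose_gives_one(self):
        assert homogeneity_index(np.full(50, 2.0)) == 1.0

    def test_ramp_and_small_set_examples(self):
        assert homogeneity_index(np.arange(1.0, 101.0)) == pytest.approx(96 / 6)
        assert homogeneity_index(np.array([2.0, 2.0, 2.2])) == pytest.approx(1.1)

    def test_zero_d95_rejected(self):
        with pytest.raises(ValueError):
            homogeneity_index(np.zeros(10))


class TestGeud:
    def test_exponent_one_is_mean(self, rng):
        d = 60 * rng.random(500)
        assert geud(d, 1.0) == pytest.approx(d.mean(), rel=1e-12)

    def test_frozen_power_mean_examples(self):
        assert geud([10.0, 20.0], 2.0) == pytest.approx(15.8113883, abs=1e-6)
        assert geud([60.0, 66.0], -10.0) == pytest.approx(62.2432470, abs=1e-6)

    @pytest.mark.parametrize("a", [-10.0, 1.0, 3.0, 19.0, 25.0])
    def test_uniform_dose_is_fixed_point(self, a):
        assert geud(np.full(37, 54.3), a) == pytest.approx(54.3, rel=1e-9)

    @settings(deadline=None, max_examples=40)
    @given(doses=doses_strategy,
           a=st.sampled_from([-10.0, -2.0, 1.0, 3.0, 19.0, 25.0]))
    def test_matches_extended_precision_oracle(self, doses, a):
        assert geud(doses, a) == pytest.approx(
            geud_bruteforce(doses, a), rel=1e-9
        )

    @settings(deadline=None, max_examples=40)
    @given(doses=st.lists(st.floats(min_value=0.5, max_value=70), min_size=2,
                          max_size=40))
    def test_monotone_in_exponent_and_bounded(self, doses):
        values = [geud(doses, a) for a in (-10, -1, 1, 3, 25)]
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))
        assert min(doses) - 1e-9 <= values[0] <= values[-1] + 1e-9
        assert values[-1] <= max(doses) + 1e-9

    def test_winsorized_lung_geud_stays_close_to_mean(self, rng):
        d = np.clip(rng.normal(18, 3, 2000), 0, None)
        d[:3] = 70.0  # isolated hot voxels
        clipped = geud(d, 1.0, clip=True)
        assert abs(clipped - d.mean()) < 0.2

    def test_cold_spot_with_negative_exponent_warns_and_returns_zero(self):
        d = np.concatenate([np.zeros(5), np.full(200, 60.0)])
        with pytest.warns(UserWarning, match="cold spot"):
            assert geud(d, -10.0) == 0.0

    def test_zero_exponent_rejected(self):
        with pytest.raises(ValueError):
            geud([1.0, 2.0], 0.0)

    def test_dvh_weighted_eud_reduces_to_power_mean(self):
        d = np.array([10.0, 20.0, 30.0, 40.0])
        v = np.full(4, 0.25)
        assert eud_from_dvh(d, v, 3.0) == pytest.approx(geud(d, 3.0), rel=1e-12)


class TestDoseResponse:
    @pytest.mark.parametrize("organ", ["heart", "spinal_cord", "esophagus", "lung"])
    def test_half_probability_at_td50(self, organ):
        p = DEFAULT_RADIOBIO_PARAMS[organ]
        assert ntcp(p.d50, p.d50, p.y50) == pytest.approx(0.5, rel=1e-12)

    def test_half_control_at_tcd50(self):
        p = DEFAULT_RADIOBIO_PARAMS["PTV"]
        assert tcp(p.d50, p.d50, p.y50) == pytest.approx(0.5, rel=1e-12)

    def test_frozen_lung_and_target_examples(self):
        assert ntcp(17.8, 24.5, 2.0) == pytest.approx(0.0720380, abs=1e-6)
        assert tcp(62.6, 51.97, 1.81) == pytest.approx(0.7936967, abs=1e-6)

    def test_zero_eud_limit_and_negative_rejected(self):
        assert ntcp(0.0, 24.5, 2.0) == 0.0
        with pytest.raises(ValueError):
            ntcp(-1.0, 24.5, 2.0)

    @settings(deadline=None, max_examples=30)
    @given(eud=st.floats(min_value=0.1, max_value=200.0))
    def test_probability_bounds_and_monotonicity(self, eud):
        p = ntcp(eud, 24.5, 2.0)
        assert 0.0 < p < 1.0
        assert ntcp(eud + 1.0, 24.5, 2.0) > p


class TestCumulativeDVH:
    def _dose_and_mask(self, rng, n=1000):
        g = GridSpec((10, 10, 10), (1, 1, 1))
        dose = DoseGrid(g, 65 * rng.random(g.shape))
        return dose, Mask(g, np.ones(g.shape, bool))

    def test_starts_at_100_percent(self, rng):
        dose, mask = self._dose_and_mask(rng)
        dvh = cumulative_dvh(dose, mask, 0.5)
        assert dvh.volume_pct[0] == 100.0

    def test_uniform_dose_step_curve(self):
        g = GridSpec((5, 5, 5), (1, 1, 1))
        dvh = cumulative_dvh(DoseGrid(g, np.full(g.shape, 10.0)),
                             Mask(g, np.ones(g.shape, bool)), 1.0)
        assert np.all(dvh.volume_pct[dvh.dose_gy <= 10.0] == 100.0)
        assert np.all(dvh.volume_pct[dvh.dose_gy > 10.0] == 0.0)

    def test_agrees_with_direct_counting_at_every_edge(self, rng):
        dose, mask = self._dose_and_mask(rng)
        dvh = cumulative_dvh(dose, mask, 2.0)
        d = dose.in_mask(mask)
        for edge, vol in zip(dvh.dose_gy, dvh.volume_pct):
            assert vol == volume_at_dose_bruteforce(d, edge)

    def test_empty_mask_rejected(self, rng):
        dose, _ = self._dose_and_mask(rng)
        empty = Mask(dose.grid, np.zeros(dose.grid.shape, bool))
        with pytest.raises(ValueError):
            cumulative_dvh(dose, empty)
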