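"""Planar simulator: resolution model, septal penetration, count statistics."""

import numpy as np
import pytest

from mibgcal import build_phantom
from mibgcal.quantify import auto_roi_phantom, compute_hmr
from mibgcal.simulate import (
    COLLIMATORS,
    AcquisitionSettings,
    CollimatorSpec,
    geometric_fwhm,
    penetration_fraction,
    simulate_planar,
    sweep_collimator_designs,
)
from mibgcal.window import EnergyWindow

from conftest import CALIBRATION_SETTINGS

MU159 = 2.3


def spec(d, t, L, **kw):
    return CollimatorSpec(f"d{d}t{t}L{L}", d, t, L, **kw)


class TestGeometricFwhm:
    def test_equals_hole_diameter_at_face(self):
        # L_eff = 40 when L = 40 + 2/mu159
        c = spec(2.0, 0.2, 40 + 2 / MU159)
        assert geometric_fwhm(c, 0.0) == pytest.approx(2.0)

    def test_doubles_at_effective_length(self):
        c = spec(2.0, 0.2, 40 + 2 / MU159)
        assert geometric_fwhm(c, 40.0) == pytest.approx(4.0)

    def test_hand_computed_value(self):
        # L_eff = 35 - 2/2.3 = 34.1304...; FWHM = 1.5*(L_eff+100)/L_eff
        c = spec(1.5, 0.2, 35.0)
        l_eff = 35.0 - 2.0 / 2.3
        assert geometric_fwhm(c, 100.0) == pytest.approx(1.5 * (l_eff + 100.0) / l_eff)

    def test_strictly_increasing_in_distance(self):
        c = COLLIMATORS["lehr"]
        values = [geometric_fwhm(c, z) for z in (0, 10, 50, 100, 180)]
        assert all(np.diff(values) > 0)


class TestPenetrationFraction:
    def test_thick_septa_absorb_everything(self):
        f = penetration_fraction(spec(1.0, 2.0, 80.0))
        assert f < 1e-4

    def test_no_collimation_limit(self):
        # L at its minimum and wide holes: w -> small, f -> b529*a/(b529*a+b159)
        f = penetration_fraction(spec(5.0, 0.05, 10.0), EnergyWindow(159, 7.5))
        cap = 0.0139 / (0.0139 + 0.833)
        assert f == pytest.approx(cap, rel=0.01)

    def test_lehr_leaks_more_than_megp(self):
        w = EnergyWindow(159, 10)
        assert penetration_fraction(COLLIMATORS["lehr"], w) > penetration_fraction(
            COLLIMATORS["megp"], w
        )

    @pytest.mark.parametrize("attr, direction", [("d", +1), ("t", -1), ("L", -1)])
    def test_monotone_in_geometry(self, attr, direction):
        base = dict(d=2.0, t=0.5, L=35.0)
        lo = penetration_fraction(spec(**base))
        base[attr] *= 1.5
        hi = penetration_fraction(spec(**base))
        assert np.sign(hi - lo) == direction

    def test_wider_window_accepts_more(self):
        c = COLLIMATORS["lmegp"]
        assert penetration_fraction(c, EnergyWindow(159, 10)) > penetration_fraction(
            c, EnergyWindow(159, 7.5)
        )


class TestSimulatePlanar:
    def test_zero_activity_gives_zero_image(self, anterior_map):
        dens = {k: 0.0 for k in anterior_map.densities}
        empty = build_phantom(CALIBRATION_SETTINGS.pixel_mm, "anterior", densities=dens)
        img = simulate_planar(empty, COLLIMATORS["lehr"], CALIBRATION_SETTINGS, noise=False)
        assert img.counts.sum() == 0

    def test_count_conservation_noise_off(self, anterior_map):
        """The expected image totals activity x duration x sensitivity
        within 0.1% regardless of blur and penetration (edge
        renormalization); the rounded integer image stays close."""
        from mibgcal.simulate import expected_image

        for key in ("lehr", "megp"):
            s = AcquisitionSettings(duration_s=300.0, distance_mm=90.0)
            expected, _ = expected_image(anterior_map, COLLIMATORS[key], s)
            assert expected.sum() == pytest.approx(1.0e6, rel=1e-3)
            img = simulate_planar(anterior_map, COLLIMATORS[key], s, noise=False)
            assert img.total == pytest.approx(1.0e6, rel=5e-3)

    def test_seed_determinism_bit_identical(self, anterior_map):
        s = AcquisitionSettings(seed=42)
        a = simulate_planar(anterior_map, COLLIMATORS["lmegp"], s)
        b = simulate_planar(anterior_map, COLLIMATORS["lmegp"], s)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_different_seeds_differ(self, anterior_map):
        a = simulate_planar(anterior_map, None, AcquisitionSettings(seed=1))
        b = simulate_planar(anterior_map, None, AcquisitionSettings(seed=2))
        assert (a.counts != b.counts).any()

    def test_ideal_system_reproduces_designated_ratio(self, ideal_anterior_image):
        rois = auto_roi_phantom(ideal_anterior_image, "anterior")
        assert compute_hmr(ideal_anterior_image, rois).hmr == pytest.approx(2.60, abs=0.01)

    def test_lehr_degrades_hmr_more_than_megp(self, anterior_map):
        def measured(coll):
            img = simulate_planar(anterior_map, coll, CALIBRATION_SETTINGS, noise=False)
            return compute_hmr(img, auto_roi_phantom(img, "anterior")).hmr

        assert measured(COLLIMATORS["lehr"]) < measured(COLLIMATORS["megp"])

    def test_counts_are_integral_non_negative(self, anterior_map):
        img = simulate_planar(anterior_map, COLLIMATORS["lehr"], AcquisitionSettings(seed=0))
        assert np.issubdtype(img.counts.dtype, np.integer)
        assert img.counts.min() >= 0

    def test_resamples_activity_to_matrix(self, anterior_map):
        s = AcquisitionSettings(matrix=128)
        img = simulate_planar(anterior_map, None, s, noise=False)
        assert img.shape == (128, 128)
        assert img.pixel_size_mm == pytest.approx(380 / 128)


class TestAcquisitionConditions:
    def test_window_75_gives_higher_hmr_for_every_collimator(self, anterior_map):
        for coll in COLLIMATORS.values():
            hmrs = {}
            for half in (7.5, 10.0):
                s = AcquisitionSettings(window=EnergyWindow(159, half), duration_s=3600.0)
                img = simulate_planar(anterior_map, coll, s, noise=False)
                hmrs[half] = compute_hmr(img, auto_roi_phantom(img, "anterior")).hmr
            assert hmrs[7.5] >= hmrs[10.0]

    def test_hmr_stable_over_camera_distance(self, anterior_map):
        """HMR varies < 5% between 10 and 180 mm camera distance."""
        for key in ("lehr", "lmegp"):
            values = []
            for z in (10, 30, 50, 70, 90, 180):
                s = AcquisitionSettings(distance_mm=float(z), duration_s=3600.0)
                img = simulate_planar(anterior_map, COLLIMATORS[key], s, noise=False)
                values.append(compute_hmr(img, auto_roi_phantom(img, "anterior")).hmr)
            assert (max(values) - min(values)) / min(values) < 0.05

    def test_longer_acquisition_reduces_hmr_spread(self, anterior_map):
        """Across seeds the mean HMR is stable while the SD shrinks with
        acquisition time (counting statistics)."""

        def sample(duration, seed):
            s = AcquisitionSettings(duration_s=duration, seed=seed)
            img = simulate_planar(anterior_map, COLLIMATORS["lmegp"], s)
            return compute_hmr(img, auto_roi_phantom(img, "anterior")).hmr

        short = np.array([sample(60.0, seed) for seed in range(30)])
        long = np.array([sample(600.0, seed) for seed in range(30)])
        assert long.std() < short.std()
        assert abs(long.mean() - short.mean()) < 3 * short.std() / np.sqrt(30)


class TestSweep:
    def test_single_point(self, anterior_map):
        grid = sweep_collimator_designs(anterior_map, [2], [0.5], [40], CALIBRATION_SETTINGS)
        assert len(grid) == 1

    def test_empty_grid_rejected(self, anterior_map):
        with pytest.raises(ValueError):
            sweep_collimator_designs(anterior_map, [], [0.5], [40], CALIBRATION_SETTINGS)

    def test_full_grid_monotone_and_ordered(self, anterior_map):
        """125-point sweep over the published design ranges: HMR is
        non-increasing in hole diameter, non-decreasing in septal
        thickness and collimator length, and maximal at (d min, t max,
        L max)."""
        settings = AcquisitionSettings(window=EnergyWindow(159, 7.5))
        ds, ts, Ls = [1, 2, 3, 4, 5], [0.10, 0.45, 0.80, 1.15, 1.50], [20, 30, 40, 50, 60]
        grid = sweep_collimator_designs(anterior_map, ds, ts, Ls, settings)
        assert len(grid) == 125
        # ordered by (L, t, d)
        assert grid[["L", "t", "d"]].apply(tuple, axis=1).is_monotonic_increasing
        piv = grid.set_index(["L", "t", "d"]).hmr
        for L in Ls:
            for t in ts:
                assert all(np.diff([piv[(L, t, d)] for d in ds]) <= 1e-12)
            for d in ds:
                assert all(np.diff([piv[(L, t, d)] for t in ts]) >= -1e-12)
        for t in ts:
            for d in ds:
                assert all(np.diff([piv[(L, t, d)] for L in Ls]) >= -1e-12)
        best = grid.loc[grid.hmr.idxmax()]
        assert (best.d, best.t, best.L) == (min(ds), max(ts), max(Ls))


class TestValidation:
    def test_collimator_bounds(self):
        with pytest.raises(ValueError):
            spec(0.2, 0.5, 40)
        with pytest.raises(ValueError):
            spec(2, 3.0, 40)
        with pytest.raises(ValueError):
            spec(2, 0.5, 100)

    def test_settings_bounds(self):
        with pytest.raises(ValueError):
            AcquisitionSettings(matrix=100)
        with pytest.raises(ValueError):
            AcquisitionSettings(duration_s=0)
        with pytest.raises(ValueError):
            AcquisitionSettings(distance_mm=-1)
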