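"""Extraction operations against hand arithmetic, brute-force block maxima,
kriging exactness, and the synthetic scene's construction oracle."""

import numpy as np
import pytest
from shapely.geometry import box

from uavtraits import (
    MaxPointSet,
    NoPlantError,
    PlotROI,
    Raster,
    block_maxima,
    compute_csm,
    compute_ndvi,
    compute_ngrdi,
    extract_plot_ph,
    krige_plot_height,
    plant_mask_from_ndvi,
    plant_mask_from_ngrdi,
    plot_cc,
    plot_mean_ndvi,
)
from uavtraits.kriging import fit_variogram, krige
from uavtraits.raster import GridMismatchError


def const_raster(value, shape=(4, 4), cell=10.0):
    return Raster(np.full(shape, value), cell)


class TestIndices:
    @pytest.mark.parametrize(
        "g, r, expected",
        [(0.2, 0.2, 0.0), (0.12, 0.06, 1.0 / 3.0), (0.10, 0.12, -1.0 / 11.0)],
    )
    def test_ngrdi_hand_arithmetic(self, g, r, expected):
        out = compute_ngrdi(const_raster(g), const_raster(r))
        assert np.allclose(out.values, expected, atol=1e-4)

    @pytest.mark.parametrize(
        "n, r, expected",
        [(0.3, 0.3, 0.0), (0.45, 0.06, 0.39 / 0.51), (0.14, 0.12, 0.02 / 0.26)],
    )
    def test_ndvi_hand_arithmetic(self, n, r, expected):
        out = compute_ndvi(const_raster(n), const_raster(r))
        assert np.allclose(out.values, expected, atol=1e-4)
        assert ((out.values >= -1) & (out.values <= 1)).all()

    def test_zero_sum_pixels_become_nodata(self):
        out = compute_ngrdi(const_raster(0.0), const_raster(0.0))
        assert np.isnan(out.values).all()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            compute_ndvi(const_raster(0.4, shape=(4, 4)), const_raster(0.1, shape=(5, 4)))
        with pytest.raises(GridMismatchError):
            compute_csm(const_raster(1.0, cell=10.0), const_raster(0.0, cell=5.0))


class TestMasks:
    def test_ngrdi_boundary_zero_is_soil(self):
        ras = Raster(np.array([[-0.2, 0.0], [0.1, np.nan]]), 10.0)
        mask = plant_mask_from_ngrdi(ras)
        assert mask.values[0, 0] == 0 and mask.values[0, 1] == 0
        assert mask.values[1, 0] == 1 and np.isnan(mask.values[1, 1])

    def test_ndvi_threshold_is_strict(self):
        assert (plant_mask_from_ndvi(const_raster(0.1)).values == 0).all()
        assert (plant_mask_from_ndvi(const_raster(0.5)).values == 1).all()

    def test_all_negative_gives_empty_mask(self):
        assert (plant_mask_from_ngrdi(const_raster(-0.3)).values == 0).all()

    def test_scene_masks_equal_true_plant_set(self, small_scene):
        bands = small_scene.bands["S2"]
        canopy = small_scene.dsm["S2"].values - small_scene.dem.values > 0
        mask = plant_mask_from_ngrdi(compute_ngrdi(bands["green"], bands["red"]))
        assert np.array_equal(mask.values == 1.0, canopy)


class TestCSM:
    def test_equal_surfaces_give_zero(self):
        dem = const_raster(100.0)
        assert (compute_csm(dem, dem).values == 0).all()

    def test_single_raised_pixel(self):
        dem = const_raster(10.0)
        vals = dem.values.copy()
        vals[2, 1] += 150.0
        csm = compute_csm(dem.with_values(vals), dem)
        assert csm.values[2, 1] == 150.0
        assert np.count_nonzero(csm.values) == 1


def square_roi(side=1.2, shrink=0.1, plot_id="T1"):
    return PlotROI(plot_id, "G1", "GRP1", box(0.0, 0.0, side, side), border_shrink=shrink)


class TestBlockMaxima:
    def test_single_valid_pixel(self):
        vals = np.full((12, 12), np.nan)
        vals[5, 6] = 120.0
        pts = block_maxima(Raster(vals, 10.0), square_roi(), resample_cell=10.0)
        assert len(pts) == 1 and pts.z[0] == 120.0

    def test_six_by_six_matches_brute_force(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(36).reshape(6, 6).astype(float)
        ras = Raster(vals, 10.0)
        # shrunk ROI covers all 36 pixel centers, so blocks are the quadrants
        roi = PlotROI("Q1", "G1", "GRP1", box(0.0, 0.0, 0.6, 0.6), border_shrink=0.02)
        pts = block_maxima(ras, roi, resample_cell=10.0, window=3)
        expected = sorted(
            float(vals[i : i + 3, j : j + 3].max())
            for i in range(0, 6, 3) for j in range(0, 6, 3)
        )
        assert len(pts) == 4
        assert sorted(pts.z) == expected

    def test_z_values_exist_at_their_coordinates(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(50, 250, size=(12, 12))
        ras = Raster(vals, 10.0)
        pts = block_maxima(ras, square_roi(), resample_cell=10.0)
        for x, y, z in zip(pts.x, pts.y, pts.z):
            j, i = int(x / 0.1), int(y / 0.1)
            assert vals[i, j] == z

    def test_all_nodata_raises_no_plant(self):
        vals = np.full((12, 12), np.nan)
        with pytest.raises(NoPlantError):
            block_maxima(Raster(vals, 10.0), square_roi(), resample_cell=10.0)

    def test_finer_resample_than_native_rejected(self):
        with pytest.raises(ValueError):
            block_maxima(const_raster(1.0, (12, 12)), square_roi(), resample_cell=5.0)


class TestKriging:
    def test_constant_field_interpolates_to_constant(self, rng):
        xy = rng.uniform(0, 2, size=(12, 2))
        z = np.full(12, 200.0)
        pred = krige(xy, z, rng.uniform(0, 2, size=(30, 2)))
        assert np.allclose(pred, 200.0)

    def test_exact_interpolation_at_data_points(self, rng):
        xy = rng.uniform(0, 2, size=(15, 2))
        z = rng.uniform(100, 250, size=15)
        pred = krige(xy, z, xy)
        assert np.allclose(pred, z, atol=1e-6)

    def test_plot_height_at_least_max_point(self, rng):
        for trial in range(5):
            n = 5 + 3 * trial
            pts = MaxPointSet(
                x=rng.uniform(0.2, 1.0, n), y=rng.uniform(0.2, 1.0, n),
                z=rng.uniform(80, 260, n),
            )
            ph = krige_plot_height(pts, square_roi(), grid_cell=10.0)
            assert ph >= pts.z.max() - 1e-9

    def test_few_points_fall_back_to_max(self):
        pts = MaxPointSet(x=np.array([0.5, 0.6]), y=np.array([0.5, 0.6]),
                          z=np.array([120.0, 180.0]))
        assert krige_plot_height(pts, square_roi()) == 180.0

    def test_variogram_fit_degrades_gracefully(self):
        # two distinct values at two lags: spherical fit may fail, linear must not
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.5, 0.5]])
        z = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        vg = fit_variogram(xy, z)
        assert vg.model in ("spherical", "linear")
        assert (vg(np.array([0.5, 1.0])) >= 0).all()


class TestPlotPH:
    def one_plant_scene(self, apexes):
        from uavtraits import SceneConfig, generate_field_scene

        cfg = SceneConfig(
            n_plot_rows=1, n_plot_cols=1, plant_density=0.0,
            plants_override={"P001": [(1.0 + 0.5 * i, 1.2, a) for i, a in enumerate(apexes)]},
            stages=(("S4", 84),),
        )
        return generate_field_scene(cfg, seed=2)

    def test_single_plant_recovers_apex_within_5_percent(self):
        scene = self.one_plant_scene([150.0])
        roi = scene.plots[0]
        res = extract_plot_ph(
            scene.dsm["S4"], scene.dem,
            scene.bands["S4"]["green"], scene.bands["S4"]["red"], roi,
        )
        assert res.status == "ok"
        assert abs(res.ph - 150.0) / 150.0 <= 0.05

    def test_two_plants_max_governs(self):
        scene = self.one_plant_scene([100.0, 160.0])
        roi = scene.plots[0]
        res = extract_plot_ph(
            scene.dsm["S4"], scene.dem,
            scene.bands["S4"]["green"], scene.bands["S4"]["red"], roi,
        )
        assert abs(res.ph - 160.0) / 160.0 <= 0.05

    def test_bare_plot_yields_missing_record_not_crash(self):
        from uavtraits import SceneConfig, generate_field_scene

        scene = generate_field_scene(
            SceneConfig(n_plot_rows=1, n_plot_cols=1, plant_density=0.0), seed=1
        )
        res = extract_plot_ph(
            scene.dsm["S1"], scene.dem,
            scene.bands["S1"]["green"], scene.bands["S1"]["red"], scene.plots[0],
        )
        assert res.status == "no-plant" and np.isnan(res.ph)

    def test_field_recovery_against_truth(self, big_scene_traits):
        """Over 56 plots the extracted PH tracks the truth apex heights."""
        from scipy.stats import spearmanr

        m = big_scene_traits
        rel_err = np.abs(m.ph - m.true_max_height_cm) / m.true_max_height_cm
        assert rel_err.mean() <= 0.05
        rho = spearmanr(m.ph, m.true_max_height_cm).statistic
        assert rho >= 0.95


class TestCCAndNDVI:
    def counting_fixture(self, n_plant=30):
        # ROI (0.1..1.1) x (0.1..1.3) contains exactly 10 x 12 = 120 centers
        roi = PlotROI("C1", "G1", "GRP1", box(0.0, 0.0, 1.2, 1.4), border_shrink=0.1)
        vals = np.zeros((14, 12))
        vals[1:13, 1:11].flat[:n_plant] = 1.0
        return Raster(vals, 10.0), roi

    def test_cc_counting_oracle(self):
        mask, roi = self.counting_fixture(30)
        assert plot_cc(mask, roi) == pytest.approx(30 / 120)

    def test_cc_extremes(self):
        full, roi = self.counting_fixture(120)
        assert plot_cc(full, roi) == 1.0
        empty, _ = self.counting_fixture(0)
        assert plot_cc(empty, roi) == 0.0

    def test_cc_monotone_in_mask(self):
        previous = -1.0
        for n in (0, 10, 40, 80, 120):
            mask, roi = self.counting_fixture(n)
            cc = plot_cc(mask, roi)
            assert cc >= previous
            previous = cc

    def test_mean_ndvi_arithmetic(self):
        mask, roi = self.counting_fixture(2)
        ndvi = mask.with_values(np.where(mask.values == 1.0, 0.0, 0.05))
        vals = ndvi.values.copy()
        vals[mask.values == 1.0] = [0.2, 0.6]
        assert plot_mean_ndvi(mask.with_values(vals), mask, roi) == pytest.approx(0.4)

    def test_mean_ndvi_empty_mask_raises(self):
        mask, roi = self.counting_fixture(0)
        with pytest.raises(NoPlantError):
            plot_mean_ndvi(mask, mask, roi)

    def test_scene_cc_matches_truth_fraction(self, small_scene):
        """At the sparse first stage CC equals the truth plant fraction."""
        bands = small_scene.bands["S1"]
        mask = plant_mask_from_ndvi(compute_ndvi(bands["nir"], bands["red"]))
        for roi in small_scene.plots:
            truth = small_scene.truth.query("plot_id == @roi.plot_id and stage == 'S1'")
            assert plot_cc(mask, roi) == pytest.approx(
                truth["true_plant_fraction"].iloc[0], abs=1e-12
            )

    def test_scene_mean_ndvi_equals_configured_plant_ndvi(self, small_scene):
        bands = small_scene.bands["S2"]
        ndvi = compute_ndvi(bands["nir"], bands["red"])
        mask = plant_mask_from_ndvi(ndvi)
        p = small_scene.config.plant_reflectance
        expected = (p["nir"] - p["red"]) / (p["nir"] + p["red"])
        for roi in small_scene.plots:
            assert plot_mean_ndvi(ndvi, mask, roi) == pytest.approx(expected)
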