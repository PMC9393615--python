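"""Calibration, segmentation, leaf labelling, trimming, outlier rules."""

import numpy as np
import pytest

import spectransfer as st
from spectransfer.envi import read_envi, write_envi
from spectransfer.preprocess import spectra_to_table


def make_cube(values, wavelengths=None, kind="reflectance"):
    values = np.asarray(values, dtype=float)
    if wavelengths is None:
        wavelengths = np.linspace(450, 902, values.shape[2])
    return st.SpectralCube(values, wavelengths, kind=kind)


class TestCalibrate:
    wl = np.array([500.0, 792.0])

    def _frames(self, shape=(4, 4, 2)):
        dark = st.SpectralCube(np.full(shape, 100.0), self.wl)
        white = st.SpectralCube(np.full(shape, 4000.0), self.wl)
        return dark, white

    @pytest.mark.parametrize(
        "raw_value,expected", [(4000.0, 1.0), (100.0, 0.0), (2050.0, 0.5)]
    )
    def test_reference_identities(self, raw_value, expected):
        dark, white = self._frames()
        raw = st.SpectralCube(np.full((4, 4, 2), raw_value), self.wl)
        refl = st.calibrate(raw, dark, white)
        assert refl.kind == "reflectance"
        assert np.allclose(refl.values, expected)

    def test_shape_mismatch_rejected(self):
        dark, white = self._frames()
        raw = st.SpectralCube(np.zeros((3, 4, 2)), self.wl)
        with pytest.raises(ValueError, match="shape"):
            st.calibrate(raw, dark, white)

    def test_nonpositive_denominator_rejected(self):
        dark, white = self._frames()
        with pytest.raises(ValueError, match="positive"):
            st.calibrate(white, white, dark)

    def test_no_clipping_above_one(self):
        dark, white = self._frames()
        raw = st.SpectralCube(np.full((4, 4, 2), 5000.0), self.wl)
        assert np.all(st.calibrate(raw, dark, white).values > 1.0)


class TestSegmentPlant:
    def test_separated_classes_recovered_exactly(self):
        values = np.full((5, 5, 2), 0.05)
        values[1:3, 1:4, :] = 0.4
        cube = make_cube(values, np.array([500.0, 792.0]))
        mask = st.segment_plant(cube)
        assert np.array_equal(mask, values[:, :, 1] > 0.1)

    def test_all_background_gives_empty_mask(self):
        cube = make_cube(np.full((4, 4, 2), 0.05), np.array([500.0, 792.0]))
        assert not st.segment_plant(cube).any()

    def test_mask_monotone_in_threshold(self, rng):
        cube = make_cube(rng.uniform(0, 1, size=(8, 8, 2)), np.array([500.0, 792.0]))
        low = st.segment_plant(cube, threshold=0.1)
        high = st.segment_plant(cube, threshold=0.5)
        assert np.all(high <= low)

    def test_requires_band_near_wavelength(self):
        cube = make_cube(np.zeros((2, 2, 1)), np.array([500.0]))
        with pytest.raises(ValueError, match="no band"):
            st.segment_plant(cube, wavelength=792.0)

    def test_requires_reflectance_kind(self):
        cube = make_cube(np.zeros((2, 2, 1)), np.array([792.0]), kind="raw")
        with pytest.raises(ValueError, match="reflectance"):
            st.segment_plant(cube)


class TestRemoveStems:
    def test_empty_list_is_identity(self):
        mask = np.ones((4, 4), dtype=bool)
        assert np.array_equal(st.remove_stems(mask, []), mask)

    def test_full_rectangle_annihilates(self):
        mask = np.ones((4, 6), dtype=bool)
        rect = {"x": 0, "y": 0, "width": 6, "height": 4}
        assert not st.remove_stems(mask, [rect]).any()

    def test_disjoint_rectangles_remove_enumerated_pixels(self):
        mask = np.ones((10, 10), dtype=bool)
        rects = [
            {"x": 1, "y": 1, "width": 3, "height": 2},
            {"x": 6, "y": 5, "width": 2, "height": 4},
        ]
        out = st.remove_stems(mask, rects)
        # count removed pixels by direct enumeration over coordinates
        removed = sum(
            1
            for y in range(10)
            for x in range(10)
            if any(
                r["x"] <= x < r["x"] + r["width"] and r["y"] <= y < r["y"] + r["height"]
                for r in rects
            )
        )
        assert mask.sum() - out.sum() == removed == 3 * 2 + 2 * 4

    def test_out_of_bounds_is_an_error_not_a_clip(self):
        mask = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="bounds"):
            st.remove_stems(mask, [{"x": 3, "y": 0, "width": 2, "height": 1}])


class TestExtractLeaves:
    def test_two_ellipses_two_components(self):
        mask = np.zeros((20, 40), dtype=bool)
        yy, xx = np.mgrid[0:20, 0:40]
        e1 = ((yy - 10) / 5) ** 2 + ((xx - 10) / 6) ** 2 <= 1
        e2 = ((yy - 10) / 5) ** 2 + ((xx - 30) / 6) ** 2 <= 1
        mask |= e1 | e2
        labels = st.extract_leaves(mask, min_area=10)
        assert labels.max() == 2
        assert (labels == 1).sum() == e1.sum()
        assert (labels == 2).sum() == e2.sum()

    def test_min_area_boundary_drops_small(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0:2, 0:2] = True  # area 4
        assert st.extract_leaves(mask, min_area=5).max() == 0
        assert st.extract_leaves(mask, min_area=4).max() == 1

    def test_diagonal_pair_is_one_component_under_8_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert st.extract_leaves(mask, min_area=1).max() == 1

    def test_labels_in_raster_order(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[4:6, 0:2] = True   # later in raster order
        mask[0:2, 3:5] = True   # first pixel earlier
        labels = st.extract_leaves(mask, min_area=1)
        assert labels[0, 3] == 1 and labels[4, 0] == 2

    def test_components_never_intersect_removed_rectangles(self, rng):
        mask = rng.random((20, 20)) > 0.4
        rects = [{"x": 5, "y": 5, "width": 6, "height": 4}]
        labels = st.extract_leaves(st.remove_stems(mask, rects), min_area=1)
        assert not labels[5:9, 5:11].any()


class TestMeanSpectrumAndTrim:
    def test_mean_of_constant_component(self):
        cube = make_cube(np.full((3, 3, 4), 0.37))
        spec = st.mean_spectrum(cube, np.ones((3, 3), dtype=bool))
        assert np.allclose(spec.reflectance, 0.37)
        assert spec.n_pixels == 9

    def test_two_pixel_arithmetic(self):
        values = np.zeros((1, 2, 1))
        values[0, 0, 0], values[0, 1, 0] = 0.2, 0.4
        spec = st.mean_spectrum(make_cube(values, np.array([700.0])), np.ones((1, 2), bool))
        assert spec.reflectance[0] == pytest.approx(0.3)

    def test_empty_component_rejected(self):
        cube = make_cube(np.zeros((2, 2, 1)), np.array([700.0]))
        with pytest.raises(ValueError, match="empty"):
            st.mean_spectrum(cube, np.zeros((2, 2), bool))

    def test_trim_full_sensor_grid_keeps_227_bands(self):
        wl = np.arange(380.0, 1032.0, 2.0)
        spec = st.LeafSpectrum(np.full(wl.size, 0.3), wl)
        trimmed = st.trim_bands(spec)
        assert trimmed.wavelengths.size == 227
        assert trimmed.wavelengths[0] == 450.0 and trimmed.wavelengths[-1] == 902.0

    def test_trim_is_idempotent_and_inclusive(self):
        wl = np.arange(450.0, 904.0, 2.0)
        spec = st.LeafSpectrum(np.linspace(0, 1, wl.size), wl)
        once = st.trim_bands(spec)
        twice = st.trim_bands(once)
        assert np.array_equal(once.wavelengths, twice.wavelengths)
        single = st.trim_bands(spec, low=500.0, high=500.0)
        assert single.wavelengths.tolist() == [500.0]

    def test_trim_empty_range_rejected(self):
        spec = st.LeafSpectrum(np.ones(3), np.array([500.0, 502.0, 504.0]))
        with pytest.raises(ValueError, match="no bands"):
            st.trim_bands(spec, low=600.0, high=700.0)


class TestRejectOutliers:
    def _table(self, config):
        return st.simulate_experiment(config, "Exp1")

    def test_clean_batch_has_zero_rejections(self, small_config):
        retained, rejected = st.reject_outliers(self._table(small_config))
        assert len(rejected) == 0
        assert len(retained) == len(self._table(small_config))

    def test_negated_spectrum_rejected_by_band_rule(self, small_config):
        table = self._table(small_config)
        wl_cols = [c for c in table.columns if c.startswith("wl_")]
        table.loc[0, wl_cols] = -table.loc[0, wl_cols]
        _, rejected = st.reject_outliers(table)
        assert 0 in rejected.index
        assert "band outside" in rejected.loc[0, "reason"]

    def test_background_spectrum_rejected_by_nir_floor(self, small_config):
        table = self._table(small_config)
        wl_cols = [c for c in table.columns if c.startswith("wl_")]
        table.loc[3, wl_cols] = 0.05  # flat background: mean NIR 0.05 < 0.15
        _, rejected = st.reject_outliers(table)
        assert "NIR" in rejected.loc[3, "reason"]

    def test_rerun_on_retained_rejects_nothing(self, small_config):
        table = self._table(small_config)
        wl_cols = [c for c in table.columns if c.startswith("wl_")]
        table.loc[5, wl_cols] = 2.0
        retained, _ = st.reject_outliers(table)
        again, rejected = st.reject_outliers(retained)
        assert len(rejected) == 0 and len(again) == len(retained)


class TestRoundTrip:
    def test_render_calibrate_segment_mean_recovers_spectra(self):
        """Full pipeline recovers the generator spectra within 3 x noise sd."""
        wl = np.arange(450.0, 904.0, 2.0)
        spectra = np.vstack(
            [
                st.simulate_spectrum("RT", 2),
                st.simulate_spectrum("ST", 8),
                st.simulate_spectrum("RW", 6),
                st.simulate_spectrum("SW", 4),
            ]
        )
        scene = st.SceneSpec(n_rows=2, n_cols=2, pixel_noise_sd=0.004)
        rendered = st.render_cube(spectra, wl, scene, np.random.default_rng(7))
        raw = st.SpectralCube(rendered.raw, wl)
        dark = st.SpectralCube(rendered.dark, wl)
        white = st.SpectralCube(rendered.white, wl)
        leaves = st.extract_cube_spectra(raw, dark, white, rendered.stem_rectangles)
        assert len(leaves) == 4
        recovered = {leaf.labels["leaf_id"]: leaf.reflectance for leaf in leaves}
        # mean over >100 pixels shrinks noise; 3*noise_sd is a loose cap
        for k in range(4):
            err = np.max(np.abs(recovered[k + 1] - spectra[k]))
            assert err < 3 * scene.pixel_noise_sd

    def test_envi_round_trip(self, tmp_path):
        wl = np.array([450.0, 600.0, 902.0])
        cube = st.SpectralCube(np.random.default_rng(0).random((5, 7, 3)), wl)
        write_envi(tmp_path / "cube.bil", cube)
        back = read_envi(tmp_path / "cube.bil")
        assert np.array_equal(back.wavelengths, wl)
        assert np.allclose(back.values, cube.values, atol=1e-6)

    def test_spectra_to_table_round_trip(self):
        wl = np.array([500.0, 700.0])
        specs = [
            st.LeafSpectrum(np.array([0.1, 0.5]), wl, labels={"leaf_id": 1}, n_pixels=9),
            st.LeafSpectrum(np.array([0.2, 0.6]), wl, labels={"leaf_id": 2}, n_pixels=4),
        ]
        table = spectra_to_table(specs)
        assert list(table["leaf_id"]) == [1, 2]
        assert table.loc[1, "wl_700"] == 0.6
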