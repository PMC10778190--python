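"""Generator correctness: masks, point processes, localizations, movies."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import sparkmap as sm
from sparkmap.puncta import nearest_neighbour_distances
from sparkmap.synthetic import MovieParams


class TestCellMask:
    def test_zero_irregularity_is_a_disk(self):
        mask = sm.gen_cell_mask((120, 120), 5.0, 0.0, seed=0)
        area_um2 = mask.sum() * 0.01
        assert area_um2 == pytest.approx(np.pi * 25.0, rel=0.02)
        lbl, n = ndimage.label(mask)
        assert n == 1

    def test_determinism(self):
        a = sm.gen_cell_mask((100, 100), 3.5, 0.3, seed=42)
        b = sm.gen_cell_mask((100, 100), 3.5, 0.3, seed=42)
        assert np.array_equal(a, b)
        c = sm.gen_cell_mask((100, 100), 3.5, 0.3, seed=43)
        assert not np.array_equal(a, c)

    def test_irregular_area_near_circle(self):
        mask = sm.gen_cell_mask((120, 120), 4.0, 0.3, seed=1)
        area_um2 = mask.sum() * 0.01
        assert abs(area_um2 - np.pi * 16.0) / (np.pi * 16.0) < 0.2
        lbl, n = ndimage.label(mask)
        assert n == 1

    def test_radius_too_large_errors(self):
        with pytest.raises(ValueError):
            sm.gen_cell_mask((50, 50), 4.0, 0.0, seed=0)


class TestPunctaField:
    def test_poisson_count(self, small_cell):
        area = small_cell.sum() * 0.01
        density = 13.4
        pts = sm.gen_puncta_field(small_cell, density, seed=10)
        expected = density * area
        assert abs(len(pts) - expected) < 3 * np.sqrt(expected)

    def test_hotspot_ratio_recovered(self, small_cell):
        hot = (sm.Hotspot((5000.0, 5000.0), 900.0, 4.0),)
        pts = sm.gen_puncta_field(small_cell, 20.0, hotspots=hot, seed=11)
        xy = pts[["x_nm", "y_nm"]].to_numpy()
        d2 = (xy[:, 0] - 5000.0) ** 2 + (xy[:, 1] - 5000.0) ** 2
        inside = d2 <= 900.0**2
        area_in = np.pi * 0.9**2
        area_out = small_cell.sum() * 0.01 - area_in
        ratio = (inside.sum() / area_in) / ((~inside).sum() / area_out)
        assert ratio == pytest.approx(4.0, rel=0.30)

    def test_multiplier_one_is_homogeneous(self, small_cell):
        hot = (sm.Hotspot((5000.0, 5000.0), 900.0, 1.0),)
        pts = sm.gen_puncta_field(small_cell, 20.0, hotspots=hot, seed=12)
        xy = pts[["x_nm", "y_nm"]].to_numpy()
        inside = (xy[:, 0] - 5000.0) ** 2 + (xy[:, 1] - 5000.0) ** 2 <= 900.0**2
        area_in = np.pi * 0.9**2
        area_out = small_cell.sum() * 0.01 - area_in
        ratio = (inside.sum() / area_in) / ((~inside).sum() / area_out)
        assert ratio == pytest.approx(1.0, abs=0.35)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            sm.gen_puncta_field(np.zeros((10, 10), bool), 10.0)

    def test_csr_mean_nnd_law(self):
        # uniform Poisson points at intensity lambda: mean NND -> 1/(2 sqrt(lambda))
        mask = np.ones((100, 100), bool)
        lam = 50.0
        pts = sm.gen_puncta_field(mask, lam, min_separation_nm=0.0, seed=13)
        nnd_um = nearest_neighbour_distances(pts[["x_nm", "y_nm"]].to_numpy()) / 1000.0
        mean_theory = 1.0 / (2.0 * np.sqrt(lam))
        sd_theory = np.sqrt((4.0 - np.pi) / (4.0 * np.pi * lam))
        se = sd_theory / np.sqrt(len(nnd_um))
        # boundary points have no neighbours outside the window, biasing the
        # mean up by ~1%; allow that on top of 3 SE
        assert abs(nnd_um.mean() - mean_theory) < 3.0 * se + 0.015 * mean_theory


class TestLocalizations:
    def test_identity_when_noise_free(self, small_cell):
        pts = sm.gen_puncta_field(small_cell, 5.0, seed=20)
        locs = sm.gen_localizations(pts, mean_locs_per_punctum=1.0, precision_sigma_nm=0.0, seed=21)
        assert np.allclose(
            np.sort(locs["x_nm"].to_numpy()), np.sort(pts["x_nm"].to_numpy())
        )

    def test_mean_count(self, small_cell):
        pts = sm.gen_puncta_field(small_cell, 13.4, seed=22)
        locs = sm.gen_localizations(pts, mean_locs_per_punctum=5.0, seed=23)
        expected = 5.0 * len(pts)
        assert abs(len(locs) - expected) < 4 * np.sqrt(expected)

    def test_negative_rates_error(self, small_cell):
        pts = sm.gen_puncta_field(small_cell, 5.0, seed=24)
        with pytest.raises(ValueError):
            sm.gen_localizations(pts, precision_sigma_nm=-1.0)
        with pytest.raises(ValueError):
            sm.gen_localizations(pts, false_rate_per_um2=-0.5, mask=small_cell)

    def test_false_only_is_csr(self, small_cell):
        empty = pd.DataFrame(columns=["x_nm", "y_nm"])
        locs = sm.gen_localizations(
            empty, false_rate_per_um2=40.0, mask=small_cell, pixel_size_um=0.1, seed=25
        )
        lam = 40.0
        nnd_um = nearest_neighbour_distances(locs[["x_nm", "y_nm"]].to_numpy()) / 1000.0
        mean_theory = 1.0 / (2.0 * np.sqrt(lam))
        sd_theory = np.sqrt((4.0 - np.pi) / (4.0 * np.pi * lam))
        assert abs(nnd_um.mean() - mean_theory) < 3.0 * sd_theory / np.sqrt(len(nnd_um)) + 0.02 * mean_theory


class TestSparkMovie:
    def test_zero_sparks_clean_detector(self, quiet_movie):
        movie, mask = quiet_movie
        sparks = sm.detect_sparks(movie)
        assert len(sparks) == 0

    def test_noiseless_single_spark_inverts_exactly(self):
        mask = np.ones((60, 60), bool)
        params = MovieParams(n_frames=40, snr=1e9, offset_level=0.0)
        table = pd.DataFrame({"x_um": [3.0], "y_um": [3.0], "t_frame": [20], "fwhm_um": [1.0], "amplitude": [2.0]})
        movie, truth = sm.gen_spark_movie(mask, params=params, spark_table=table, seed=30)
        base = sm.estimate_baseline(movie)
        seeds = sm.detect_candidates(movie, base)
        assert len(seeds) == 1
        ev = sm.fit_spark(movie, base, seeds[0])
        assert ev.fwhm_um == pytest.approx(1.0, abs=1e-3)
        assert ev.amplitude == pytest.approx(2.0, abs=1e-3)
        assert ev.r2 == pytest.approx(1.0, abs=1e-6)
        assert ev.x_um == pytest.approx(3.0, abs=1e-3)

    def test_snr_definition(self):
        # noise sd of the 10-frame average == mean spark peak amplitude / snr
        mask = np.ones((80, 80), bool)
        params = MovieParams(n_frames=60, snr=17.0, baseline_level=1000.0)
        movie, _ = sm.gen_spark_movie(
            mask, params=params, rate_per_frame=0.0, amplitude_range=(1.5, 3.0), seed=31
        )
        avg = movie[:10].mean(axis=0)
        noise_sd = (avg - avg.mean()).std()
        expected = 1000.0 * (2.25 - 1.0) / 17.0
        assert noise_sd == pytest.approx(expected, rel=0.1)

    def test_truth_inside_mask(self, small_cell):
        movie, truth = sm.gen_spark_movie(small_cell, rate_per_frame=0.3, seed=32)
        j = (truth["x_um"].to_numpy() / 0.1).astype(int)
        i = (truth["y_um"].to_numpy() / 0.1).astype(int)
        assert small_cell[i, j].all()


class TestKnownShift:
    def test_table_shift_identity_and_inverse(self, csr_points):
        same = sm.apply_known_shift_table(csr_points, 0.0, 0.0)
        pd.testing.assert_frame_equal(same, csr_points)
        fwd = sm.apply_known_shift_table(csr_points, 123.4, -56.7)
        back = sm.apply_known_shift_table(fwd, -123.4, 56.7)
        assert np.allclose(back["x_nm"], csr_points["x_nm"])
        assert np.allclose(back["y_nm"], csr_points["y_nm"])

    def test_integer_pixel_image_shift_is_roll(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(40, 40))
        out = sm.apply_known_shift_image(img, 300.0, -200.0, pixel_size_nm=100.0)
        expect = np.roll(np.roll(img, -2, axis=0), 3, axis=1)
        # rolled-in edges (bottom rows, left columns) are zero-filled
        assert np.allclose(out[:38, 3:], expect[:38, 3:])

    def test_determinism_of_dataset(self):
        a = sm.simulate_correlative_dataset(seed=3)
        b = sm.simulate_correlative_dataset(seed=3)
        assert np.array_equal(a.movie, b.movie)
        pd.testing.assert_frame_equal(a.localizations, b.localizations)
        pd.testing.assert_frame_equal(a.truth.puncta_truth, b.truth.puncta_truth)
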