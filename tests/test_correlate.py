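"""Spark footprints, site masks, site-vs-global statistics."""

import numpy as np
import pandas as pd
import pytest

import sparkmap as sm
from sparkmap.correlate import (
    footprint_sample,
    mass_count_table,
    nnd_site_vs_global,
    sample_all_footprints,
    site_vs_global_density,
    sparksite_mask,
)
from sparkmap.puncta import PunctaSet


def _pset(points):
    pts = np.asarray(points, dtype=float)
    return PunctaSet(pd.DataFrame({"x_nm": pts[:, 0], "y_nm": pts[:, 1], "area_nm2": 400.0}))


def _spark(x_nm, y_nm, fwhm_um, mass=1.0):
    return pd.Series({"x_nm": x_nm, "y_nm": y_nm, "fwhm_um": fwhm_um, "mass": mass})


class TestFootprint:
    def test_counts_points_inside(self):
        pset = _pset([(0, 100), (100, 0), (-150, 0), (0, -200), (50, 50), (5000, 5000)])
        s = footprint_sample(_spark(0.0, 0.0, 1.0), pset)
        assert s.count == 5

    def test_boundary_inclusive(self):
        pset = _pset([(500.0, 0.0), (500.0001, 0.0001)])
        s = footprint_sample(_spark(0.0, 0.0, 1.0), pset)  # radius exactly 500
        assert 0 in s.puncta_indices

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-2000, 2000, size=(200, 2))
        pset = _pset(pts)
        for k in range(10):
            cx, cy = rng.uniform(-1000, 1000, 2)
            fwhm = rng.uniform(0.3, 2.0)
            s = footprint_sample(_spark(cx, cy, fwhm), pset)
            brute = np.nonzero(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) <= fwhm * 500.0)[0]
            assert sorted(s.puncta_indices) == sorted(brute)

    def test_monotone_in_fwhm(self):
        rng = np.random.default_rng(2)
        pset = _pset(rng.uniform(-1500, 1500, size=(300, 2)))
        counts = [footprint_sample(_spark(0, 0, f), pset).count for f in (0.5, 1.0, 2.0, 3.0)]
        assert counts == sorted(counts)

    def test_nnd_within_footprint(self):
        pset = _pset([(0.0, 0.0), (100.0, 0.0), (4000.0, 4000.0)])
        s = footprint_sample(_spark(50.0, 0.0, 1.0), pset)
        assert s.count == 2
        assert s.mean_nnd_nm == pytest.approx(100.0)
        lone = footprint_sample(_spark(4000.0, 4000.0, 0.5), pset)
        assert lone.count == 1 and lone.mean_nnd_nm is None


class TestSparksiteMask:
    def test_single_disk_fraction(self):
        cell = np.ones((100, 100), bool)  # 100 um^2 at 100 nm/px
        sparks = pd.DataFrame({"x_nm": [5000.0], "y_nm": [5000.0], "fwhm_um": [1.0]})
        _, frac = sparksite_mask(sparks, cell, 100.0)
        assert frac == pytest.approx(np.pi * 0.25 / 100.0, rel=0.05)

    def test_coincident_sparks_count_once(self):
        cell = np.ones((100, 100), bool)
        one = pd.DataFrame({"x_nm": [5000.0], "y_nm": [5000.0], "fwhm_um": [1.0]})
        two = pd.concat([one, one], ignore_index=True)
        _, f1 = sparksite_mask(one, cell, 100.0)
        _, f2 = sparksite_mask(two, cell, 100.0)
        assert f1 == f2

    def test_union_subadditive(self):
        cell = np.ones((100, 100), bool)
        sparks = pd.DataFrame(
            {"x_nm": [4000.0, 4600.0, 6000.0], "y_nm": [5000.0, 5000.0, 6000.0], "fwhm_um": [1.0, 1.0, 1.2]}
        )
        _, f_all = sparksite_mask(sparks, cell, 100.0)
        singles = sum(
            sparksite_mask(sparks.iloc[[k]], cell, 100.0)[1] for k in range(len(sparks))
        )
        assert f_all <= singles + 1e-12

    def test_empty_sparks(self):
        cell = np.ones((50, 50), bool)
        mask, frac = sparksite_mask(pd.DataFrame(columns=["x_nm", "y_nm", "fwhm_um"]), cell, 100.0)
        assert frac == 0.0 and not mask.any()

    def test_known_coverage_recovered(self):
        # tiling disks over a known fraction of the cell
        cell = np.ones((200, 200), bool)
        xs, ys = np.meshgrid(np.arange(2000, 19000, 2400), np.arange(2000, 19000, 2400))
        sparks = pd.DataFrame(
            {"x_nm": xs.ravel().astype(float), "y_nm": ys.ravel().astype(float), "fwhm_um": 1.2}
        )
        _, frac = sparksite_mask(sparks, cell, 100.0)
        expected = len(sparks) * np.pi * 0.6**2 / 400.0
        assert frac == pytest.approx(expected, abs=0.02)


class TestSiteVsGlobal:
    def test_uniform_ratio_near_one(self, small_cell):
        pts = sm.gen_puncta_field(small_cell, 30.0, seed=3)
        sparks = pd.DataFrame(
            {"x_nm": [3500.0, 5500.0, 6500.0], "y_nm": [5000.0, 3600.0, 6000.0], "fwhm_um": 1.5}
        )
        site, _ = sparksite_mask(sparks, small_cell, 100.0)
        summary = site_vs_global_density(_pset(pts[["x_nm", "y_nm"]].to_numpy()), site, small_cell, 100.0)
        assert summary.density_ratio == pytest.approx(1.0, abs=0.45)

    def test_all_points_inside_site(self):
        cell = np.ones((100, 100), bool)
        sparks = pd.DataFrame({"x_nm": [5000.0], "y_nm": [5000.0], "fwhm_um": [2.0]})
        site, frac = sparksite_mask(sparks, cell, 100.0)
        rng = np.random.default_rng(4)
        ang = rng.uniform(0, 2 * np.pi, 50)
        rad = 800.0 * np.sqrt(rng.uniform(0, 1, 50))
        pts = np.column_stack([5000 + rad * np.cos(ang), 5000 + rad * np.sin(ang)])
        summary = site_vs_global_density(_pset(pts), site, cell, 100.0)
        assert summary.density_ratio == pytest.approx(1.0 / frac, rel=0.05)

    def test_zero_site_mask_errors(self):
        cell = np.ones((10, 10), bool)
        with pytest.raises(ValueError):
            site_vs_global_density(_pset([(1, 1), (2, 2)]), np.zeros_like(cell), cell, 100.0)


class TestMassCount:
    def test_summary_statistics(self):
        pset = _pset([(0, 0), (100, 0), (200, 0)])
        sparks = pd.DataFrame(
            {
                "x_nm": [100.0, 5000.0, 100.0],
                "y_nm": [0.0, 5000.0, 0.0],
                "fwhm_um": [0.9, 0.9, 2.0],
                "mass": [1.0, 2.0, 3.0],
            }
        )
        samples = sample_all_footprints(sparks, pset)
        table, summary = mass_count_table(samples)
        assert summary["n_sparks"] == 3
        assert summary["count_mean"] == pytest.approx(np.mean([c.count for c in samples]))
        assert table["count"].tolist() == [3, 0, 3]

    def test_mean_sd_reference(self):
        pset = _pset([(0, 0), (10000, 10000)])
        sparks = pd.DataFrame(
            {"x_nm": [0.0, 0.0, 0.0], "y_nm": [0.0, 0.0, 0.0], "fwhm_um": [1.0] * 3, "mass": [1.0, 2.0, 3.0]}
        )
        samples = sample_all_footprints(sparks, pset)
        for s, c in zip(samples, (10, 20, 30)):
            s.puncta_indices = np.arange(c)  # constructed counts
        _, summary = mass_count_table(samples)
        assert summary["count_mean"] == 20.0
        assert summary["count_sd"] == pytest.approx(10.0)

    def test_monotone_coupling_positive_rank_corr(self):
        rng = np.random.default_rng(5)
        samples = []
        pts = rng.uniform(0, 20000, size=(2000, 2))
        pset = _pset(pts)
        for k, fwhm in enumerate(np.linspace(0.5, 2.0, 12)):
            s = footprint_sample(_spark(10000.0, 10000.0, fwhm, mass=fwhm * 1.206), pset, spark_id=k)
            samples.append(s)
        _, summary = mass_count_table(samples)
        assert summary["mass_count_spearman"] > 0


class TestNNDHistograms:
    def test_two_puncta_in_one_footprint(self):
        pset = _pset([(0.0, 0.0), (100.0, 0.0), (8000.0, 8000.0), (9000.0, 9000.0)])
        sparks = pd.DataFrame({"x_nm": [50.0], "y_nm": [0.0], "fwhm_um": [1.0], "mass": [1.0]})
        samples = sample_all_footprints(sparks, pset)
        out = nnd_site_vs_global(pset, samples)
        assert np.allclose(out["nnd_site_nm"], [100.0, 100.0])
        assert not out["site_empty"]

    def test_enriched_sites_have_shorter_nnd(self, small_cell):
        hot = (sm.Hotspot((5000.0, 5000.0), 900.0, 5.0),)
        pts = sm.gen_puncta_field(small_cell, 15.0, hotspots=hot, seed=6)
        pset = _pset(pts[["x_nm", "y_nm"]].to_numpy())
        sparks = pd.DataFrame({"x_nm": [5000.0], "y_nm": [5000.0], "fwhm_um": [1.5], "mass": [1.0]})
        samples = sample_all_footprints(sparks, pset)
        out = nnd_site_vs_global(pset, samples)
        assert out["nnd_site_nm"].mean() < out["nnd_global_nm"].mean()

    def test_no_multi_punctum_footprint_flagged(self):
        pset = _pset([(0.0, 0.0), (9000.0, 9000.0)])
        sparks = pd.DataFrame({"x_nm": [0.0], "y_nm": [0.0], "fwhm_um": [1.0], "mass": [1.0]})
        out = nnd_site_vs_global(pset, sample_all_footprints(sparks, pset))
        assert out["site_empty"]
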