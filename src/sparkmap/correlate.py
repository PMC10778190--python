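"""Spark-footprint sampling of channel puncta and site-level statistics.

Each aligned spark defines a circular footprint centered on its centroid
with diameter equal to its FWHM.  Puncta inside the footprint (boundary
inclusive) are counted and their within-footprint nearest-neighbour
distances averaged; the union of all footprints, intersected with the cell
mask, defines the spark-site region whose punctum density is compared with
the cell-wide density.  Footprints are per-spark samples, not a partition:
a punctum may belong to several sparks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .puncta import PunctaSet, nearest_neighbour_distances, spatial_density

NND_BIN_NM = 25.0


@dataclass
class FootprintSample:
    """Puncta sampled under one spark footprint."""

    spark_id: int
    center_nm: tuple[float, float]
    diameter_nm: float
    puncta_indices: np.ndarray
    spark_mass: float
    mean_nnd_nm: float | None = None

    @property
    def count(self) -> int:
        return len(self.puncta_indices)


@dataclass
class SiteSummary:
    """Spark-site versus cell-wide statistics."""

    site_area_fraction: float
    density_site_per_um2: float
    density_global_per_um2: float
    density_ratio: float
    nnd_site_nm: np.ndarray = field(default_factory=lambda: np.empty(0))
    nnd_global_nm: np.ndarray = field(default_factory=lambda: np.empty(0))


def footprint_sample(
    spark: pd.Series | dict,
    puncta: PunctaSet | np.ndarray,
    spark_id: int = 0,
    tree: cKDTree | None = None,
) -> FootprintSample:
    """Sample the puncta lying within one spark's footprint.

    The spark must carry map coordinates (``x_nm, y_nm``) and ``fwhm_um``;
    inclusion is Euclidean distance <= FWHM/2 from the spark center
    (boundary inclusive).  ``mean_nnd_nm`` averages, over the included
    puncta, the distance to the nearest *included* neighbour; it is
    undefined (None) for fewer than two puncta.
    """
    pts = puncta.points if isinstance(puncta, PunctaSet) else np.asarray(puncta, dtype=float)
    cx, cy = float(spark["x_nm"]), float(spark["y_nm"])
    r = float(spark["fwhm_um"]) * 1000.0 / 2.0
    if tree is None:
        tree = cKDTree(pts) if len(pts) else None
    idx = np.array(sorted(tree.query_ball_point([cx, cy], r)), dtype=int) if tree is not None else np.empty(0, int)
    mean_nnd = None
    if len(idx) >= 2:
        mean_nnd = float(np.mean(nearest_neighbour_distances(pts[idx])))
    return FootprintSample(
        spark_id=spark_id,
        center_nm=(cx, cy),
        diameter_nm=2.0 * r,
        puncta_indices=idx,
        spark_mass=float(spark["mass"]) if "mass" in spark else np.nan,
        mean_nnd_nm=mean_nnd,
    )


def sample_all_footprints(sparks: pd.DataFrame, puncta: PunctaSet) -> list[FootprintSample]:
    tree = cKDTree(puncta.points) if len(puncta) else None
    return [
        footprint_sample(row, puncta, spark_id=i, tree=tree)
        for i, (_, row) in enumerate(sparks.iterrows())
    ]


def sparksite_mask(
    sparks: pd.DataFrame,
    cell_mask: np.ndarray,
    pixel_size_nm: float,
    origin_nm: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, float]:
    """Union of spark footprints on the cell-mask grid, and its area fraction.

    Overlapping footprints are counted once.  Returns ``(site_mask,
    fraction)`` with fraction = area(union intersected with cell) /
    area(cell).  An empty spark table yields a zero mask and fraction 0.
    """
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    h, w = cell_mask.shape
    site = np.zeros((h, w), dtype=bool)
    xc = origin_nm[0] + (np.arange(w) + 0.5) * pixel_size_nm
    yc = origin_nm[1] + (np.arange(h) + 0.5) * pixel_size_nm
    for _, row in sparks.iterrows():
        r = float(row["fwhm_um"]) * 1000.0 / 2.0
        cx, cy = float(row["x_nm"]), float(row["y_nm"])
        j0 = max(0, int(np.floor((cx - r - origin_nm[0]) / pixel_size_nm)) - 1)
        j1 = min(w, int(np.ceil((cx + r - origin_nm[0]) / pixel_size_nm)) + 1)
        i0 = max(0, int(np.floor((cy - r - origin_nm[1]) / pixel_size_nm)) - 1)
        i1 = min(h, int(np.ceil((cy + r - origin_nm[1]) / pixel_size_nm)) + 1)
        if j0 >= j1 or i0 >= i1:
            continue
        dx = xc[j0:j1][None, :] - cx
        dy = yc[i0:i1][:, None] - cy
        site[i0:i1, j0:j1] |= dx**2 + dy**2 <= r**2
    site &= cell_mask
    fraction = float(site.sum()) / float(cell_mask.sum())
    return site, fraction


def site_vs_global_density(
    puncta: PunctaSet,
    site_mask: np.ndarray,
    cell_mask: np.ndarray,
    pixel_size_nm: float,
    origin_nm: tuple[float, float] = (0.0, 0.0),
) -> SiteSummary:
    """Punctum density inside the spark-site region versus the whole cell.

    The global density is over the full cell footprint (spark sites
    included), matching how a cell-wide density is measured on the same
    map.  Nearest-neighbour distance lists are attached for both regions;
    within the site region, neighbours are restricted to site puncta.
    """
    if not site_mask.any():
        raise ValueError("spark-site mask has zero area")
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    pts = puncta.points
    d_site = spatial_density(pts, site_mask & cell_mask, pixel_size_nm, origin_nm)
    d_glob = spatial_density(pts, cell_mask, pixel_size_nm, origin_nm)
    frac = float((site_mask & cell_mask).sum()) / float(cell_mask.sum())
    from .puncta import points_in_mask

    nnd_global = nearest_neighbour_distances(pts) if len(pts) >= 2 else np.empty(0)
    in_site = points_in_mask(pts, site_mask & cell_mask, pixel_size_nm, origin_nm)
    site_pts = pts[in_site]
    nnd_site = nearest_neighbour_distances(site_pts) if len(site_pts) >= 2 else np.empty(0)
    ratio = d_site / d_glob if d_glob > 0 else np.nan
    return SiteSummary(
        site_area_fraction=frac,
        density_site_per_um2=d_site,
        density_global_per_um2=d_glob,
        density_ratio=ratio,
        nnd_site_nm=nnd_site,
        nnd_global_nm=nnd_global,
    )


def mass_count_table(samples: list[FootprintSample]) -> tuple[pd.DataFrame, dict]:
    """Per-spark (mass, count) scattergram table plus count summary.

    Summary: mean and SD (ddof=1) of counts and the Spearman rank
    correlation between spark mass and punctum count.
    """
    if len(samples) < 2:
        raise ValueError("at least 2 footprint samples are required")
    table = pd.DataFrame(
        {
            "spark_id": [s.spark_id for s in samples],
            "x_nm": [s.center_nm[0] for s in samples],
            "y_nm": [s.center_nm[1] for s in samples],
            "fwhm_um": [s.diameter_nm / 1000.0 for s in samples],
            "mass": [s.spark_mass for s in samples],
            "count": [s.count for s in samples],
            "mean_nnd_nm": [s.mean_nnd_nm if s.mean_nnd_nm is not None else np.nan for s in samples],
        }
    )
    counts = table["count"].to_numpy(dtype=float)
    if np.ptp(counts) > 0 and np.ptp(table["mass"].to_numpy()) > 0:
        rho = float(spearmanr(table["mass"], table["count"]).statistic)
    else:
        rho = np.nan
    summary = {
        "n_sparks": int(len(table)),
        "count_mean": float(counts.mean()),
        "count_sd": float(counts.std(ddof=1)),
        "mass_count_spearman": rho,
    }
    return table, summary


def nnd_site_vs_global(
    puncta: PunctaSet,
    samples: list[FootprintSample],
    bin_width_nm: float = NND_BIN_NM,
) -> dict:
    """Pooled within-footprint NNDs versus the cell-wide NND distribution.

    Footprints with fewer than two puncta contribute to count statistics
    but not to the NND pool (their within-window NND is undefined).
    Histogram tables share one binning (left edges, counts, percentages).
    """
    pts = puncta.points
    if len(pts) < 2:
        raise ValueError("at least 2 puncta are required for a global NND distribution")
    nnd_global = nearest_neighbour_distances(pts)
    pooled: list[np.ndarray] = []
    for s in samples:
        if s.count >= 2:
            pooled.append(nearest_neighbour_distances(pts[s.puncta_indices]))
    nnd_site = np.concatenate(pooled) if pooled else np.empty(0)
    top = max(nnd_global.max(), nnd_site.max() if len(nnd_site) else 0.0)
    edges = np.arange(0.0, top + 2 * bin_width_nm, bin_width_nm)
    h_glob, _ = np.histogram(nnd_global, bins=edges)
    h_site, _ = np.histogram(nnd_site, bins=edges) if len(nnd_site) else (np.zeros(len(edges) - 1, int), edges)
    hist = pd.DataFrame(
        {
            "bin_left_nm": edges[:-1],
            "site_count": h_site,
            "site_pct": 100.0 * h_site / max(h_site.sum(), 1),
            "global_count": h_glob,
            "global_pct": 100.0 * h_glob / max(h_glob.sum(), 1),
        }
    )
    return {
        "nnd_site_nm": nnd_site,
        "nnd_global_nm": nnd_global,
        "histogram": hist,
        "site_empty": len(nnd_site) == 0,
    }
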