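"""Punctum detection on rendered maps and spatial point statistics.

A punctum is a discrete labelling density in the rendered map, interpreted
as one or a few channels.  Detection: Otsu-relative thresholding of the
in-support pixels, 8-connected components, intensity-weighted centroids,
pixel-count areas.  The point statistics (nearest-neighbour distances,
region-conditioned densities) operate on centroid tables in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

from .rendering import RenderedMap


@dataclass
class PunctaSet:
    """Detected puncta: centroids (nm) and areas (nm^2), one area each."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["x_nm", "y_nm", "area_nm2"]))
    source_map: RenderedMap | None = None

    def __post_init__(self) -> None:
        required = {"x_nm", "y_nm", "area_nm2"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"puncta table requires columns {sorted(required)}")
        if len(self.table) and np.any(self.table["area_nm2"].to_numpy() <= 0):
            raise ValueError("puncta areas must be positive")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def points(self) -> np.ndarray:
        return self.table[["x_nm", "y_nm"]].to_numpy(dtype=float)

    @property
    def areas(self) -> np.ndarray:
        return self.table["area_nm2"].to_numpy(dtype=float)


def detect_puncta(
    rmap: RenderedMap,
    threshold_frac: float = 1.0,
    min_area_nm2: float = 100.0,
) -> PunctaSet:
    """Detect labelling puncta as bright connected components of the map.

    The threshold is ``threshold_frac`` times the Otsu level of the
    in-support (positive) pixels; components are 8-connected; components
    smaller than ``min_area_nm2`` (default 4 px at 5 nm/px) are treated as
    noise.  Centroids are intensity-weighted and reported in nm map
    coordinates; the area is the component pixel count times the pixel
    area.
    """
    px = rmap.pixels
    pos = px[px > 0]
    if pos.size == 0:
        return PunctaSet(source_map=rmap)
    thr = threshold_frac * float(threshold_otsu(pos))
    above = px > thr
    if not above.any():
        return PunctaSet(source_map=rmap)
    lbl, n = ndimage.label(above, structure=np.ones((3, 3), dtype=bool))
    idx = np.arange(1, n + 1)
    counts = ndimage.sum_labels(above, lbl, index=idx)
    area = counts * rmap.pixel_size_nm**2
    keep = area >= min_area_nm2
    if not keep.any():
        return PunctaSet(source_map=rmap)
    coms = ndimage.center_of_mass(px, lbl, index=idx[keep])
    coms = np.asarray(coms, dtype=float)  # (row, col), intensity-weighted
    x = rmap.origin_nm[0] + (coms[:, 1] + 0.5) * rmap.pixel_size_nm
    y = rmap.origin_nm[1] + (coms[:, 0] + 0.5) * rmap.pixel_size_nm
    table = pd.DataFrame({"x_nm": x, "y_nm": y, "area_nm2": area[keep]})
    return PunctaSet(table=table.reset_index(drop=True), source_map=rmap)


def area_fraction_below(puncta: PunctaSet, area_cut_nm2: float) -> float:
    """Fraction of puncta with area <= the cut (e.g. 2000 nm^2)."""
    if len(puncta) == 0:
        raise ValueError("empty puncta set")
    return float(np.mean(puncta.areas <= area_cut_nm2))


def nearest_neighbour_distances(points: np.ndarray) -> np.ndarray:
    """Per-point Euclidean distance to the closest other point."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("at least 2 points are required")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1]


def points_in_mask(
    points: np.ndarray, mask: np.ndarray, pixel_size_nm: float, origin_nm: tuple[float, float] = (0.0, 0.0)
) -> np.ndarray:
    """Boolean membership of nm points in a raster mask.

    A point maps to the pixel whose half-open square contains it; points on
    a boundary pixel count as inside.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    j = np.floor((pts[:, 0] - origin_nm[0]) / pixel_size_nm).astype(int)
    i = np.floor((pts[:, 1] - origin_nm[1]) / pixel_size_nm).astype(int)
    ok = (i >= 0) & (i < mask.shape[0]) & (j >= 0) & (j < mask.shape[1])
    inside = np.zeros(len(pts), dtype=bool)
    inside[ok] = mask[i[ok], j[ok]]
    return inside


def spatial_density(
    points: np.ndarray,
    mask: np.ndarray,
    pixel_size_nm: float,
    origin_nm: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Point density inside a mask, per um^2 of mask area."""
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("mask has zero area")
    area_um2 = n_px * (pixel_size_nm / 1000.0) ** 2
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return 0.0
    count = int(points_in_mask(pts, mask, pixel_size_nm, origin_nm).sum())
    return count / area_um2
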