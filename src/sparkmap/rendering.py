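"""Rendering of localization tables into super-resolution density maps.

A localization table (x, y in nm) is turned into a continuous density
image on a 5 nm/px grid via Delaunay triangulation: each vertex is assigned
the local point density 3 / (total area of its incident triangles), and the
density is linearly interpolated across each triangle.  Averaging renders
over several point sets jittered by the localization precision suppresses
the angular artefacts of a single triangulation.  The analysis always runs
on the real-valued map; 16-bit quantization is export-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib.tri as mtri
import numpy as np
import pandas as pd
from scipy import ndimage

from ._rng import substream
from .synthetic import FWHM_TO_SIGMA

DEFAULT_PIXEL_NM = 5.0
DEFAULT_PAD_NM = 250.0


@dataclass
class RenderedMap:
    """2D density image with physical georeferencing.

    ``origin_nm`` is the (x, y) of the top-left corner of pixel (0, 0); the
    center of pixel (i, j) is at origin + (j + 0.5, i + 0.5) * pixel_size.
    """

    pixels: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_NM
    origin_nm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if np.any(self.pixels < 0):
            raise ValueError("rendered map values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        h, w = self.pixels.shape
        x = self.origin_nm[0] + (np.arange(w) + 0.5) * self.pixel_size_nm
        y = self.origin_nm[1] + (np.arange(h) + 0.5) * self.pixel_size_nm
        return x, y

    def to_pixel_indices(self, x_nm: np.ndarray, y_nm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        j = np.floor((np.asarray(x_nm) - self.origin_nm[0]) / self.pixel_size_nm).astype(int)
        i = np.floor((np.asarray(y_nm) - self.origin_nm[1]) / self.pixel_size_nm).astype(int)
        return i, j


def _vertex_density(x: np.ndarray, y: np.ndarray) -> tuple[mtri.Triangulation, np.ndarray]:
    tri = mtri.Triangulation(x, y)
    t = tri.triangles
    ax, ay = x[t[:, 0]], y[t[:, 0]]
    bx, by = x[t[:, 1]], y[t[:, 1]]
    cx, cy = x[t[:, 2]], y[t[:, 2]]
    area = 0.5 * np.abs((bx - ax) * (cy - ay) - (cx - ax) * (by - ay))
    incident = np.zeros(len(x))
    for k in range(3):
        np.add.at(incident, t[:, k], area)
    with np.errstate(divide="ignore"):
        dens = np.where(incident > 0, 3.0 / incident, 0.0)
    return tri, dens


def render_delaunay(
    locs: pd.DataFrame,
    pixel_size_nm: float = DEFAULT_PIXEL_NM,
    n_jitter: int = 10,
    jitter_sigma_nm: float | None = None,
    pad_nm: float = DEFAULT_PAD_NM,
    extent: tuple[tuple[float, float], tuple[int, int]] | None = None,
    seed: int = 0,
) -> RenderedMap:
    """Render a localization table into a density map.

    ``jitter_sigma_nm`` defaults to the table's ``precision_nm`` column
    (median) or 10 nm.  ``n_jitter`` renders are averaged, each with the
    points perturbed by the localization precision; ``n_jitter=1`` with
    ``jitter_sigma_nm=0`` renders the raw triangulation.  The map extent is
    the bounding box of the points padded by ``pad_nm`` unless an explicit
    ``extent = (origin_nm, shape)`` is supplied.  Pixels outside the convex
    hull render as 0.
    """
    x = locs["x_nm"].to_numpy(dtype=float)
    y = locs["y_nm"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("at least 3 localizations are required to triangulate")
    if n_jitter < 1:
        raise ValueError("n_jitter must be >= 1")
    if jitter_sigma_nm is None:
        if "precision_nm" in locs.columns and len(locs):
            jitter_sigma_nm = float(np.median(locs["precision_nm"]))
        else:
            jitter_sigma_nm = 10.0
    if extent is not None:
        origin, shape = extent
        origin = (float(origin[0]), float(origin[1]))
        h, w = int(shape[0]), int(shape[1])
    else:
        x0 = x.min() - pad_nm
        y0 = y.min() - pad_nm
        w = int(np.ceil((x.max() + pad_nm - x0) / pixel_size_nm))
        h = int(np.ceil((y.max() + pad_nm - y0) / pixel_size_nm))
        origin = (x0, y0)
    gx = origin[0] + (np.arange(w) + 0.5) * pixel_size_nm
    gy = origin[1] + (np.arange(h) + 0.5) * pixel_size_nm
    gxx, gyy = np.meshgrid(gx, gy)
    rng = substream(seed, "render_jitter")
    accum = np.zeros((h, w))
    for _ in range(n_jitter):
        if jitter_sigma_nm > 0:
            xs = x + rng.normal(scale=jitter_sigma_nm, size=x.shape)
            ys = y + rng.normal(scale=jitter_sigma_nm, size=y.shape)
        else:
            xs, ys = x, y
        try:
            tri, dens = _vertex_density(xs, ys)
        except (ValueError, RuntimeError) as err:
            raise ValueError(f"triangulation failed (collinear or degenerate points): {err}") from err
        interp = mtri.LinearTriInterpolator(tri, dens)
        vals = interp(gxx, gyy)
        accum += np.ma.filled(vals, 0.0)
    pixels = np.clip(accum / n_jitter, 0.0, None)
    return RenderedMap(pixels=pixels, pixel_size_nm=pixel_size_nm, origin_nm=origin)


def quantize_16bit(rmap: RenderedMap, clip_percentile: float = 99.9) -> np.ndarray:
    """Linearly scale a density map onto uint16 [0, 65535] for export.

    The scale runs from 0 to the ``clip_percentile`` of the positive pixel
    values (values above clip saturate); the mapping is order-preserving
    below the clip.  An all-zero map exports as all zeros.
    """
    px = rmap.pixels
    pos = px[px > 0]
    if pos.size == 0:
        return np.zeros(px.shape, dtype=np.uint16)
    top = float(np.percentile(pos, clip_percentile))
    if top <= 0:
        return np.zeros(px.shape, dtype=np.uint16)
    scaled = np.clip(px / top, 0.0, 1.0) * 65535.0
    return np.round(scaled).astype(np.uint16)


def blur_to_resolution(
    image: np.ndarray, target_fwhm_nm: float, pixel_size_nm: float
) -> np.ndarray:
    """Convolve an image with a Gaussian PSF of the given FWHM.

    Used both to degrade super-resolution maps to confocal/TIRF resolution
    and inside the alignment stage.  Total intensity is conserved (up to
    edge truncation of the kernel).
    """
    if target_fwhm_nm <= 0:
        raise ValueError("target_fwhm_nm must be positive")
    sigma_px = target_fwhm_nm * FWHM_TO_SIGMA / pixel_size_nm
    return ndimage.gaussian_filter(np.asarray(image, dtype=float), sigma_px, mode="constant", cval=0.0)
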