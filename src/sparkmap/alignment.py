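"""Registration of the averaged Ca2+ image against the rendered map.

The diffraction-limited reference (the ~10-frame-averaged Ca2+ image) is
upscaled to the 5 nm map grid; a coarse, operator-style shift provides the
starting point; the fine alignment maximizes the cross-correlation between
the upscaled reference and the rendered map blurred down to the reference
resolution, with a sub-pixel peak from quadratic interpolation.  The
transform is a rigid 2D translation (dx, dy in nm) mapping Ca2+-frame
coordinates into map coordinates: x_map = x_ca + dx.

``simulate_alignment_error`` quantifies the registration error of this
whole chain on synthetic ground truth at a given PSF width and SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._rng import substream
from .rendering import RenderedMap, blur_to_resolution, render_delaunay
from . import synthetic
from .synthetic import Hotspot, apply_known_shift_table


@dataclass
class AlignmentTransform:
    """Rigid shift (nm) from Ca2+-image coordinates into map coordinates."""

    dx_nm: float
    dy_nm: float
    peak_correlation: float = np.nan
    method: str = "coarse"
    search_radius_nm: float = np.nan
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isfinite(self.peak_correlation) and not -1.0 - 1e-9 <= self.peak_correlation <= 1.0 + 1e-9:
            raise ValueError("peak_correlation must lie in [-1, 1]")


def coarse_align(user_shift_nm: tuple[float, float]) -> AlignmentTransform:
    """Record the operator-provided starting shift (from config, not a GUI)."""
    dx, dy = user_shift_nm
    return AlignmentTransform(dx_nm=float(dx), dy_nm=float(dy), method="coarse")


def upscale_reference(
    image: np.ndarray,
    from_pixel_nm: float,
    to_pixel_nm: float = 5.0,
    origin_nm: tuple[float, float] = (0.0, 0.0),
    match: RenderedMap | None = None,
) -> RenderedMap:
    """Bilinearly resample a diffraction-limited image onto the 5 nm grid.

    The physical extent is preserved: output pixel centers are mapped back
    into the input through the shared nm frame (extent arithmetic, never
    index arithmetic).  With ``match`` given, the output is sampled exactly
    on that map's grid so the two images can be correlated pixel-for-pixel;
    samples outside the input render as 0.
    """
    if from_pixel_nm <= to_pixel_nm:
        raise ValueError("upscaling requires from_pixel_nm > to_pixel_nm")
    image = np.asarray(image, dtype=float)
    if match is not None:
        gx, gy = match.pixel_centers()
        out_origin = match.origin_nm
        out_pixel = match.pixel_size_nm
    else:
        h, w = image.shape
        out_pixel = to_pixel_nm
        out_w = int(round(w * from_pixel_nm / to_pixel_nm))
        out_h = int(round(h * from_pixel_nm / to_pixel_nm))
        gx = origin_nm[0] + (np.arange(out_w) + 0.5) * to_pixel_nm
        gy = origin_nm[1] + (np.arange(out_h) + 0.5) * to_pixel_nm
        out_origin = origin_nm
    # continuous input pixel coordinates of the output pixel centers
    cj = (gx - origin_nm[0]) / from_pixel_nm - 0.5
    ci = (gy - origin_nm[1]) / from_pixel_nm - 0.5
    cjj, cii = np.meshgrid(cj, ci)
    out = ndimage.map_coordinates(image, [cii, cjj], order=1, mode="constant", cval=0.0)
    return RenderedMap(pixels=np.clip(out, 0.0, None), pixel_size_nm=out_pixel, origin_nm=out_origin)


def _quadratic_peak(c_m1: float, c_0: float, c_p1: float) -> float:
    denom = c_m1 - 2.0 * c_0 + c_p1
    if denom >= 0 or abs(denom) < 1e-30:
        return 0.0
    return float(np.clip(0.5 * (c_m1 - c_p1) / denom, -0.5, 0.5))


def _masked_ncc(
    a: np.ndarray,
    b: np.ndarray,
    ma: np.ndarray,
    mb: np.ndarray,
    row_window: tuple[int, int] | None = None,
    col_window: tuple[int, int] | None = None,
) -> tuple[np.ndarray, int, int]:
    """Normalized cross-correlation over the mask overlap at every lag.

    The value at lag u is the Pearson correlation of a and b(+u) over the
    pixels where both masks hold, so a flat plateau or the image envelope
    cannot bias the peak; lags with too little overlap return -inf.  The
    six required lag sums share FFTs, and each correlation plane is cropped
    to the requested lag window immediately to bound memory.

    Returns ``(cc, u_row0, u_col0)`` where ``cc[0, 0]`` corresponds to lag
    ``(u_row0, u_col0)`` in pixels.
    """
    from scipy import fft as sfft

    ha, wa = a.shape
    hb, wb = b.shape
    full_h, full_w = ha + hb - 1, wa + wb - 1
    r0, r1 = row_window if row_window else (0, full_h)
    c0, c1 = col_window if col_window else (0, full_w)
    r0, r1 = max(0, r0), min(full_h, r1)
    c0, c1 = max(0, c0), min(full_w, c1)
    sh = (sfft.next_fast_len(full_h), sfft.next_fast_len(full_w))
    a = np.where(ma, a, 0.0)
    b = np.where(mb, b, 0.0)

    fa = [sfft.rfft2(z, sh) for z in (ma.astype(float), a, a * a)]

    def xcorr(fp, fq):
        out = sfft.irfft2(fq * np.conj(fp), sh)
        out = np.roll(out, (ha - 1, wa - 1), axis=(0, 1))[:full_h, :full_w]
        return out[r0:r1, c0:c1].copy()

    # stream the b-side transforms one at a time to bound peak memory
    fb1 = sfft.rfft2(mb.astype(float), sh)
    n = xcorr(fa[0], fb1)
    sa = xcorr(fa[1], fb1)
    saa = xcorr(fa[2], fb1)
    del fb1
    fb2 = sfft.rfft2(b, sh)
    sb = xcorr(fa[0], fb2)
    x = xcorr(fa[1], fb2)
    del fb2
    fb3 = sfft.rfft2(b * b, sh)
    sbb = xcorr(fa[0], fb3)
    del fb3, fa

    n = np.round(n)
    min_overlap = 0.25 * min(ma.sum(), mb.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        num = x - sa * sb / n
        va = saa - sa**2 / n
        vb = sbb - sb**2 / n
        cc = num / np.sqrt(va * vb)
    bad = (n < max(min_overlap, 16)) | ~np.isfinite(cc)
    cc = np.where(bad, -np.inf, np.clip(cc, -1.0, 1.0))
    return cc, r0 - (ha - 1), c0 - (wa - 1)


def fine_align(
    reference: RenderedMap,
    rendered: RenderedMap,
    start: AlignmentTransform | None = None,
    search_radius_nm: float = 2000.0,
    target_fwhm_nm: float = 250.0,
) -> AlignmentTransform:
    """Cross-correlation refinement of the coarse shift.

    Both images must live on the same grid (use ``upscale_reference`` with
    ``match=rendered``).  The rendered map is blurred to the reference
    resolution, and the normalized cross-correlation — restricted at every
    lag to the overlap of the two supports (positive pixels), with per-lag
    mean and variance normalization — is evaluated over displacements
    within ``search_radius_nm`` of the starting shift; the peak is refined
    to sub-pixel precision by 3-point quadratic interpolation per axis.  A
    peak landing on the search boundary is flagged (possible under-search),
    as is a weak correlation peak.
    """
    if reference.pixels.shape != rendered.pixels.shape or reference.pixel_size_nm != rendered.pixel_size_nm:
        raise ValueError("reference and map must share one grid; resample the reference first")
    p = rendered.pixel_size_nm
    start = start or AlignmentTransform(0.0, 0.0)
    b = blur_to_resolution(rendered.pixels, target_fwhm_nm, p)
    a = reference.pixels.astype(float)
    ma = a > 0
    mb = b > b.max() * 1e-6
    if not ma.any() or not mb.any():
        raise ValueError("cannot correlate an empty image")
    # cc[u] = corr(a(x), b(x + u)): maximal where b == a shifted by u
    h, w = a.shape
    r_px = search_radius_nm / p
    row0, col0 = start.dy_nm / p, start.dx_nm / p
    pad = 3
    rw = (int(np.floor(row0 - r_px)) - pad + (h - 1), int(np.ceil(row0 + r_px)) + pad + 1 + (h - 1))
    cw = (int(np.floor(col0 - r_px)) - pad + (w - 1), int(np.ceil(col0 + r_px)) + pad + 1 + (w - 1))
    cc, ur0, uc0 = _masked_ncc(a, b, ma, mb, row_window=rw, col_window=cw)
    u_rows = ur0 + np.arange(cc.shape[0])
    u_cols = uc0 + np.arange(cc.shape[1])
    win = (np.abs(u_rows[:, None] - row0) <= r_px) & (np.abs(u_cols[None, :] - col0) <= r_px)
    if not win.any():
        raise ValueError("search window does not intersect the correlation plane")
    masked = np.where(win, cc, -np.inf)
    pk = np.unravel_index(int(np.argmax(masked)), cc.shape)
    flags: list[str] = []
    ir, ic = pk
    # boundary check against the search window
    edge_r = abs(u_rows[ir] - row0) >= np.floor(r_px)
    edge_c = abs(u_cols[ic] - col0) >= np.floor(r_px)
    if edge_r or edge_c:
        flags.append("peak_on_search_boundary")
    dr = dc = 0.0
    if 0 < ir < cc.shape[0] - 1 and np.isfinite(cc[ir - 1, ic]) and np.isfinite(cc[ir + 1, ic]):
        dr = _quadratic_peak(cc[ir - 1, ic], cc[ir, ic], cc[ir + 1, ic])
    if 0 < ic < cc.shape[1] - 1 and np.isfinite(cc[ir, ic - 1]) and np.isfinite(cc[ir, ic + 1]):
        dc = _quadratic_peak(cc[ir, ic - 1], cc[ir, ic], cc[ir, ic + 1])
    peak_val = float(cc[ir, ic])
    if peak_val < 0.2:
        flags.append("low_correlation")
    dy = (u_rows[ir] + dr) * p
    dx = (u_cols[ic] + dc) * p
    # the grids already share an origin, so the correlation displacement is
    # the full shift in the common frame
    return AlignmentTransform(
        dx_nm=float(dx),
        dy_nm=float(dy),
        peak_correlation=float(np.clip(peak_val, -1.0, 1.0)),
        method="fine",
        search_radius_nm=float(search_radius_nm),
        flags=flags,
    )


def apply_transform(sparks: pd.DataFrame, transform: AlignmentTransform) -> pd.DataFrame:
    """Map spark centroids (um, Ca2+ frame) into nm map coordinates.

    Appends ``x_nm``/``y_nm`` columns; FWHM is untouched.
    """
    out = sparks.copy()
    out["x_nm"] = out["x_um"] * 1000.0 + transform.dx_nm
    out["y_nm"] = out["y_um"] * 1000.0 + transform.dy_nm
    return out


def invert_transform(transform: AlignmentTransform) -> AlignmentTransform:
    return AlignmentTransform(
        dx_nm=-transform.dx_nm,
        dy_nm=-transform.dy_nm,
        peak_correlation=transform.peak_correlation,
        method=transform.method,
        search_radius_nm=transform.search_radius_nm,
    )


# ---------------------------------------------------------------------------
# alignment-error simulation
# ---------------------------------------------------------------------------

def _block_mean(image: np.ndarray, factor: int) -> np.ndarray:
    h = (image.shape[0] // factor) * factor
    w = (image.shape[1] // factor) * factor
    im = image[:h, :w]
    return im.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def simulate_alignment_error(
    psf_fwhm_nm: float = 250.0,
    snr: float | None = 17.0,
    n_iterations: int = 20,
    seed: int = 0,
    cell_radius_um: float = 3.0,
    density_per_um2: float = 13.4,
    max_shift_nm: float = 1000.0,
    coarse_perturbation_nm: float = 500.0,
    search_radius_nm: float = 2000.0,
    camera_pixel_nm: float = 100.0,
    map_pixel_nm: float = 5.0,
) -> np.ndarray:
    """Monte-Carlo estimate of the registration error of the full chain.

    Per iteration: a cell-scale punctum field is synthesized and rendered
    at 5 nm/px; the diffraction-limited Ca2+ reference is derived from the
    unshifted ground truth (blur to ``psf_fwhm_nm``, resample to the camera
    pixel, add Gaussian noise so mean in-cell signal / noise SD equals
    ``snr``); the map is re-rendered from the point table shifted by a
    random known displacement; the reference is upscaled, coarse-aligned at
    truth plus a uniform perturbation (the operator's error) and
    fine-aligned; the Euclidean error versus the known shift is recorded.

    ``snr=None`` (or ``inf``) disables noise.  Returns the per-iteration
    error array in nm.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    errors = np.empty(n_iterations)
    pixel_um = camera_pixel_nm / 1000.0
    factor = int(round(camera_pixel_nm / map_pixel_nm))
    for it in range(n_iterations):
        rng = substream(seed, "align_sim", index=it)
        sub = int(rng.integers(0, 2**31 - 1))
        frame_px = int(np.ceil(2.0 * cell_radius_um * 1.5 / pixel_um))
        mask = synthetic.gen_cell_mask(
            (frame_px, frame_px), cell_radius_um, irregularity=0.25, seed=sub, pixel_size_um=pixel_um
        )
        # a few hotspots give the map the internal structure real labelling has
        hot_centers = rng.uniform(
            frame_px * camera_pixel_nm * 0.35, frame_px * camera_pixel_nm * 0.65, size=(3, 2)
        )
        hotspots = tuple(Hotspot(center_nm=tuple(c), radius_nm=700.0, multiplier=4.0) for c in hot_centers)
        puncta = synthetic.gen_puncta_field(
            mask, density_per_um2, hotspots=hotspots, seed=sub, pixel_size_um=pixel_um
        )
        locs = synthetic.gen_localizations(
            puncta, mean_locs_per_punctum=20.0, precision_sigma_nm=10.0,
            false_rate_per_um2=1.0, mask=mask, pixel_size_um=pixel_um, seed=sub,
        )
        true_dx, true_dy = rng.uniform(-max_shift_nm, max_shift_nm, size=2)
        margin = max_shift_nm + 4.0 * camera_pixel_nm
        x0 = float(locs["x_nm"].min() - margin)
        y0 = float(locs["y_nm"].min() - margin)
        # snap the origin to the camera grid so block-averaging is exact
        x0 = np.floor(x0 / camera_pixel_nm) * camera_pixel_nm
        y0 = np.floor(y0 / camera_pixel_nm) * camera_pixel_nm
        w = int(np.ceil((locs["x_nm"].max() + margin - x0) / camera_pixel_nm)) * factor
        h = int(np.ceil((locs["y_nm"].max() + margin - y0) / camera_pixel_nm)) * factor
        extent = ((x0, y0), (h, w))
        base = render_delaunay(
            locs, pixel_size_nm=map_pixel_nm, n_jitter=1, jitter_sigma_nm=0.0, extent=extent, seed=sub
        )
        shifted_locs = apply_known_shift_table(locs, true_dx, true_dy)
        rmap = render_delaunay(
            shifted_locs, pixel_size_nm=map_pixel_nm, n_jitter=1, jitter_sigma_nm=0.0, extent=extent, seed=sub
        )
        ref_hi = blur_to_resolution(base.pixels, psf_fwhm_nm, map_pixel_nm)
        ref_cam = _block_mean(ref_hi, factor)
        if snr is not None and np.isfinite(snr):
            sig = float(ref_cam[ref_cam > ref_cam.max() * 0.05].mean())
            ref_cam = ref_cam + rng.normal(scale=sig / snr, size=ref_cam.shape)
        ref_up = upscale_reference(
            np.clip(ref_cam, 0.0, None), camera_pixel_nm, map_pixel_nm, origin_nm=(x0, y0), match=rmap
        )
        start = coarse_align(
            (
                true_dx + rng.uniform(-coarse_perturbation_nm, coarse_perturbation_nm),
                true_dy + rng.uniform(-coarse_perturbation_nm, coarse_perturbation_nm),
            )
        )
        fine = fine_align(ref_up, rmap, start=start, search_radius_nm=search_radius_nm)
        errors[it] = float(np.hypot(fine.dx_nm - true_dx, fine.dy_nm - true_dy))
    return errors
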