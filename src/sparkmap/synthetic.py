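"""Synthetic paired TIRF / localization-map data with known ground truth.

Generates the two imaging modalities the correlative pipeline consumes:

* a TIRF movie of a cell loaded with a Ca2+ indicator in which localized,
  transient Ca2+ sparks (2D Gaussian spatial profiles) occur on a noisy
  baseline, and
* a single-molecule localization table emulating a dSTORM acquisition of
  ER Ca2+-release channel labelling: a field of channel puncta with a
  homogeneous background density plus circular hotspot regions of elevated
  density, each punctum emitting one or more localizations.

A rigid shift between the two coordinate frames (the physical re-mounting
of the dish between acquisitions) is part of the ground truth, so alignment
can be validated end to end.

Coordinate convention (shared by every module): continuous (x, y) in nm,
origin at the top-left corner of the image, x along columns and y along
rows.  Pixel (i, j) covers the half-open square
[j*p, (j+1)*p) x [i*p, (i+1)*p); its center sits at (+0.5)*p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._rng import substream

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM / 2.3548


@dataclass(frozen=True)
class Hotspot:
    """Circular region of elevated punctum density.

    center_nm : (x, y) of the hotspot center.
    radius_nm : hotspot radius.
    multiplier : local density relative to the cell-wide background, >= 1.
    """

    center_nm: tuple[float, float]
    radius_nm: float
    multiplier: float

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("hotspot radius must be positive")
        if self.multiplier < 1:
            raise ValueError("hotspot density multiplier must be >= 1")


@dataclass
class MovieParams:
    """Acquisition parameters of the synthetic TIRF movie.

    frame_interval_ms : camera frame interval (100 ms frame rate by default).
    pixel_size_um : projected camera pixel size (0.1 um class).
    psf_fwhm_nm : diffraction-limited resolution (~250 nm); applied to the
        static cell image so that the cell outline is realistically soft.
    snr : signal-to-noise ratio of the *10-frame-averaged* image, defined as
        the mean baseline-subtracted spark peak amplitude divided by the
        noise SD of the averaged image.
    baseline_level : indicator fluorescence inside the cell, in counts.
    offset_level : camera offset outside the cell, in counts.
    n_frames : number of frames.
    rise_frames / decay_tau_frames : spark kinetics (1-frame rise, exponential
        decay); only the peak frame is analysed downstream.
    """

    frame_interval_ms: float = 100.0
    pixel_size_um: float = 0.1
    psf_fwhm_nm: float = 250.0
    snr: float = 17.0
    baseline_level: float = 1000.0
    offset_level: float = 100.0
    n_frames: int = 120
    rise_frames: int = 1
    decay_tau_frames: float = 2.0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.psf_fwhm_nm <= 0:
            raise ValueError("psf_fwhm_nm must be positive")
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline has to recover."""

    cell_mask: np.ndarray
    pixel_size_um: float
    spark_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    puncta_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    hotspots: tuple[Hotspot, ...] = ()
    applied_shift_nm: tuple[float, float] = (0.0, 0.0)
    seed: int = 0


# ---------------------------------------------------------------------------
# cell mask
# ---------------------------------------------------------------------------

def gen_cell_mask(
    shape: tuple[int, int],
    radius_um: float,
    irregularity: float = 0.2,
    seed: int = 0,
    pixel_size_um: float = 0.1,
) -> np.ndarray:
    """Rasterize a single, closed, star-convex cell outline.

    The boundary is a circle of the given radius modulated by a few
    low-order random Fourier modes whose peak relative excursion equals
    ``irregularity``.  Returns a boolean mask; deterministic in ``seed``.
    """
    if not 0 <= irregularity < 1:
        raise ValueError("irregularity must lie in [0, 1)")
    h, w = shape
    max_r_px = radius_um * (1.0 + irregularity) / pixel_size_um
    if max_r_px >= min(h, w) / 2.0:
        raise ValueError(
            f"cell radius {radius_um} um (+irregularity) does not fit in a "
            f"{h}x{w} frame at {pixel_size_um} um/px"
        )
    rng = substream(seed, "cell_mask")
    theta = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    mod = np.zeros_like(theta)
    if irregularity > 0:
        for mode in range(2, 7):
            amp = rng.normal()
            phase = rng.uniform(0, 2 * np.pi)
            mod += amp * np.cos(mode * theta + phase)
        peak = np.max(np.abs(mod))
        if peak > 0:
            mod *= irregularity / peak
    r = radius_um / pixel_size_um * (1.0 + mod)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # half-open pixel convention: a pixel is inside when its center is
    ii, jj = np.mgrid[0:h, 0:w]
    ang = np.arctan2(ii - cy, jj - cx) % (2 * np.pi)
    r_at = np.interp(ang, theta, r, period=2 * np.pi)
    mask = (ii - cy) ** 2 + (jj - cx) ** 2 <= r_at**2
    # keep the largest connected component (star-convexity makes this a no-op
    # in practice, but guards against degenerate modulation)
    lbl, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, lbl, index=np.arange(1, n + 1))
        mask = lbl == (1 + int(np.argmax(sizes)))
    return mask


# ---------------------------------------------------------------------------
# puncta field
# ---------------------------------------------------------------------------

def _points_in_mask(xy_nm: np.ndarray, mask: np.ndarray, pixel_nm: float) -> np.ndarray:
    j = np.floor(xy_nm[:, 0] / pixel_nm).astype(int)
    i = np.floor(xy_nm[:, 1] / pixel_nm).astype(int)
    ok = (i >= 0) & (i < mask.shape[0]) & (j >= 0) & (j < mask.shape[1])
    inside = np.zeros(len(xy_nm), dtype=bool)
    inside[ok] = mask[i[ok], j[ok]]
    return inside


def _dart_throw(
    n_target: int,
    sampler,
    accepted: list[np.ndarray],
    min_sep: float,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> list[np.ndarray]:
    """Sequentially accept points from `sampler`, rejecting any candidate
    closer than `min_sep` to an already accepted point (hard-core thinning
    that preserves the target count)."""
    if min_sep <= 0:
        for _ in range(n_target):
            p = sampler(rng)
            if p is not None:
                accepted.append(p)
        return accepted
    cell = min_sep  # spatial hash with cell size = min separation
    grid: dict[tuple[int, int], list[int]] = {}
    for k, p in enumerate(accepted):
        grid.setdefault((int(p[0] // cell), int(p[1] // cell)), []).append(k)
    placed = 0
    tries = 0
    while placed < n_target and tries < max_tries * max(n_target, 1):
        tries += 1
        p = sampler(rng)
        if p is None:
            continue
        gx, gy = int(p[0] // cell), int(p[1] // cell)
        clash = False
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for k in grid.get((gx + dx, gy + dy), ()):
                    q = accepted[k]
                    if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < min_sep**2:
                        clash = True
                        break
                if clash:
                    break
            if clash:
                break
        if clash:
            continue
        grid.setdefault((gx, gy), []).append(len(accepted))
        accepted.append(p)
        placed += 1
    return accepted


def gen_puncta_field(
    mask: np.ndarray,
    global_density_per_um2: float,
    hotspots: tuple[Hotspot, ...] = (),
    cluster_sigma_nm: float = 0.0,
    cluster_mean: float = 1.0,
    min_separation_nm: float = 60.0,
    seed: int = 0,
    pixel_size_um: float = 0.1,
) -> pd.DataFrame:
    """Sample channel-punctum centroids inside a cell mask.

    Background puncta follow a homogeneous Poisson process of intensity
    ``global_density_per_um2``; inside each hotspot, extra points raise the
    local intensity to ``multiplier`` times the background.  A hard-core
    minimum separation (default 60 nm, the scale at which two labelling
    densities are no longer resolvable as distinct puncta) is enforced by
    dart throwing; at the densities used here it does not alter counts.
    Optional Thomas-style clustering replaces each sampled parent by
    ``1 + Poisson(cluster_mean - 1)`` offspring scattered with SD
    ``cluster_sigma_nm``.

    Returns a DataFrame with ``x_nm, y_nm, hotspot_member``.
    """
    if global_density_per_um2 <= 0:
        raise ValueError("global density must be positive")
    if not mask.any():
        raise ValueError("cell mask is empty")
    pixel_nm = pixel_size_um * 1000.0
    area_um2 = float(mask.sum()) * pixel_size_um**2
    rng = substream(seed, "puncta_field")
    h, w = mask.shape

    def sample_in_mask(r: np.random.Generator):
        for _ in range(64):
            p = np.array([r.uniform(0, w * pixel_nm), r.uniform(0, h * pixel_nm)])
            if _points_in_mask(p[None, :], mask, pixel_nm)[0]:
                return p
        return None

    accepted: list[np.ndarray] = []
    n_base = rng.poisson(global_density_per_um2 * area_um2)
    accepted = _dart_throw(n_base, sample_in_mask, accepted, min_separation_nm, rng)

    hot = np.array([h_.center_nm + (h_.radius_nm,) for h_ in hotspots]).reshape(-1, 3)
    for spot in hotspots:
        cx, cy = spot.center_nm
        # hotspot area clipped to the mask, by MC over the disc
        probe = rng.uniform(-1, 1, size=(512, 2))
        probe = probe[(probe**2).sum(axis=1) <= 1.0] * spot.radius_nm + (cx, cy)
        frac_in = _points_in_mask(probe, mask, pixel_nm).mean() if len(probe) else 0.0
        area_spot = np.pi * (spot.radius_nm / 1000.0) ** 2 * frac_in
        n_extra = rng.poisson((spot.multiplier - 1.0) * global_density_per_um2 * area_spot)

        def sample_in_spot(r: np.random.Generator, cx=cx, cy=cy, rad=spot.radius_nm):
            for _ in range(64):
                u = r.uniform(-1, 1, size=2)
                if (u**2).sum() <= 1.0:
                    p = np.array([cx + u[0] * rad, cy + u[1] * rad])
                    if _points_in_mask(p[None, :], mask, pixel_nm)[0]:
                        return p
            return None

        accepted = _dart_throw(n_extra, sample_in_spot, accepted, min_separation_nm, rng)

    pts = np.array(accepted).reshape(-1, 2)

    if cluster_mean > 1.0 or (cluster_sigma_nm > 0 and cluster_mean != 1.0):
        children = []
        for p in pts:
            n_off = 1 + rng.poisson(max(cluster_mean - 1.0, 0.0))
            off = p + rng.normal(scale=cluster_sigma_nm, size=(n_off, 2))
            children.append(off)
        pts = np.vstack(children) if children else pts
        pts = pts[_points_in_mask(pts, mask, pixel_nm)]

    member = np.zeros(len(pts), dtype=bool)
    for k in range(len(hot)):
        d2 = (pts[:, 0] - hot[k, 0]) ** 2 + (pts[:, 1] - hot[k, 1]) ** 2
        member |= d2 <= hot[k, 2] ** 2
    return pd.DataFrame({"x_nm": pts[:, 0], "y_nm": pts[:, 1], "hotspot_member": member})


# ---------------------------------------------------------------------------
# localizations
# ---------------------------------------------------------------------------

def gen_localizations(
    puncta: pd.DataFrame,
    mean_locs_per_punctum: float = 20.0,
    precision_sigma_nm: float = 10.0,
    false_rate_per_um2: float = 0.0,
    mask: np.ndarray | None = None,
    pixel_size_um: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit single-molecule localizations from a punctum field.

    Each punctum produces ``1 + Poisson(mean - 1)`` localizations scattered
    with Gaussian jitter ``precision_sigma_nm`` (so every punctum is
    represented at least once and the mean count is exact).  Nonspecific
    localizations are added as a uniform Poisson field at
    ``false_rate_per_um2`` inside the cell mask.
    """
    if precision_sigma_nm < 0:
        raise ValueError("precision_sigma_nm must be non-negative")
    if false_rate_per_um2 < 0:
        raise ValueError("false_rate_per_um2 must be non-negative")
    if mean_locs_per_punctum < 1:
        raise ValueError("mean_locs_per_punctum must be >= 1")
    rng = substream(seed, "localizations")
    xs, ys = [], []
    pts = puncta[["x_nm", "y_nm"]].to_numpy(dtype=float)
    if len(pts):
        counts = 1 + rng.poisson(mean_locs_per_punctum - 1.0, size=len(pts))
        rep = np.repeat(pts, counts, axis=0)
        jit = rng.normal(scale=precision_sigma_nm, size=rep.shape) if precision_sigma_nm > 0 else 0.0
        rep = rep + jit
        xs.append(rep[:, 0])
        ys.append(rep[:, 1])
    if false_rate_per_um2 > 0:
        if mask is None:
            raise ValueError("a cell mask is required to place false localizations")
        pixel_nm = pixel_size_um * 1000.0
        area_um2 = float(mask.sum()) * pixel_size_um**2
        n_false = rng.poisson(false_rate_per_um2 * area_um2)
        got = 0
        fx, fy = [], []
        h, w = mask.shape
        while got < n_false:
            cand = np.column_stack(
                [rng.uniform(0, w * pixel_nm, size=4 * n_false), rng.uniform(0, h * pixel_nm, size=4 * n_false)]
            )
            cand = cand[_points_in_mask(cand, mask, pixel_nm)]
            take = cand[: n_false - got]
            fx.append(take[:, 0])
            fy.append(take[:, 1])
            got += len(take)
        xs.append(np.concatenate(fx) if fx else np.empty(0))
        ys.append(np.concatenate(fy) if fy else np.empty(0))
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    return pd.DataFrame({"x_nm": x, "y_nm": y, "precision_nm": np.full(len(x), float(precision_sigma_nm))})


# ---------------------------------------------------------------------------
# spark movie
# ---------------------------------------------------------------------------

def gen_spark_movie(
    mask: np.ndarray,
    params: MovieParams | None = None,
    spark_sites_um: np.ndarray | None = None,
    spark_table: pd.DataFrame | None = None,
    rate_per_frame: float = 0.4,
    fwhm_range_um: tuple[float, float] = (0.6, 1.8),
    amplitude_range: tuple[float, float] = (1.5, 3.0),
    site_jitter_um: float = 0.05,
    n_quiet_frames: int = 12,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a TIRF movie of Ca2+ sparks on a noisy cellular baseline.

    Each spark is a symmetric 2D Gaussian (FWHM drawn from
    ``fwhm_range_um``, peak amplitude F/F0 from ``amplitude_range``) with a
    1-frame rise and exponential decay.  When ``spark_sites_um`` is given,
    sparks occur only at those sites (with a small positional jitter),
    ``rate_per_frame`` counting expected sparks per site per frame;
    otherwise spark centroids are uniform inside the mask and the rate is
    cell-wide.  ``spark_table`` bypasses the random draws entirely and
    injects the given events (columns ``x_um, y_um, t_frame`` and
    optionally ``fwhm_um, amplitude``), for controlled recovery
    experiments.  The default width range spans the central part of the
    downstream 0.5-2.0 um retention band so that boundary censoring by the
    width filter does not confound recovery statistics.  Gaussian read-out noise is scaled so the SNR of the 10-frame
    averaged image equals ``params.snr``, with SNR defined as mean spark
    peak amplitude (counts above baseline) over averaged-image noise SD.

    The first ``n_quiet_frames`` frames are kept spark-free so a clean
    diffraction-limited reference image can be averaged from them.

    Returns ``(movie, spark_truth)`` with the movie as float32 (T, H, W)
    and truth columns ``x_um, y_um, t_frame, fwhm_um, amplitude``.
    """
    params = params or MovieParams()
    if rate_per_frame < 0:
        raise ValueError("rate_per_frame must be >= 0")
    rng = substream(seed, "spark_movie")
    h, w = mask.shape
    p_um = params.pixel_size_um
    t_total = params.n_frames

    # static cell image: baseline inside the cell, camera offset outside,
    # softened by the optical PSF
    static = np.where(mask, params.baseline_level, 0.0)
    psf_sigma_px = params.psf_fwhm_nm * FWHM_TO_SIGMA / (p_um * 1000.0)
    static = ndimage.gaussian_filter(static, psf_sigma_px) + params.offset_level

    # draw spark truth
    records = []
    fixed: list[tuple[float, float]] = []
    frames = np.arange(n_quiet_frames, max(t_total - 3, n_quiet_frames))
    if spark_table is not None:
        for _, r in spark_table.iterrows():
            records.append((float(r["x_um"]), float(r["y_um"]), int(r["t_frame"])))
            fixed.append(
                (
                    float(r["fwhm_um"]) if "fwhm_um" in spark_table.columns else np.nan,
                    float(r["amplitude"]) if "amplitude" in spark_table.columns else np.nan,
                )
            )
    elif spark_sites_um is not None and len(spark_sites_um):
        for sx, sy in np.asarray(spark_sites_um, dtype=float):
            for t in frames:
                for _ in range(rng.poisson(rate_per_frame)):
                    records.append(
                        (
                            sx + rng.normal(scale=site_jitter_um),
                            sy + rng.normal(scale=site_jitter_um),
                            int(t),
                        )
                    )
    elif rate_per_frame > 0:
        in_i, in_j = np.nonzero(mask)
        for t in frames:
            for _ in range(rng.poisson(rate_per_frame)):
                k = rng.integers(len(in_i))
                records.append(
                    (
                        (in_j[k] + rng.uniform()) * p_um,
                        (in_i[k] + rng.uniform()) * p_um,
                        int(t),
                    )
                )
    truth_rows = []
    movie = np.broadcast_to(static, (t_total, h, w)).astype(np.float64).copy()
    yy, xx = np.mgrid[0:h, 0:w]
    xc_um = (xx + 0.5) * p_um
    yc_um = (yy + 0.5) * p_um
    for k, (sx, sy, t0) in enumerate(records):
        fwhm = rng.uniform(*fwhm_range_um)
        amp = rng.uniform(*amplitude_range)
        if k < len(fixed):
            if np.isfinite(fixed[k][0]):
                fwhm = fixed[k][0]
            if np.isfinite(fixed[k][1]):
                amp = fixed[k][1]
        sig = fwhm * FWHM_TO_SIGMA
        prof = np.exp(-(((xc_um - sx) ** 2 + (yc_um - sy) ** 2) / (2.0 * sig**2)))
        peak_counts = params.baseline_level * (amp - 1.0)
        for dt in range(0, min(12, t_total - t0)):
            if dt == 0:
                k_t = 1.0  # peak on the detection frame after a 1-frame rise
            else:
                k_t = np.exp(-dt / params.decay_tau_frames)
            movie[t0 + dt] += peak_counts * prof * k_t
        truth_rows.append((sx, sy, t0, fwhm, amp))
    spark_truth = pd.DataFrame(truth_rows, columns=["x_um", "y_um", "t_frame", "fwhm_um", "amplitude"])

    # noise scaled to the averaged-image SNR definition
    mean_amp = 0.5 * (amplitude_range[0] + amplitude_range[1])
    signal_counts = params.baseline_level * (mean_amp - 1.0)
    sigma_frame = np.sqrt(10.0) * signal_counts / params.snr
    movie += rng.normal(scale=sigma_frame, size=movie.shape)
    return movie.astype(np.float32), spark_truth


# ---------------------------------------------------------------------------
# known shifts
# ---------------------------------------------------------------------------

def apply_known_shift_table(table: pd.DataFrame, dx_nm: float, dy_nm: float) -> pd.DataFrame:
    """Rigidly translate a point table (exact arithmetic on coordinates)."""
    out = table.copy()
    out["x_nm"] = out["x_nm"] + dx_nm
    out["y_nm"] = out["y_nm"] + dy_nm
    return out


def apply_known_shift_image(
    image: np.ndarray, dx_nm: float, dy_nm: float, pixel_size_nm: float, order: int = 1
) -> np.ndarray:
    """Rigidly translate an image by (dx, dy) nm with spline interpolation.

    Integer-pixel shifts are exact translations; sub-pixel shifts use
    bilinear interpolation by default.  Content shifted in from outside the
    frame is zero.
    """
    return ndimage.shift(
        image.astype(float), (dy_nm / pixel_size_nm, dx_nm / pixel_size_nm), order=order, mode="constant", cval=0.0
    )


# ---------------------------------------------------------------------------
# full paired dataset
# ---------------------------------------------------------------------------

@dataclass
class CorrelativeDatasetParams:
    """Study conditions for a paired spark-movie / localization dataset.

    Defaults emulate a DRG-soma-like TIRF field: a ~7 um-radius cell in a
    ~15 um field at 0.1 um/px, a cell-wide punctum density of 13.4 um^-2,
    and a small number of release-site hotspots whose density is 4x the
    background (the observed enrichment regime is ~3.8-5x).  Sparks are
    generated at the hotspot centers so that enrichment recovery can be
    validated against a known multiplier.  Spark FWHM is kept commensurate
    with the hotspot diameter (release sites set the spark length scale;
    spark width is insensitive to stimulation).
    """

    frame_shape: tuple[int, int] = (160, 160)
    cell_radius_um: float = 6.5
    irregularity: float = 0.15
    pixel_size_um: float = 0.1
    global_density_per_um2: float = 13.4
    n_hotspots: int = 3
    hotspot_radius_nm: float = 800.0
    hotspot_multiplier: float = 4.0
    min_separation_nm: float = 60.0
    mean_locs_per_punctum: float = 20.0
    precision_sigma_nm: float = 10.0
    false_rate_per_um2: float = 1.0
    spark_rate_per_site_per_frame: float = 0.05
    fwhm_range_um: tuple[float, float] = (0.9, 1.2)
    amplitude_range: tuple[float, float] = (1.5, 3.0)
    shift_nm: tuple[float, float] = (850.0, -620.0)
    movie: MovieParams = field(default_factory=MovieParams)


@dataclass
class CorrelativeDataset:
    movie: np.ndarray
    localizations: pd.DataFrame
    truth: GroundTruth
    params: CorrelativeDatasetParams


def _place_hotspots(
    mask: np.ndarray, params: CorrelativeDatasetParams, rng: np.random.Generator
) -> tuple[Hotspot, ...]:
    """Drop non-overlapping hotspots well inside the cell."""
    pixel_nm = params.pixel_size_um * 1000.0
    eroded = ndimage.binary_erosion(
        mask, iterations=max(1, int(np.ceil((params.hotspot_radius_nm + 300.0) / pixel_nm)))
    )
    ii, jj = np.nonzero(eroded if eroded.any() else mask)
    centers: list[tuple[float, float]] = []
    guard = 0
    while len(centers) < params.n_hotspots and guard < 10000:
        guard += 1
        k = rng.integers(len(ii))
        cx = (jj[k] + rng.uniform()) * pixel_nm
        cy = (ii[k] + rng.uniform()) * pixel_nm
        if all(
            (cx - ox) ** 2 + (cy - oy) ** 2 > (3.0 * params.hotspot_radius_nm) ** 2 for ox, oy in centers
        ):
            centers.append((cx, cy))
    return tuple(
        Hotspot(center_nm=c, radius_nm=params.hotspot_radius_nm, multiplier=params.hotspot_multiplier)
        for c in centers
    )


def simulate_correlative_dataset(
    params: CorrelativeDatasetParams | None = None, seed: int = 0
) -> CorrelativeDataset:
    """Generate a fully paired dataset: movie, localization table, truth.

    The localization table lives in the dSTORM frame, i.e. the puncta
    coordinates shifted by ``params.shift_nm`` relative to the Ca2+ frame.
    """
    params = params or CorrelativeDatasetParams()
    rng = substream(seed, "dataset")
    mask = gen_cell_mask(
        params.frame_shape,
        params.cell_radius_um,
        params.irregularity,
        seed=seed,
        pixel_size_um=params.pixel_size_um,
    )
    hotspots = _place_hotspots(mask, params, rng)
    puncta = gen_puncta_field(
        mask,
        params.global_density_per_um2,
        hotspots=hotspots,
        min_separation_nm=params.min_separation_nm,
        seed=seed,
        pixel_size_um=params.pixel_size_um,
    )
    locs_ca_frame = gen_localizations(
        puncta,
        mean_locs_per_punctum=params.mean_locs_per_punctum,
        precision_sigma_nm=params.precision_sigma_nm,
        false_rate_per_um2=params.false_rate_per_um2,
        mask=mask,
        pixel_size_um=params.pixel_size_um,
        seed=seed,
    )
    localizations = apply_known_shift_table(locs_ca_frame, *params.shift_nm)
    sites_um = np.array([[s.center_nm[0] / 1000.0, s.center_nm[1] / 1000.0] for s in hotspots])
    movie, spark_truth = gen_spark_movie(
        mask,
        params=params.movie,
        spark_sites_um=sites_um if len(sites_um) else None,
        rate_per_frame=params.spark_rate_per_site_per_frame,
        fwhm_range_um=params.fwhm_range_um,
        amplitude_range=params.amplitude_range,
        seed=seed,
    )
    truth = GroundTruth(
        cell_mask=mask,
        pixel_size_um=params.pixel_size_um,
        spark_truth=spark_truth,
        puncta_truth=puncta,
        hotspots=hotspots,
        applied_shift_nm=params.shift_nm,
        seed=seed,
    )
    return CorrelativeDataset(movie=movie, localizations=localizations, truth=truth, params=params)
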