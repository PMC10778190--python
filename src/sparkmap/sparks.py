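"""Ca2+ spark detection, localization, Gaussian fitting and quantification.

The stage consumes a TIRF movie (T, H, W) and produces a per-spark table:
centroid (x, y in um), peak frame, spatial FWHM of a symmetric 2D Gaussian
fit to the normalized peak frame, amplitude F/F0, goodness of fit R^2 and
the spark mass, a scalar proxy for total Ca2+ released computed as
amplitude x FWHM x 1.206.

Pipeline: per-pixel temporal-percentile baseline F0 -> normalized signal
dF/F0 = (F - F0)/F0 -> spatiotemporal Gaussian smoothing -> thresholding at
k_sigma times the smoothed noise SD -> connected suprathreshold voxels
merged into candidates (brightest voxel wins) -> 2D Gaussian fit on each
candidate's peak frame -> width/R^2 filtering (0.5 um <= FWHM <= 2.0 um,
R^2 >= 0.5) -> duplicate suppression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.stats import norm

from .synthetic import FWHM_TO_SIGMA

SPARK_MASS_FACTOR = 1.206

SPARK_COLUMNS = ["x_um", "y_um", "t_frame", "fwhm_um", "amplitude", "r2", "mass"]


@dataclass
class BaselineMap:
    """Per-pixel baseline F0 and noise estimate of a spark movie."""

    f0: np.ndarray
    noise_sd_map: np.ndarray
    noise_sd: float

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.f0)):
            raise ValueError("baseline contains non-finite values")


@dataclass
class SparkEvent:
    x_um: float
    y_um: float
    t_frame: int
    fwhm_um: float
    amplitude: float
    r2: float
    mass: float
    valid: bool = True


def estimate_baseline(movie: np.ndarray, percentile: float = 20.0) -> BaselineMap:
    """Estimate the per-pixel baseline F0 and the frame noise SD.

    F0 is a temporal low percentile (default 20th), robust against sparks,
    corrected for the downward bias a low percentile suffers on Gaussian
    noise: for noise SD s the q-th percentile of baseline + noise sits at
    baseline + z_q s, so z_q s is subtracted back.  The per-pixel noise SD
    comes from frame-to-frame first differences via the median absolute
    deviation (sparks touch too few consecutive-frame pairs to move a
    median).
    """
    movie = np.asarray(movie, dtype=np.float64)
    if movie.ndim != 3 or movie.shape[0] < 20:
        raise ValueError("movie must be (T, H, W) with at least 20 frames")
    if not movie.any():
        raise ValueError("movie is identically zero")
    diffs = np.diff(movie, axis=0)
    mad = np.median(np.abs(diffs - np.median(diffs, axis=0)), axis=0)
    noise_map = mad / 0.6744897501960817 / np.sqrt(2.0)
    q = percentile / 100.0
    f0 = np.percentile(movie, percentile, axis=0) - norm.ppf(q) * noise_map
    scalar = float(np.median(noise_map))
    return BaselineMap(f0=f0, noise_sd_map=noise_map, noise_sd=scalar)


def detect_candidates(
    movie: np.ndarray,
    baseline: BaselineMap,
    k_sigma: float = 3.8,
    smooth_sigma: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mask: np.ndarray | None = None,
    peak_footprint: tuple[int, int] = (2, 5),
) -> list[tuple[int, int, int]]:
    """Find spark seed voxels as local maxima of smoothed dF/F0.

    The normalized movie is smoothed with a Gaussian kernel (sigma in
    (frames, rows, cols)) and thresholded at ``k_sigma`` times the robust
    SD of the smoothed signal.  Every suprathreshold voxel that is the
    maximum of its spatiotemporal neighbourhood (``peak_footprint`` =
    (frames, pixels) half-widths) becomes a candidate, so simultaneous
    sparks whose suprathreshold regions touch are still seeded separately.

    Returns a list of ``(t, i, j)`` seeds (frame, row, col), brightest
    first.
    """
    movie = np.asarray(movie, dtype=np.float64)
    f0 = np.maximum(baseline.f0, 1e-9)
    dff = (movie - f0[None]) / f0[None]
    if mask is not None:
        dff = dff * mask[None]
    sm = ndimage.gaussian_filter(dff, sigma=(smooth_sigma[0], smooth_sigma[1], smooth_sigma[2]))
    sel = sm[:, mask] if mask is not None else sm.reshape(len(sm), -1)
    med = np.median(sel)
    sd_sm = float(np.median(np.abs(sel - med)) / 0.6744897501960817)
    thr = med + k_sigma * sd_sm
    above = sm > thr
    if not above.any():
        return []
    # one candidate per suprathreshold local maximum: simultaneous sparks a
    # few um apart can share one connected component at this threshold, so
    # a component is split at its distinct peaks (separated by at least the
    # peak footprint); re-detections of one spark are merged downstream
    ft, fs = peak_footprint
    footprint = np.ones((2 * ft + 1, 2 * fs + 1, 2 * fs + 1), dtype=bool)
    is_peak = (sm == ndimage.maximum_filter(sm, footprint=footprint)) & above
    tt, ii, jj = np.nonzero(is_peak)
    order = np.argsort(sm[tt, ii, jj])[::-1]
    # exact ties (e.g. a symmetric peak straddling two pixels) can mark
    # adjacent voxels as maxima of each other's window; keep one per
    # footprint-sized neighbourhood, brightest first
    seeds: list[tuple[int, int, int]] = []
    for k in order:
        t, i, j = int(tt[k]), int(ii[k]), int(jj[k])
        if any(abs(t - t2) <= ft and abs(i - i2) <= fs and abs(j - j2) <= fs for t2, i2, j2 in seeds):
            continue
        seeds.append((t, i, j))
    return seeds


def spark_mass(amplitude, fwhm_um, cubic: bool = False):
    """Spark mass: amplitude (F/F0) x FWHM (um) x 1.206.

    The literature formula behind the 1.206 factor treats spark mass as a
    volume proxy (amplitude x FWHM^3); ``cubic=True`` exposes that variant.
    The linear-in-FWHM product is the default output.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    fwhm_um = np.asarray(fwhm_um, dtype=float)
    if np.any(amplitude <= 0) or np.any(fwhm_um <= 0):
        raise ValueError("amplitude and FWHM must be positive")
    w = fwhm_um**3 if cubic else fwhm_um
    out = amplitude * w * SPARK_MASS_FACTOR
    return float(out) if out.ndim == 0 else out


def _gauss2d(coords, height, x0, y0, sigma, offset):
    x, y = coords
    return offset + height * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2.0 * sigma**2))


def fit_spark(
    movie: np.ndarray,
    baseline: BaselineMap,
    seed_event: tuple[int, int, int],
    pixel_size_um: float = 0.1,
    roi_halfwidth_um: float = 4.0,
    fit_smooth_sigma_px: float = 1.0,
    mask: np.ndarray | None = None,
    mass_cubic: bool = False,
) -> SparkEvent:
    """Fit a symmetric 2D Gaussian to the normalized peak frame of a spark.

    The fit runs on dF/F0 of the candidate's frame, spatially smoothed with
    a Gaussian of ``fit_smooth_sigma_px`` pixels, inside a square ROI
    (side 2 x ``roi_halfwidth_um``, clipped at frame edges).  The smoothing
    kernel is deconvolved analytically from the fitted width and height, so
    a noiseless Gaussian spark is recovered exactly; R^2 is reported on the
    smoothed ROI.  FWHM is
    2 sqrt(2 ln 2) sigma; amplitude is F/F0 at the fitted peak
    (1 + offset + height); R^2 is 1 - SS_res/SS_tot over ROI pixels.
    A non-convergent fit returns an event flagged invalid with r2 = 0.
    """
    t, i, j = seed_event
    movie = np.asarray(movie, dtype=np.float64)
    T, H, W = movie.shape
    if not (0 <= t < T and 0 <= i < H and 0 <= j < W):
        raise ValueError("seed outside movie bounds")
    # the detector's temporal smoothing can displace the seed by a frame;
    # re-locate the peak frame in a +/-2 frame neighbourhood
    t_lo, t_hi = max(0, t - 2), min(T, t + 3)
    local = movie[t_lo:t_hi, max(0, i - 1) : i + 2, max(0, j - 1) : j + 2].mean(axis=(1, 2))
    t = t_lo + int(np.argmax(local))
    half = max(2, int(round(roi_halfwidth_um / pixel_size_um)))
    i0, i1 = max(0, i - half), min(H, i + half + 1)
    j0, j1 = max(0, j - half), min(W, j + half + 1)
    f0_full = np.maximum(baseline.f0, 1e-9)
    frame = (movie[t] - f0_full) / f0_full
    if mask is not None:
        # outside the cell F0 is only camera offset and dF/F0 is unbounded;
        # zero it before smoothing so it cannot bleed into the ROI
        frame = frame * mask
    if fit_smooth_sigma_px > 0:
        frame = ndimage.gaussian_filter(frame, fit_smooth_sigma_px)
    roi = frame[i0:i1, j0:j1]
    yy, xx = np.mgrid[i0:i1, j0:j1]
    xum = (xx + 0.5) * pixel_size_um
    yum = (yy + 0.5) * pixel_size_um
    # restrict the fit to the cell footprint: outside it F0 is only the
    # camera offset and dF/F0 is essentially unbounded noise
    sel = mask[i0:i1, j0:j1] if mask is not None else np.ones(roi.shape, dtype=bool)
    if sel.sum() < 16 or not sel[i - i0, j - j0]:
        sel = np.ones(roi.shape, dtype=bool)

    # dF/F0 noise is heteroscedastic (SD proportional to 1/F0): weight the
    # fit accordingly so near-edge pixels with small F0 cannot dominate
    noise_rel = (baseline.noise_sd_map / f0_full)[i0:i1, j0:j1]
    floor = max(float(np.median(noise_rel[sel])), 1e-12)
    noise_rel = np.clip(noise_rel, floor, None)
    weights = noise_rel if np.any(baseline.noise_sd_map > 0) else None

    peak_val = roi[i - i0, j - j0]
    # second-moment width initialization from the seed's neighbourhood only
    near_seed = (xum - (j + 0.5) * pixel_size_um) ** 2 + (yum - (i + 0.5) * pixel_size_um) ** 2 <= 1.5**2
    w = np.where(sel & near_seed, np.clip(roi, 0.0, None), 0.0)
    if w.sum() > 0:
        mx = float((w * xum).sum() / w.sum())
        my = float((w * yum).sum() / w.sum())
        var = float((w * ((xum - mx) ** 2 + (yum - my) ** 2)).sum() / w.sum() / 2.0)
        sigma0 = float(np.clip(np.sqrt(max(var, 1e-6)), 0.1, 2.0))
    else:
        sigma0 = 0.4
    p0 = (max(peak_val, 1e-3), (j + 0.5) * pixel_size_um, (i + 0.5) * pixel_size_um, sigma0, 0.0)
    lo = (0.0, j0 * pixel_size_um, i0 * pixel_size_um, 0.02, -1.0)
    hi = (np.inf, j1 * pixel_size_um, i1 * pixel_size_um, 5.0, 1.0)

    invalid = SparkEvent(
        x_um=(j + 0.5) * pixel_size_um,
        y_um=(i + 0.5) * pixel_size_um,
        t_frame=t,
        fwhm_um=np.nan,
        amplitude=np.nan,
        r2=0.0,
        mass=np.nan,
        valid=False,
    )
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (xum[sel].ravel(), yum[sel].ravel()),
            roi[sel].ravel(),
            p0=p0,
            sigma=weights[sel].ravel() if weights is not None else None,
            bounds=(lo, hi),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return invalid
    height, x0, y0, sigma, offset = popt
    # R^2 is evaluated on the signal-centred region (radius one FWHM around
    # the fitted centre): the wide fit ROI may contain a second simultaneous
    # spark, which should not degrade the confidence of this one
    r_r2 = max(sigma / FWHM_TO_SIGMA, 0.5)
    near = sel & (((xum - x0) ** 2 + (yum - y0) ** 2) <= r_r2**2)
    if near.sum() < 9:
        near = sel
    resid = roi[near].ravel() - _gauss2d((xum[near].ravel(), yum[near].ravel()), *popt)
    ss_res = float((resid**2).sum())
    ss_tot = float(((roi[near] - roi[near].mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2 = float(np.clip(r2, 0.0, 1.0))
    # deconvolve the fit-stage smoothing from the width and height: a
    # Gaussian spark of width s seen through a Gaussian kernel of width s_k
    # fits as sigma^2 = s^2 + s_k^2 with its peak reduced by s^2/sigma^2
    # (exact for Gaussians)
    s_k = fit_smooth_sigma_px * pixel_size_um
    var_true = sigma**2 - s_k**2
    if var_true <= (0.05 * pixel_size_um) ** 2:
        return invalid
    sigma_true = float(np.sqrt(var_true))
    height_true = float(height * sigma**2 / var_true)
    fwhm = float(sigma_true / FWHM_TO_SIGMA)
    amplitude = float(1.0 + offset + height_true)
    if not np.isfinite(fwhm) or fwhm <= 0 or amplitude <= 0 or height <= 0:
        return invalid
    return SparkEvent(
        x_um=float(x0),
        y_um=float(y0),
        t_frame=t,
        fwhm_um=fwhm,
        amplitude=amplitude,
        r2=r2,
        mass=spark_mass(amplitude, fwhm, cubic=mass_cubic),
        valid=True,
    )


def events_to_frame(events: list[SparkEvent]) -> pd.DataFrame:
    rows = [
        (e.x_um, e.y_um, e.t_frame, e.fwhm_um, e.amplitude, e.r2, e.mass)
        for e in events
    ]
    return pd.DataFrame(rows, columns=SPARK_COLUMNS)


def filter_sparks(events, fwhm_min_um: float = 0.5, fwhm_max_um: float = 2.0, r2_min: float = 0.5):
    """Retain sparks with 0.5 um <= FWHM <= 2.0 um and R^2 >= 0.5.

    Bounds are inclusive.  Accepts either a DataFrame with ``fwhm_um`` and
    ``r2`` columns (returns a filtered DataFrame) or a sequence of
    SparkEvent (returns a list).
    """
    if isinstance(events, pd.DataFrame):
        keep = (
            (events["fwhm_um"] >= fwhm_min_um)
            & (events["fwhm_um"] <= fwhm_max_um)
            & (events["r2"] >= r2_min)
        )
        return events[keep].reset_index(drop=True)
    return [
        e
        for e in events
        if e.valid
        and np.isfinite(e.fwhm_um)
        and fwhm_min_um <= e.fwhm_um <= fwhm_max_um
        and e.r2 >= r2_min
    ]


def suppress_duplicates(events: list[SparkEvent], max_dt: int = 2) -> list[SparkEvent]:
    """Merge candidates that re-detect the same spark.

    An event within one FWHM (of the brighter event) and ``max_dt`` frames
    of an already retained brighter event is dropped, leaving one event per
    spark."""
    order = sorted(events, key=lambda e: e.amplitude, reverse=True)
    kept: list[SparkEvent] = []
    for e in order:
        dup = False
        for k in kept:
            d = np.hypot(e.x_um - k.x_um, e.y_um - k.y_um)
            if d <= k.fwhm_um and abs(e.t_frame - k.t_frame) <= max_dt:
                dup = True
                break
        if not dup:
            kept.append(e)
    kept.sort(key=lambda e: (e.t_frame, e.y_um, e.x_um))
    return kept


def average_reference(movie: np.ndarray, n_frames: int = 10, start: int = 0) -> np.ndarray:
    """Average consecutive frames into a low-noise diffraction-limited image.

    The default window is the first 10 frames; in synthetic runs the movie
    generator keeps those spark-free.
    """
    movie = np.asarray(movie, dtype=np.float64)
    if n_frames < 1 or start < 0 or start + n_frames > movie.shape[0]:
        raise ValueError("requested averaging window exceeds the movie length")
    return movie[start : start + n_frames].mean(axis=0)


def detect_sparks(
    movie: np.ndarray,
    pixel_size_um: float = 0.1,
    baseline_percentile: float = 20.0,
    k_sigma: float = 3.8,
    smooth_sigma: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mask: np.ndarray | None = None,
    roi_halfwidth_um: float = 4.0,
    fwhm_bounds_um: tuple[float, float] = (0.5, 2.0),
    r2_min: float = 0.5,
    mass_cubic: bool = False,
) -> pd.DataFrame:
    """Full detection chain: baseline -> candidates -> fits -> filters.

    Returns the spark table (``x_um, y_um, t_frame, fwhm_um, amplitude,
    r2, mass``) after width/R^2 filtering and duplicate suppression.
    """
    baseline = estimate_baseline(movie, percentile=baseline_percentile)
    if mask is None:
        # the baseline image is bimodal (camera offset outside the cell,
        # indicator fluorescence inside): threshold it to confine detection
        # to the cell footprint
        from skimage.filters import threshold_otsu

        f0 = baseline.f0
        if float(f0.max()) > 2.0 * max(float(f0.min()), 1e-9):
            mask = f0 > threshold_otsu(f0)
        else:
            mask = np.ones_like(f0, dtype=bool)
    seeds = detect_candidates(movie, baseline, k_sigma=k_sigma, smooth_sigma=smooth_sigma, mask=mask)
    events = [
        fit_spark(
            movie,
            baseline,
            s,
            pixel_size_um=pixel_size_um,
            roi_halfwidth_um=roi_halfwidth_um,
            mask=mask,
            mass_cubic=mass_cubic,
        )
        for s in seeds
    ]
    events = filter_sparks(events, fwhm_bounds_um[0], fwhm_bounds_um[1], r2_min)
    events = suppress_duplicates(events)
    return events_to_frame(events)
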