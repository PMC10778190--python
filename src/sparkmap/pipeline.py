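"""End-to-end orchestration: simulate -> detect -> render -> align -> correlate.

Each stage logs its in/out counts, writes its outputs under the run
directory, and a manifest (parameters, seed, versions, stage counts)
suffices to re-execute the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .alignment import AlignmentTransform, apply_transform, coarse_align, fine_align, upscale_reference
from .config import RunConfig, config_to_dict, save_config
from .correlate import (
    mass_count_table,
    nnd_site_vs_global,
    sample_all_footprints,
    site_vs_global_density,
    sparksite_mask,
)
from .puncta import PunctaSet, detect_puncta
from .rendering import render_delaunay
from .sparks import average_reference, detect_sparks
from .synthetic import apply_known_shift_image, simulate_correlative_dataset

log = logging.getLogger("sparkmap")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full correlative pipeline and return the result bundle.

    Bundle keys: ``sparks`` (table, Ca2+ frame), ``sparks_aligned`` (map
    frame), ``map`` (RenderedMap), ``puncta`` (PunctaSet), ``transform``,
    ``site_summary``, ``mass_count`` (table, summary), ``nnd`` and
    ``manifest``.  All outputs are also written under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int | float] = {}

    # ---- inputs ----------------------------------------------------------
    truth = None
    if config.simulate:
        ds = simulate_correlative_dataset(config.simulation, seed=config.seed)
        movie = ds.movie.astype(np.float64)
        locs = ds.localizations
        truth = ds.truth
        cell_mask = truth.cell_mask
        pixel_size_um = config.simulation.pixel_size_um
        io.write_movie(outdir / "movie.tif", movie, pixel_size_um, config.simulation.movie.frame_interval_ms)
        io.write_localizations(outdir / "localizations.csv", locs)
        io.write_mask(outdir / "cell_mask.tif", cell_mask, pixel_size_um)
        truth.spark_truth.to_csv(outdir / "truth_sparks.csv", index=False)
        truth.puncta_truth.to_csv(outdir / "truth_puncta.csv", index=False)
    else:
        if not config.movie_path or not config.localizations_path:
            raise StageError("inputs", "simulation disabled and movie/localization paths missing")
        movie, meta = io.read_movie(config.movie_path)
        pixel_size_um = float(meta.get("pixel_size_um", 0.1))
        locs = io.read_localizations(config.localizations_path)
        if config.cell_mask_path:
            cell_mask, _ = io.read_mask(config.cell_mask_path)
        else:
            cell_mask = None
    log.info("inputs: %d frames, %d localizations", movie.shape[0], len(locs))

    # ---- spark detection -------------------------------------------------
    det = config.detection
    sparks = detect_sparks(
        movie,
        pixel_size_um=pixel_size_um,
        baseline_percentile=det.baseline_percentile,
        k_sigma=det.k_sigma,
        smooth_sigma=det.smooth_sigma,
        mask=cell_mask,
        roi_halfwidth_um=det.roi_halfwidth_um,
        fwhm_bounds_um=det.fwhm_bounds_um,
        r2_min=det.r2_min,
        mass_cubic=det.mass_cubic,
    )
    counts["sparks_retained"] = len(sparks)
    io.write_sparks(outdir / "sparks.csv", sparks)
    if len(sparks) == 0:
        raise StageError("spark_detection", "no sparks retained after filtering")

    # ---- rendering -------------------------------------------------------
    rmap = render_delaunay(
        locs,
        pixel_size_nm=config.render.pixel_size_nm,
        n_jitter=config.render.n_jitter,
        pad_nm=config.render.pad_nm,
        seed=config.seed,
    )
    io.write_map(outdir / "map.tif", rmap, config.render.clip_percentile)

    # ---- puncta ----------------------------------------------------------
    pset = detect_puncta(rmap, config.puncta.threshold_frac, config.puncta.min_area_nm2)
    counts["puncta_detected"] = len(pset)
    io.write_puncta(outdir / "puncta.csv", pset.table)
    if len(pset) < 2:
        raise StageError("puncta", "fewer than 2 puncta detected")

    # ---- alignment -------------------------------------------------------
    reference = average_reference(movie, n_frames=config.align.reference_n_frames)
    ref_up = upscale_reference(
        reference,
        from_pixel_nm=pixel_size_um * 1000.0,
        to_pixel_nm=rmap.pixel_size_nm,
        origin_nm=(0.0, 0.0),
        match=rmap,
    )
    start = coarse_align((config.align.coarse_dx_nm, config.align.coarse_dy_nm))
    transform = fine_align(
        ref_up,
        rmap,
        start=start,
        search_radius_nm=config.align.search_radius_nm,
        target_fwhm_nm=config.align.target_fwhm_nm,
    )
    io.write_transform(outdir / "transform.json", transform)
    counts["alignment_peak_correlation"] = transform.peak_correlation
    sparks_aligned = apply_transform(sparks, transform)
    io.write_sparks(outdir / "sparks_aligned.csv", sparks_aligned)

    # ---- correlative analysis -------------------------------------------
    if cell_mask is None:
        raise StageError("correlate", "a cell mask is required for site statistics")
    # carry the cell mask into the map frame
    pixel_nm = pixel_size_um * 1000.0
    mask_map_frame = (
        apply_known_shift_image(cell_mask.astype(float), transform.dx_nm, transform.dy_nm, pixel_nm, order=0) > 0.5
    )
    mask_origin = (0.0, 0.0)
    samples = sample_all_footprints(sparks_aligned, pset)
    site_mask, fraction = sparksite_mask(sparks_aligned, mask_map_frame, pixel_nm, mask_origin)
    summary = site_vs_global_density(pset, site_mask, mask_map_frame, pixel_nm, mask_origin)
    table, count_summary = mass_count_table(samples)
    nnd = nnd_site_vs_global(pset, samples)
    table.to_csv(outdir / "footprints.csv", index=False)
    nnd["histogram"].to_csv(outdir / "nnd_histograms.csv", index=False)
    site_summary = {
        "site_area_fraction": summary.site_area_fraction,
        "density_site_per_um2": summary.density_site_per_um2,
        "density_global_per_um2": summary.density_global_per_um2,
        "density_ratio": summary.density_ratio,
        **count_summary,
    }
    (outdir / "site_summary.json").write_text(json.dumps(site_summary, indent=2))
    counts["footprints"] = len(samples)

    if config.save_figures:
        _save_figures(outdir, sparks_aligned, pset, rmap, table, nnd)

    manifest = {
        "sparkmap_version": __version__,
        "seed": config.seed,
        "config": config_to_dict(config),
        "stage_counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    save_config(config, outdir / "config.yaml")

    return {
        "sparks": sparks,
        "sparks_aligned": sparks_aligned,
        "map": rmap,
        "puncta": pset,
        "transform": transform,
        "site_mask": site_mask,
        "cell_mask_map_frame": mask_map_frame,
        "site_summary": site_summary,
        "mass_count": (table, count_summary),
        "nnd": nnd,
        "truth": truth,
        "manifest": manifest,
    }


def _save_figures(outdir: Path, sparks: pd.DataFrame, pset: PunctaSet, rmap, table: pd.DataFrame, nnd: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(np.log1p(rmap.pixels), cmap="magma", origin="upper")
    i, j = rmap.to_pixel_indices(sparks["x_nm"].to_numpy(), sparks["y_nm"].to_numpy())
    ax.plot(j, i, "g+", ms=10, label="sparks")
    ax.legend()
    ax.set_title("spark centroids over rendered map")
    fig.savefig(outdir / "overlay.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots()
    ax.scatter(table["mass"], table["count"], s=12)
    ax.set_xlabel("spark mass (A.U.)")
    ax.set_ylabel("puncta in footprint")
    ax.set_xscale("log")
    fig.savefig(outdir / "mass_vs_count.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots()
    h = nnd["histogram"]
    ax.bar(h["bin_left_nm"], h["global_pct"], width=20, alpha=0.5, label="cell-wide")
    ax.bar(h["bin_left_nm"], h["site_pct"], width=20, alpha=0.5, label="spark sites")
    ax.set_xlabel("nearest-neighbour distance (nm)")
    ax.set_ylabel("% of puncta")
    ax.legend()
    fig.savefig(outdir / "nnd_histograms.png", dpi=150)
    plt.close(fig)
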