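# Methods

`sparkmap` implements a correlative analysis that maps subplasmalemmal
Ca²⁺ sparks recorded in TIRF movies onto super-resolution (dSTORM-style)
localization maps of ER Ca²⁺-release channel labelling (e.g. RyR3, IP3R1
puncta), and computes spark-level and site-level spatial statistics.  This
note describes the models, the estimators, the synthetic data they are
validated against, and the choices made where the design was open.

## Coordinate conventions

All point data are continuous (x, y) in nm with the origin at the top-left
corner of the image, x along columns and y along rows.  Pixel (i, j) covers
the half-open square [j·p, (j+1)·p) × [i·p, (i+1)·p); its center sits at
(+0.5)·p.  Both modalities share this frame, so a rigid shift (dx, dy)
in nm is the entire inter-modality transform: `x_map = x_ca + dx`.
Points landing exactly on a mask-boundary pixel count as inside.

## Spark detection and quantification

The TIRF movie F(x, y, t) is normalized by a per-pixel baseline F₀:

* **Baseline.** F₀ is the 20th temporal percentile of each pixel's trace,
  which is robust to sparks (a pixel is spark-lit in a small fraction of
  frames).  A low percentile of a noisy trace is biased low by z_q·σ, so
  that term is added back, with σ estimated per pixel from the MAD of
  frame-to-frame differences (÷√2).  Without this correction every
  amplitude would be inflated by ≈ 0.84 σ/F₀ (≈ 25 % at the default noise
  level).  The percentile is a config knob (`baseline_percentile`).
* **Candidates.** ΔF/F₀ = (F − F₀)/F₀ is smoothed with a spatiotemporal
  Gaussian (σ = 1 px, 1 frame) and thresholded at k·σ̂ (default k = 3.8)
  where σ̂ is the robust SD of the smoothed in-cell signal.  Every
  suprathreshold voxel that is the maximum of a ±2-frame × ±5-px
  neighbourhood seeds one candidate.  Seeding local maxima rather than one
  candidate per connected component matters at realistic spark rates:
  simultaneous sparks a few µm apart share one suprathreshold component
  and would otherwise collapse into a single event.
* **Fit.** A symmetric 2D Gaussian (height, x₀, y₀, σ, offset) is fitted
  by weighted least squares to the spatially smoothed (σ_k = 1 px) ΔF/F₀
  peak frame inside a square ROI of side 8 µm, restricted to in-cell
  pixels.  Two details are load-bearing:
  * ΔF/F₀ is heteroscedastic (its noise SD is proportional to 1/F₀), so
    each pixel is weighted by its own noise estimate; near the cell edge
    F₀ falls towards the camera offset and unweighted fits are hijacked
    by edge pixels.  Out-of-cell pixels are zeroed *before* smoothing so
    their unbounded ΔF/F₀ cannot bleed into the ROI.
  * The smoothing kernel is deconvolved analytically from the result:
    a Gaussian spark of width s observed through a Gaussian kernel s_k
    fits as σ² = s² + s_k² with its peak reduced by s²/σ².  A noiseless
    Gaussian spark is therefore recovered exactly.
  FWHM = 2√(2 ln 2)·σ; amplitude F/F₀ = 1 + offset + height.  R² =
  1 − SS_res/SS_tot is evaluated over a signal-centred region (radius one
  fitted FWHM, minimum 0.5 µm): over the full 8 µm ROI the statistic is
  bounded near 0.2 by noise pixels alone at the experimental SNR, and a
  second simultaneous spark in the ROI should not destroy this spark's
  confidence score.
* **Filtering.** Events are retained iff 0.5 µm ≤ FWHM ≤ 2.0 µm and
  R² ≥ 0.5 (bounds inclusive).  Candidates within one FWHM and two frames
  of a retained brighter event are treated as re-detections and dropped,
  leaving one event per spark.
* **Spark mass** = amplitude × FWHM × 1.206 (A.U.), a scalar proxy for the
  total Ca²⁺ released.  The classical spark-mass formula behind the 1.206
  factor uses FWHM³ (a volume proxy); `spark_mass(..., cubic=True)`
  exposes that variant without making it the default output.

## Localization-map rendering

Localization tables (x, y in nm, optional per-event precision) are
rendered at 5 nm/px by Delaunay triangulation: each vertex gets the local
density estimate 3/(total area of its incident triangles) and the density
is interpolated linearly across each triangle.  Triangulation artefacts
are suppressed by averaging `n_jitter` renders (default 10) with the
points perturbed by the localization precision (default 10 nm).  Pixels
outside the convex hull render as 0.  The map extent is the padded
bounding box of the points (250 nm), with the origin recorded so nm
coordinates round-trip exactly; an explicit extent can be supplied when
two point sets must share a grid.  16-bit quantization (linear to the
99.9th percentile) is export-only — all analysis runs on the real-valued
map, so punctum statistics never depend on quantization.

A practical property of this estimator worth knowing: a cluster of ≤ 5
localizations often has *all* its points on its own convex hull, where the
incident triangles reach out to distant neighbours, so such clusters
render dim and can fall below the detection threshold.  Labelling puncta
should be represented by ~10⁺ localizations for reliable rendering (the
synthetic generator defaults to a mean of 20, consistent with a
20k–30k-frame dSTORM acquisition).

## Punctum detection and point statistics

Puncta are detected on the real-valued map by thresholding at
`threshold_frac` × the Otsu level of the in-support (positive) pixels
(default frac 1.0), taking 8-connected components of at least
`min_area_nm2` (default 100 nm² = 4 px), and reporting intensity-weighted
centroids and pixel-count areas.  Raising the threshold shrinks every
component; counts are monotone in `min_area` exactly and in the threshold
up to split/merge events of individual blobs.

Nearest-neighbour distances (NND) use a k-d tree (validated against the
O(n²) oracle); densities are counts per µm² of mask area; for a
homogeneous Poisson process of intensity λ the mean NND is 1/(2√λ), which
the generator output reproduces within sampling error.

## Alignment

The diffraction-limited reference is the mean of ~10 consecutive movie
frames, bilinearly resampled onto the 5 nm map grid through the shared nm
frame (extent arithmetic, never index arithmetic).  A coarse shift — the
operator's manual starting point, supplied via config rather than a GUI —
seeds an automated fine alignment: the rendered map is blurred to the
reference resolution (250 nm default) and the normalized cross-correlation
is maximized over displacements within `search_radius_nm` (default 2 µm)
of the start.

The correlation is a *masked* NCC: at every lag the Pearson correlation is
computed over the overlap of the two supports, with per-lag mean and
variance normalization (computed with shared FFTs; correlation planes are
cropped to the search window to bound memory).  This matters: globally
normalized cross-correlation on plateau-like density maps carries a
systematic envelope bias of tens of nm, while the masked form recovers
known shifts to < 0.1 nm on noiseless renders.  The sub-pixel peak is the
3-point quadratic interpolation per axis; a peak on the search boundary or
a weak peak (< 0.2) sets a flag on the transform.  The transform is a
rigid translation only — no rotation or scale — which is a documented
limitation.

`simulate_alignment_error` quantifies the whole chain per iteration:
synthesize a cell-scale punctum field, render it, derive the
diffraction-limited reference from the unshifted ground truth (blur to
the PSF, resample to the 100 nm camera grid, add Gaussian noise so the
mean in-cell signal over noise SD equals the target SNR), re-render from
the point table displaced by a random known shift (±1 µm), perturb the
coarse start by ±500 nm, run the fine alignment, and record the Euclidean
error.  At PSF FWHM 250 nm and SNR 17 the errors are ~1–5 nm, far inside
the 100 nm error budget, because the reference shares the map's internal
structure.  In full pipeline runs, where the reference is the flat
in-cell indicator baseline and only the cell outline carries signal,
residual errors are ~20–60 nm — still within the budget, and the honest
analogue of the semi-automated outline-based registration.

## Correlative statistics

Each aligned spark defines a circular footprint centred on its centroid
with diameter equal to its FWHM; puncta at distance ≤ FWHM/2 (boundary
inclusive) are sampled.  Footprints are per-spark samples, not a
partition — a punctum may belong to several sparks.  Per footprint the
mean NND is computed with neighbours restricted to the footprint's own
puncta and is undefined for fewer than two (such footprints count in the
count statistics but not in NND pooling).  The spark-site region is the
union of all footprints (overlaps once) intersected with the cell mask;
its punctum density is compared with the cell-wide density over the full
cell footprint — sites included, which is how a cell-wide density is
measured on a single map.  The per-spark (mass, count) table is summarized
with the count mean/SD and the Spearman rank correlation; NND histograms
use 25 nm bins (spark-mass and FWHM histograms use 0.1 A.U. and 0.2 µm).

Group-level inference (repeated-measures ANOVA/Tukey across cells and
conditions) is deliberately not re-implemented; the pipeline emits tidy
per-cell summary tables for external statistics software.

## Synthetic data: what it emulates, and what it does not

The generator produces both modalities with full ground truth:

* **Cell mask** — a star-convex outline (radius modulated by low-order
  random Fourier modes, peak excursion = `irregularity`).
* **Puncta** — homogeneous Poisson background (default 13.4 µm⁻², the
  measured cell-wide punctum density regime) plus circular hotspots whose
  density is `multiplier` × background (default 4, inside the observed
  3.8–5× enrichment band).  A hard-core minimum separation (60 nm,
  enforced by dart throwing that preserves the Poisson count) emulates the
  finite resolvable size of labelling puncta and yields hotspot NND
  spacings of ~100–130 nm.  Optional Thomas-style clustering is available.
* **Localizations** — each punctum emits 1 + Poisson(mean − 1)
  localizations (mean 20) with Gaussian precision jitter (10 nm), plus a
  uniform nonspecific background (1 µm⁻²) inside the cell.
* **Movie** — 100 ms/frame, 0.1 µm/px, baseline 1000 counts inside the
  PSF-softened cell outline over a 100-count camera offset.  Sparks are
  2D Gaussians with a 1-frame rise and exponential decay (τ = 2 frames;
  kinetics are cosmetic — only the peak frame is analysed).  Spark FWHM
  is drawn from (0.6, 1.8) µm — the central part of the 0.5–2.0 µm
  retention band, so that boundary censoring by the width filter does not
  confound recovery statistics — and amplitudes from (1.5, 3.0) F/F₀; the
  true rate and amplitude distribution are unreported free parameters.
  Gaussian read-out noise is scaled so that the SNR of the **10-frame
  averaged** image equals the target (default 17.0), with SNR defined as
  the mean baseline-subtracted spark peak amplitude divided by the noise
  SD of the averaged image.  The first 12 frames are kept spark-free so a
  clean reference can be averaged.
* **Paired dataset** — sparks occur at the hotspot centers (50 nm jitter),
  expressing the hypothesis the analysis is designed to test (release
  sites coincide with channel enrichment), and the localization table is
  rigidly shifted (default (850, −620) nm) to emulate re-mounting between
  acquisitions.  All randomness flows from one top-level seed through
  named substreams, so identical (seed, params) reproduce bit-identical
  datasets.

Not emulated: fluorophore blinking photophysics and raw dSTORM frame
fitting (pre-localized tables are consumed), stage drift, 3D structure,
multi-channel acquisition, spatially textured indicator baseline, and
channel mobility between the two acquisitions.  Consequently, passing
tests demonstrate the correctness and statistical calibration of the
*analysis chain* under the stated generative model; they do not certify
performance on real data whose deviations (non-Gaussian noise, baseline
texture, drift) are outside that model.

One internal-consistency caveat about the published observables this
generator parallels: a site density of ~51 µm⁻², a cell-wide density of
~13 µm⁻² and a ~28 % site-area fraction cannot hold simultaneously on one
map (0.28 × 51 already exceeds 13), so those numbers must pool cells or
conditions differently.  The defaults therefore target clean recovery of
the enrichment *multiplier* (small site-area fraction ≈ 3 %, multiplier
within the reported 3.8–5× band) rather than jointly matching all
headline numbers.  Note also that the measured site-vs-cell-wide ratio is
intrinsically below the configured multiplier m by the factor
1/(1 + f(m − 1)) (f = hotspot area fraction), because the sites
contribute to the cell-wide denominator — at the defaults, a multiplier
of 4 measures as ≈ 3.4–3.6.

## Problem sizes and determinism

Default validation experiments: 20 alignment-error iterations on
~3 µm-radius cells; 100-spark recovery movies of 128×128 px; full
correlative runs on a 16 µm field with ~2000 puncta and ~40k
localizations (maps of ~3100² px at 5 nm).  These sizes keep every
experiment at minutes on a single CPU while leaving Poisson sampling
errors on recovered densities at the few-percent level.  Every stochastic
stage derives its generator from a named substream of one top-level seed
(CRC-keyed `SeedSequence`), so adding a stage never perturbs the draws of
existing stages and complete runs are reproducible bit-for-bit from
(config, seed).
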