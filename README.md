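# sparkmap

Correlative analysis of TIRF Ca²⁺ sparks against super-resolution maps of
ER Ca²⁺-release channels.

In sensory neurons (and other excitable cells), elementary Ca²⁺-release
events — *sparks* — arise from nanoscale groupings of ER channels such as
ryanodine receptors (RyR3) and IP₃ receptors (IP3R1).  A correlative
experiment records the sparks live in TIRF, then images the same cell's
channel labelling with dSTORM, and asks: what does the channel map look
like underneath each spark?  `sparkmap` implements the full analysis chain
for that experiment:

* **Spark detection** — per-pixel baseline F₀, candidate detection on
  smoothed ΔF/F₀, symmetric 2D Gaussian fits (FWHM = 2√(2 ln 2)·σ,
  amplitude F/F₀, fit R²), retention of sparks with
  0.5 µm ≤ FWHM ≤ 2.0 µm and R² ≥ 0.5, and the spark mass
  `M = (F/F₀) × FWHM × 1.206` (A.U.).
* **Map rendering** — localization tables → 5 nm/px density maps via
  Delaunay triangulation (vertex density 3/incident-triangle-area,
  linearly interpolated, jitter-averaged), with 16-bit TIFF export.
* **Punctum analysis** — Otsu-relative detection of labelling puncta
  (centroids, areas), nearest-neighbour distances, region densities.
* **Alignment** — the ~10-frame-averaged Ca²⁺ image is upscaled onto the
  map grid; a config-supplied coarse shift seeds an automated fine
  alignment by masked normalized cross-correlation with sub-pixel peak
  refinement; the rigid shift (dx, dy) is applied to the spark
  coordinates.
* **Correlative statistics** — per spark, the puncta inside a circular
  footprint of diameter FWHM are counted and their within-footprint NNDs
  averaged; the union of footprints defines the spark-site region, whose
  punctum density and NND distribution are compared with the cell-wide
  ones; per-spark (mass, count) scattergram tables are emitted.
* **Synthetic data** — a first-class generator produces paired movies and
  localization tables with full ground truth (cell outline, punctum
  hotspots with known enrichment, known inter-modality shift, sparks with
  known width/amplitude), so every stage is validated against truth with
  no external data.

See `docs/methods.md` for the models, estimators and their assumptions.

## Worked example

A complete synthetic run — generate a paired dataset, detect sparks,
render and segment the map, align, and correlate:

```python
from sparkmap.config import RunConfig
from sparkmap.pipeline import run_pipeline

cfg = RunConfig(seed=1, outdir="run1")
cfg.align.coarse_dx_nm = 700.0   # operator's starting shift (nm)
cfg.align.coarse_dy_nm = -400.0
bundle = run_pipeline(cfg)

print(bundle["sparks"].head(4))
print(bundle["site_summary"])
```

prints (abridged):

```
    x_um    y_um  t_frame  fwhm_um  amplitude     r2   mass
0  7.757  11.605       13    1.022      1.827  0.927  2.252
1  9.669   5.417       26    1.171      2.088  0.963  2.948
2  9.570   5.435       30    1.079      2.109  0.965  2.743
3  7.703  11.686       33    1.082      1.880  0.936  2.454

{'site_area_fraction': 0.0273, 'density_site_per_um2': 51.10,
 'density_global_per_um2': 15.07, 'density_ratio': 3.39,
 'n_sparks': 17, 'count_mean': 45.47, 'count_sd': 15.20,
 'mass_count_spearman': 0.398}
```

Reading this output: 17 sparks survived the width/R² filter; each row is
one spark with its centroid (µm), peak frame, fitted FWHM, amplitude
F/F₀ and mass.  The fine alignment recovered the applied inter-modality
shift of (850, −620) nm to (885, −585) nm — a ~47 nm registration error
from outline-only matching, inside the method's 100 nm error budget.  The
spark footprints cover 2.7 % of the cell, and the punctum density under
them is 51.1 µm⁻² versus 15.1 µm⁻² cell-wide — a ratio of 3.39 for a
configured hotspot enrichment of 4× (the measured ratio sits below the
configured multiplier because the sites also contribute to the cell-wide
denominator; see `docs/methods.md`).  The positive Spearman correlation
says heavier sparks sit on more puncta, as constructed.

The same run from a shell, plus the registration-error simulation:

```sh
sparkmap run --seed 1 --out run1
sparkmap simulate-alignment-error --snr 17 --psf-fwhm 250 --n-iter 20 --seed 1
```

Every stage is also exposed separately (`sparkmap simulate`,
`detect-sparks`, `render`, `detect-puncta`, `align`) and as plain library
functions.

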