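# Methods

## Object model

A field of AO-stained whole milk is modeled as three registered planes over
the same pixel grid: DIC (globules as bright-rimmed "bubbles"), AO-RNA, and
AO-DNA. Three object classes are detected:

- **Milk fat globule** — approximately circular; detected in DIC.
- **Cytoplasmic crescent** — RNA-only signal adherent to a globule
  boundary; membrane-enclosed cytoplasm without a nucleus.
- **Nucleated cell** — colocalized RNA and DNA signal, free-floating.

Coordinates are 0-based with x = column, y = row; centroids are means of
member-pixel coordinates. Areas are px², and additionally µm² when a pixel
size is supplied.

## Detection

All channels share one skeleton: Gaussian smoothing (σ = 1 px), a global
threshold, 8-connected components (thin crescent arcs fragment under
4-connectivity), and a minimum-area filter (50 px² globules, 5 px²
RNA/DNA objects).

**Thresholding.** Default is Otsu, guarded by a robust noise floor: the
effective threshold is max(Otsu, median + k·1.4826·MAD) with k = 6. The
floor exists because Otsu always bisects a histogram; on a channel with no
real signal (e.g. the DNA plane of a cell-free field) it would binarize
noise, while six robust standard deviations above the median admits
essentially no noise pixels. A `fixed` mode supplies per-channel constants
instead; channels without a listed constant fall back to the automatic
rule. Fixed thresholds are the right choice when object classes span large
intensity ranges in one channel (a bimodal criterion like Otsu then lands
*between* the two foreground classes and erases the dimmer one) and are
what the calibrated-share benchmark scenes use.

**Globules.** DIC shows rims, not filled disks, so by default the Sobel
gradient magnitude of the smoothed plane is thresholded (both rim edges
have high gradient), the rim mask is closed (3×3), holes are filled to
recover the disk, and one erosion (3×3) undoes the dilation bias of
closing. An `intensity` mode thresholds the plane directly for simple
images. Components then pass an area filter and a circularity filter
(4πA/P² ≥ 0.6, perimeter by the Crofton formula, clamped at 1.05 because
digitization can push small disks slightly past 1). Touching globules are
not split in this version; merged blobs typically fail the circularity
filter, and the per-image fraction of low-circularity objects is logged as
a quality indicator.

**Geometry correction.** Detected globule components are hole-filled and
their area/centroid/equivalent radius recomputed; the step is idempotent
and changes nothing for already-solid components.

**Classification.** The DNA mask is dilated by 1 px (tolerating small
chromatic misregistration between fluorescence channels); an RNA object
whose member-pixel overlap fraction with the dilated mask is ≥ 0.3
(boundary inclusive) is a nucleated cell, otherwise a crescent candidate.
Both knobs are configuration-exposed.

**Intensity integration.** An object's integrated intensity is
Σ max(value − background, 0) over its member pixels, where background is
the median of below-threshold pixels. Member pixels are the thresholded
component expanded by a 2-px nearest-label halo (`measure_dilation_px`):
optical blur pushes a tail of every object's signal just below threshold,
and thin arcs lose proportionally more of it than disks, which would bias
the cellular/exosomal ratio; the halo recovers most of that tail. Areas
and centroids always come from the un-expanded component.

## Linking

distance(crescent, globule) = ‖centroids‖₂ − equivalent_radius, i.e.
distance to the idealized globule *boundary*; raw centroid distance would
mis-assign small crescents sitting on large globules. The minimizing
globule wins; exact ties break to the lowest globule id; beyond
`max_link_distance` (25 px) or with no globules the crescent is kept as an
orphan. Orphans still count as exosomal RNA — crescents can detach from
globules during spreading, and discarding their signal would bias the RNA
attribution — but contribute nothing to the incidence numerator.

## Summaries

- `pct_globules_with_crescents` — a globule with several linked crescents
  counts once; undefined (NaN) when no globules were found.
- `cellular_rna_pct` — Σ over cells / Σ over (cells + all crescents), by
  integrated intensity (default) or by area. The denominator covers
  segmented objects only; diffuse sub-threshold skim signal is excluded,
  which is a declared interpretation of "% of whole-milk RNA". Intensity is
  the default because RNA mass tracks fluorescence yield better than
  projected area.

## Tiling

Large images are processed in overlapping tiles. Tiles advance by
`tile_size − overlap`; each tile's authoritative *core* is bounded by the
midlines of its overlap bands, so cores partition the image exactly and an
object is kept by the unique tile whose core contains its centroid. The
caller must choose `overlap` at least as large as the biggest expected
object diameter. After aggregation, crescent–globule linking is re-run over
the full object lists, so links may cross tile boundaries. Thresholds are
computed per tile (robustness to illumination drift across a slide); as a
consequence, whole-image and tiled runs are only bit-identical when fixed
thresholds are used — with automatic thresholds, detections exactly at a
threshold margin can differ, which the tiling tests make explicit.

## Synthetic scenes

The generator emulates what the pipeline must handle, with exact ground
truth recorded at the raster level (pixel-count areas, pixel-mean
centroids, pre-noise integrated signals):

- globule radii lognormal (default median 8 px, σ_log 0.25, clipped below
  at 5 px — smaller objects fall under the detection area filter and
  sub-resolution globules are not modeled);
- crescents as annular arcs hugging the *outside* of the owner globule's
  boundary (fraction 0.35 of the circle, 3 px thick), matching micrograph
  appearance and making boundary-distance linking geometrically correct;
- cells as 5-px-radius RNA disks with concentric 3-px DNA nuclei, placed
  independently of globules;
- DIC rims drawn 2 px wide just *inside* the true boundary so the filled
  detection reproduces the true disk area;
- Gaussian blur (σ = 1 px) then additive Gaussian noise (σ = 2, on
  backgrounds of 10 fluorescence / 120 DIC and signal amplitudes of
  80–180) — modest but realistic contrast; a Poisson option exists;
- placement by seeded rejection sampling on a neighbor grid with a minimum
  edge-to-edge gap (7 px; crescent thickness is added to the exclusion
  radius of crescent-bearing globules). The packing density of the default
  scenes sits well below the random-sequential-adsorption limit; infeasible
  requests fail with an explicit error after a bounded number of draws.
- Incidence can be a per-globule probability or an exact count of bearing
  globules (one crescent each); `cellular_share_target` re-derives the cell
  and crescent RNA amplitudes geometrically around a base amplitude of 400
  so the ground-truth cellular share of integrated RNA hits the target
  exactly while both classes stay well above the noise floor even at
  shares below 1 %.

What the generator does *not* emulate — and hence what passing tests do not
establish about real micrographs: overlapping or touching globules,
out-of-focus planes, realistic DIC shading (only an idealized rim),
illumination gradients, autofluorescence texture, debris, or empirical
crescent size distributions. Recovery results on synthetic scenes bound
the pipeline's algorithmic error, not its performance on scanner output.

## Benchmark scenarios

`lactoscan.scenarios` fixes the two canonical recovery set-ups used by the
acceptance script and tests:

- **Incidence recovery** — 20,000 globules on 4096² px (radius median 5 px,
  σ_log 0.15, a density comfortably inside the packing limit), default blur
  and noise, crescent-bearing count fixed to round(p·N); the pipeline's
  incidence should reproduce p exactly when detection is perfect.
- **Share recovery** — 512² px, 200 globules, 20 cells,
  `cellular_share_target` set to the benchmark percentage, fixed
  fluorescence thresholds of 20 (≈ 5 noise σ above background); recovery
  within ±2 percentage points, and ±0.5 in the sub-1 % regime.

These problem sizes run in roughly a minute per whole-slide scene and
seconds per share scene on one CPU.

## Statistics

Two-group comparisons default to Welch's t-test (the unequal-variance form
with Welch–Satterthwaite degrees of freedom), with pooled variance as a
sensitivity option; two zero-variance samples with equal means return
t = 0, p = 1 by convention. Boxplot summaries use linear interpolation
between order statistics for quartiles, whiskers at the sample extremes,
and box widths proportional to √n normalized to the largest group. Linear
fits are ordinary least squares with R² the squared Pearson correlation and
a two-sided slope t-test on n − 2 degrees of freedom.

## Numerical and degenerate-input choices

- Constant planes under Otsu yield zero objects with a logged warning, not
  an error.
- Empty record lists are legal everywhere (header-only CSVs, orphan-only
  linking, NaN summary fields).
- Tile cores are half-open intervals, so an object centered exactly on a
  core boundary belongs to exactly one tile.
- Seeded runs are bit-reproducible: scene geometry and noise derive from
  `numpy.random.default_rng` seeded from the scene seed; rendering a scene
  twice gives identical pixels.
- TIFF output is uint16 (values rounded and clipped), which round-trips
  integer-valued renders exactly.

## Known limitations

- No watershed splitting of touching globules; dense real fields will
  undercount via the circularity filter.
- Per-tile automatic thresholds trade slide-scale robustness for exact
  tiling invariance (see Tiling).
- The crescent size distribution and the original imaging thresholds are
  declared defaults, not fitted to data.
- Absolute RNA yield is out of scope; only ratios of fluorescence are
  reported.
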