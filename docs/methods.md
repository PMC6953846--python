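# Methods

## Pipeline model and assumptions

The pipeline maps ten land-cover classes per country by sequential binary
classification. The core assumptions are:

- **Co-registration.** All rasters of a run share one projected CRS,
  grid shape and affine transform; reprojection is out of scope. Pixel
  indexing is 0-based (row, col); the transform maps pixel edges and all
  point-in-polygon/buffer tests use pixel centers.
- **Median compositing is sufficient cloud removal.** QA bits (default
  dialect: bit 0 cloud, bit 1 shadow, bit 2 fill; a Landsat
  Collection-style mapping can be configured) flag contaminated pixels to
  nodata; the per-band, per-pixel median over the window then ignores
  them. An even observation count takes the mean of the two middle
  values (the common platform convention). The thermal proxy band B10 is
  composited exactly like the reflectance bands; its scaling is whatever
  the input provides, so thresholds on NDII/NDBaI are scaling-dependent.
- **Masking-then-classifying reduces commission.** Phase-I thresholds
  are strict inequalities exactly as configured (`>` excludes equality).
  Rules AND together, so candidate sets are monotone in the rule set and
  independent of rule order. Threshold suggestion returns the loosest
  threshold retaining 100% of the target-class samples (zero omission by
  construction), with the comparator toward the target's side of the
  layer distribution.
- **Sequential order matters and is configurable.** The default order is
  water, mangroves/wetlands, artificial surfaces, barren land, ecosystem
  complex (Liberia), woody crops, [flooded forests via SAR, Gabon], tree
  covered dense, tree covered open, mixed vegetation (Liberia),
  grasslands. The order can introduce commission/omission at class
  boundaries; it is a legend-level setting, not hard-coded.
- **Binary forests.** Each class trains a 100-tree majority-vote random
  forest with a per-split predictor subset of size sqrt(p). Predictors
  are the seven bands plus the index group(s) matching the class
  (water/wetland indices, built-up/bare indices, green-vegetation
  indices, band ratios). "Other" training pixels are the non-target
  training pixels restricted to the current candidate mask; if fewer than
  the training floor (10 per label) remain there, the unrestricted
  non-target set is used so the binary problem stays well-posed.
- **Verification.** Water and mangroves carry a slope cap (default 10°,
  configurable) computed from the DEM by Horn's 3×3 method; offending
  pixels revert to the pool.
- **SAR flood rule.** permanent = detected dry AND rainy; seasonal =
  rainy only. A dry-only detection has no defined category; it is
  treated as not flooded (the conservative completion of the rule) and
  counted as an anomaly. Detection thresholds default to Otsu's split of
  the amplitude histogram inside the DEM-constrained region (elevation
  below 20 m by default; an optional river-corridor buffer mode exists);
  a degenerate histogram is an error that asks for a fixed threshold.
  Conflicts with earlier classes resolve in favour of the earlier class,
  mirroring mask propagation.
- **Accuracy.** The equal-weight stratified design (50 per class) is
  reported as-is; it estimates per-class accuracies at equal precision
  but not area-weighted map accuracy. Confidence intervals use the
  Wilson score interval (better coverage at n = 50 strata than Wald,
  which remains available). Statistics are stored at full precision;
  rounding to display percentages is the caller's concern. A zero
  marginal makes a statistic undefined (NaN), never 0.

## Key parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| trees per forest | 100 | – | standard ensemble size for this workload |
| per-split predictors | sqrt(p) | – | conventional RF default |
| validation samples | 50/class | pixels | equal representability of strata |
| pixel size | 30 | m | Landsat nominal resolution |
| settlement buffer | 2,000 | m | **calibration knob** — no published value exists; 2 km spans the halo of mixed built/bare pixels around a settlement point without reaching neighbouring strata |
| shore buffer | 1,000 | m | confines the sand/intertidal complex |
| Gabon mangrove elevation cap | 95 | m | mangroves do not persist above the coastal plain |
| slope cap (water/mangrove) | 10 | deg | "low relief" made operational; configurable |
| flood DEM cap | 20 | m | low, flood-prone land along rivers |
| index epsilon | 1e-10 | – | zero-denominator pixels become nodata, not ±inf |

## The synthetic generator

The generator defines the study conditions for all tests. It emulates:
per-class band means for bands B2–B7 and a thermal proxy B10; independent
per-band Gaussian noise (SD 0.01 reflectance units) truncated to [0, 1];
a rainy-season green-up of +0.02 on B5 for vegetated classes; cloud and
shadow disks with QA bits set; a coastal DEM gradient (~0.6 m per pixel)
with a low river corridor; shoreline, settlements, concessions and (for
Gabon) a forest-extent polygon consistent with the truth raster; and
dry/rainy HH amplitude pairs (background 0.30, flooded 0.70, noise SD
0.04, linear scale) with a small fraction of bright upland anomalies for
the DEM constraint to reject.

The default spectral library is constructed so that (a) every default
Phase-I rule is true for its target class's mean and false for at least
one other class's mean, and (b) any two classes that must be separated by
a forest differ by at least five noise SDs in some band. Both properties
are asserted in tests. What passing tests therefore show is that the
*pipeline logic* is correct under the assumptions the method makes; they
do not show that real Landsat scenes satisfy those assumptions — real
signatures overlap more, clouds are not disks, thermal scaling varies,
and reference labels carry interpreter error. Wall-to-wall recovery of
~99.9% on synthetic scenes is the separability ceiling, not a claim about
real-world accuracy.

## Numerical choices and degenerate inputs

- Even-count medians average the middle pair; gap pixels (zero valid
  observations) propagate as nodata through indices and classification
  and appear as a distinct nodata code in the final map.
- Non-finite predictor rows are dropped from training; candidate pixels
  with non-finite predictors are left unassigned rather than guessed.
- An empty candidate mask skips the class with a warning instead of
  failing the run; an empty scene window is a hard error.
- Per-class forests are seeded from the run seed plus the iteration
  index, so runs are bit-reproducible and classes remain independently
  re-runnable.
- Assigning a pixel twice is an invariant breach and raises immediately.

## Design choices where the design was open

- **Estimator shape.** The sequential classifier is exposed as an
  estimator class (`fit`/`predict`, `get_params`/`set_params`) wrapping
  scikit-learn forests, while the raster stages stay functional — raster
  stacks and vector layers are not tabular samples, so forcing the whole
  pipeline into transformer signatures would obscure the data flow.
- **Raster IO** uses TIFF with a JSON metadata tag (transform, CRS,
  nodata, band names, colormap) and an embedded palette for category
  maps; vectors are GeoJSON via shapely. Round-trips are bit-exact.
- **Gabon's ten-class legend** carries both flooded-forest classes
  (permanent and seasonal) alongside the eight optical classes; accuracy
  assessment may collapse them to a single flood class if reference
  labels cannot distinguish the two.
- **Training data** travel as pixel tables (row, col, class) and,
  for interchange, as one-pixel square polygons in GeoJSON.

## Problem sizes

Default test and acceptance runs use 200×200 scenes (40,000 pixels,
seven acquisitions, ten classes, ten forests) and 100×100 scenes for
unit-level fixtures; a full run takes a few seconds on one CPU. These
sizes exercise every code path — larger grids change runtime, not logic.

## Known limitations

- No reprojection, tiling or out-of-core processing; inputs must fit in
  memory on one grid.
- Cloud *detection* is not implemented (QA bits are trusted), and SAR
  preprocessing (speckle filtering, terrain flattening, dB calibration)
  is out of scope; flood thresholds are amplitude-scale-dependent.
- The equal-weight accuracy design over-weights rare classes in the
  overall figure; area-weighted estimators are not enabled by default.
- The settlement-buffer radius materially shapes the artificial-surfaces
  class and has no principled default; treat it as a per-country
  calibration.
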