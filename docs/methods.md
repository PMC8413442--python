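# Methods

## Model

The pipeline implements a composite environmental index in the ESAI
(Environmentally Sensitive Areas) tradition: raw factors are first mapped
to quality scores through lookup tables, the scores are combined into
thematic quality indices by geometric mean, and the indices are combined
into a single risk index by a weighted arithmetic mean.

The geometric mean is deliberate: it makes an index sensitive to its
weakest factor (one very poor score drags the index down regardless of the
others) and is only defined for strictly positive scores — the shipped
tables have a global minimum score of 1.25 (lowest accumulated-temperature
class), so the indices are always well defined. Internally the geometric
mean is computed as `exp(mean(log(score)))` for numerical robustness with
many factors.

The Environmental Area Index is the convex combination
`EAI = 0.6·CQI + 0.2·SQI + 0.2·VQI`. Low EAI means high ecological risk.
Two modelling choices here were genuinely open:

* **Three terms, not two.** The source formulation of the risk model
  prints only the climate and vegetation terms but assigns three
  coefficients (0.6, 0.2, 0.2) "to each index", and constructs a soil
  quality index that would otherwise be unused. This package makes the
  three-term form the default; the two-term variant is available simply by
  passing `IndexWeights(0.75, 0.0, 0.25)`-style weights (any weights
  summing to 1 are accepted).
* **What the weights mean.** The weights are interpretable as normalised
  random-forest variable importances. `estimate_weights` reproduces the
  procedure generically: fit a forest (default ntree = 1000, mtry = 2) of
  a user-supplied reference label on (CQI, SQI, VQI), normalise the
  mean-decrease-in-impurity importances to sum 1, and report out-of-bag
  accuracy as the goodness of the coefficients. What the reference label
  is in a real application is the user's choice; the synthetic module
  generates labels from a hidden ground-truth EAI so that the recovery
  loop is testable. Optional rounding to one decimal reproduces the style
  of headline weights such as 0.6/0.2/0.2; it is off by default.

## Score tables

All 16 tables ship as an editable CSV (`eai_risk/data/score_tables.csv`)
with one row per bin or category, and are validated on load (contiguous
bins covering the whole real line, scores in (0, 10]).

Conventions that the tables require but that a printed table cannot
express:

* **Bin endpoints.** Every binned table is a step function over
  lower-closed half-open intervals `[a, b)`; "< a" is `(-inf, a)` and
  "> b" is `[b, +inf)`. The same lower-closed rule applies to
  classification breaks, so a value exactly on a break belongs to the
  upper class. One uniform convention keeps scoring and grading
  consistent and makes every boundary testable.
* **Soil depth** is printed as four point values (0, 10, 30, 100 cm →
  2.5, 5.0, 7.5, 10.0); it is implemented as the step function
  `(-inf,10) → 2.5, [10,30) → 5.0, [30,100) → 7.5, [100,inf) → 10.0`,
  which reproduces every printed pair without inventing an interpolation
  rule.
* **Vegetation coverage** bins run to "> 158", beyond 100 %; the table is
  applied to the raw numeric variable exactly as printed (the source does
  not state the variable's units).
* **Altitude** is the one continuous factor whose scores *decrease* with
  the raw value (high ground is harsher); the monotonicity tests encode
  this direction explicitly.
* **Slope** is described in the source text as an auxiliary climate
  factor, but the climate index formula contains no slope term and the
  climate score table lists no slope scores; the package follows the
  formula (altitude, no slope). The aspect classes that the vegetation
  index uses can be supplied directly as codes 1–4 (sunny → shady) or
  derived from a DEM with `aspect_classes_from_dem` (gradient azimuth;
  south-facing = sunny in the northern hemisphere; flat cells default to
  the neutral half-sunny class).
* The published soil-quality grading prints its second break as both
  "5.1" and "5.14" in different rows; 5.14 is adopted.

## Rasters and missing data

A `Grid` is a 2-D array with a boolean nodata mask, a square cell size
(the model analogue of 500 m cells), a top-left origin and an opaque CRS
tag. Row 0 is the northernmost row and column 0 the westernmost, which is
the convention behind every "northwest → southeast" statement in the
package. GeoTIFF I/O goes through `tifffile` with the GDAL nodata tag, so
round-trips restore values (float32) and masks exactly. The nodata policy
is mask union at every combination step: a cell missing in any input is
missing in the output, and resampling masks any output cell whose
interpolation stencil touches a masked or out-of-extent source cell.
Categorical factors (erosion, vegetation-resistance, aspect classes) may
only be resampled with nearest-neighbour — interpolating class codes would
invent categories — and this is enforced through a per-factor kind
registry. Open water is not treated specially (no default lake mask); a
user can mask water by pre-masking the inputs.

## Classification

Natural-breaks grading uses exact Fisher–Jenks dynamic programming on the
sorted unique values with frequency weights: O(k·u²) in the number of
unique values u, deterministic, no sampling. Tests verify exact optimality
of the within-class sum of squared deviations against brute-force
enumeration on small instances, and dominance over equal-interval and
quantile breaks on larger ones. The pipeline's default for cross-period
comparisons is the *fixed* published break scheme, so that changes in
class shares between periods reflect changes in the index, not changes in
the classifier; per-run Jenks is a config switch
(`classification: jenks`).

## Risk accounting

Area shares are cell counts over unmasked cells (uniform cell area; no
latitude-dependent correction, as the pipeline is projection-agnostic —
a documented limitation). Elevation stratification uses the band edges
2300/3600/4400/5000 m by default; empty bands are reported as missing, not
as 0/0. Change rates between periods are percentage-point differences of
class shares, which therefore sum to zero within each stratum. Trend rates
are OLS slopes of annual regional means on calendar year, times ten
(units per decade), with the fit's R²; annual values rather than period
means are used for statistical efficiency. A perfectly constant series is
reported as rate 0 with R² 0 by convention.

## The synthetic generator

`generate_base_scene` builds every factor as an affine map of a latent
quality field: a deterministic NW→SE ramp plus seeded, spatially smoothed
Gaussian noise (5×5 moving-average kernel; default pointwise sd 0.10 in
latent units), clipped to [0, 1]. Factor ranges span all bins of the
corresponding score table. The DEM is built from a NW-high latent field by
rank mapping, which hits the prescribed band area shares (defaults
1.97/16.11/21.52/37.75/22.65 %) to within rounding; altitude enters the
climate index directly, so low ground in the southeast reinforces the
quality gradient there. One scene seed expands into fixed named
sub-streams (one per factor), so adding a factor never perturbs the
others.

`generate_scenario_series` adds linear trends to precipitation and
temperature at the per-decade scenario rates (7.2/10.5/12.3/16.6 mm and
0.07/0.28/0.56/0.62 °C for SSP126/245/370/585) over 2021–2100, by default
spatially patterned so that precipitation rises fastest in the southeast
and temperature fastest in the northwest (the pattern has regional mean 1,
so the regional trend equals the nominal rate). Interannual noise is a
yearly anomaly shared across ensemble members (defaults 38 mm and 0.40 °C)
plus smaller member-specific deviations (15 mm, 0.15 °C, 9 members);
the shared part sets the ensemble-mean variability, chosen as a plausible
interannual scale for a large high-mountain region. Soil factors are held
fixed in future runs (soil properties assumed unchanged), and the drought
index, accumulated temperature, PAR and vegetation factors also default to
static because no evolution rule for them is defined; each factor's
dynamic/static status is explicit in the pipeline.

What the generator does *not* emulate: real GCM spatial fields and their
inter-model spread structure, glacier/permafrost or vegetation feedbacks,
spatially correlated interannual weather, non-linear trends, and any
particular map projection. Passing tests therefore demonstrate that the
pipeline's algebra, accounting and recovery loops are correct under the
assumed structure — not that real-plateau area percentages would be
reproduced, which requires the real rasters.

## Problem sizes

Default test and demonstration sizes are a 200×200 scene (40 000 cells)
for end-to-end runs, 80×80 for shared fixtures, 80-year annual series with
9 members for trends, and 5 000 labelled samples with 1000-tree forests
for weight estimation; a full base-plus-four-scenario run completes in a
few seconds on one CPU.

## Known limitations

* Projection-agnostic: the CRS tag is carried but never interpreted, and
  no reprojection or latitude-dependent cell-area weighting is performed.
* The random-forest goodness figure depends entirely on the supplied
  reference labels; on synthetic labels generated from a hidden EAI it is
  near-perfect by construction and should not be compared to any
  real-data goodness value.
* Jenks on rasters with very many unique values is exact but quadratic in
  the unique-value count; the fixed-break mode is the default for large
  cross-period runs.
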