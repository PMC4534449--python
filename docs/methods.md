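# Methods

## The estimation problem

Occurrence data for established wild pig populations are presence-only:
surveys report where pigs are, never where they are absent. The package
therefore estimates a *logistic discrimination function* — a logistic
regression of presence records (1) against background records (0) drawn
uniformly from all sampling units — whose fitted surface is proportional to,
but not equal to, the absolute probability of occurrence. Background units
are availability, not pseudo-absence, and a unit may appear in both samples;
logistic discrimination is robust to that overlap. Alternative presence-only
estimators (MaxEnt-style machinery, prevalence-calibrated losses) are out of
scope by design: the discrimination function is transparent, and only
relative suitability is mapped.

The sampling unit is the watershed: a contiguous cell cluster with an id,
centroid, centroid elevation, and area. On synthetic landscapes the
partition is a discrete Voronoi tessellation grown from random seed cells —
not hydrological truth, but the analysis needs only a partition with areas,
centroids, and adjacency.

## Covariates

Seven watershed covariates, standardized (z-scores, sample SD with n−1)
before fitting:

| covariate | units | construction |
|---|---|---|
| days_above_35 | days/yr | mean count of station-days with lapse-adjusted tmax > 35 °C |
| days_below_minus4 | days/yr | mean count with lapse-adjusted tmin < −4 °C |
| snow_depth | m | multi-year mean April-1 depth, zonal mean |
| dist_water | km | zonal mean Euclidean distance to nearest retained water cell |
| forest_pct | % | area in deciduous/evergreen/mixed forest or woody wetlands |
| forage_pct | % | area in crop or mast-producing cover |
| heterogeneity | 0–3 | mean count of {water, cover, forage} within a 9 km² window |

Temperature thresholds (35 °C, −4 °C) are physiological limits for swine;
each watershed uses the up-to-10 closest stations within 250 km of its
centroid (ties broken by station id for a stable ordering), and daily
temperatures are lapse-adjusted to the centroid elevation at 6.49 °C per
1000 m *before* thresholding, because thresholding is nonlinear. Years with
partial records still contribute their available days, and duplicated daily
records are dropped rather than double-counted. Counts are averaged over all
selected station-years.

Streams below 3 cfs mean annual flow are removed as ephemeral before the
distance transform (cell-centre to cell-centre Euclidean distances; water
cells score 0). Raising the flow cutoff can only remove water, so mean
distances are monotone non-decreasing in the cutoff — a tested invariant.

The heterogeneity window is a disk of area 9 km² (radius √(9/π) ≈ 1.693 km),
the average sounder home range; the radius is rounded to the nearest whole
cell and boundary cells are included. A resource "counts" when at least one
positive cell lies in the window, implemented as binary dilation by the disk
and verified against an exhaustive per-cell scan. Two forest-class presets
exist (`FOREST_CLASSES` including woody wetlands — the default — and
`FOREST_CLASSES_NO_WETLANDS`), since the two reasonable definitions differ.

Standardization is computed on the union of the presence and background
samples used for fitting, so the fitted scale matches the estimation data;
the `sample` argument accepts any id set (e.g., all watersheds) when a
different convention is wanted. The per-column mean/SD travel with the table
so the hot-day optimum can be reported in natural days/yr.

## Occurrence ingest

A watershed-year is marked present when an intersecting population's total
polygon area exceeds 13 km² (three average individual home ranges) *and* the
intersection covers more than 2.5 % of the watershed — the first criterion
drops fragments too small to hold multiple home ranges, the second keeps
covariates meaningfully linked to the occupied fraction of large watersheds.
Both thresholds are strict inequalities and tightening either can only
remove records (tested monotonicity).

Introduction flagging: a first occupancy farther (centroid-to-centroid
Euclidean distance) than the dispersal threshold from every watershed
occupied the previous year is flagged as a likely human translocation.
First-survey-year records are founding populations and never flagged. A
flagged watershed re-enters the accepted occupancy set from the first later
year it is reported occupied again or an adjacent (boundary-sharing)
watershed is accepted; only flagged populations that never re-enter are
excluded from the presence sample. The dispersal threshold has no canonical
value and is a required parameter — the pipeline carries it in config and
echoes it in every run.

The background sample is a seeded uniform draw *without* replacement of
2 × |presence| watersheds from all watersheds (watersheds are finite distinct
units); the multiplier is configurable.

## Model fitting and averaging

The global model has the seven linear terms plus the square of standardized
hot days; the quadratic captures a thermal optimum (more hot days help, up
to a point). Marginality is on by default: the quadratic never enters a
subset without its linear term, giving 192 subsets (3 states for the
linear/quadratic pair × 2⁶); without the constraint, 256. The null
(intercept-only) model is included.

Each subset is fitted by Newton–Raphson maximum likelihood with
log-likelihood step-halving, converged at score norm < 1e-8; SEs come from
the inverse observed information. Quasi-separation is detected (diverging
coefficients) and attached to the fit as a warning — the fit, with its
computed likelihood, stays in the ledger rather than being silently dropped.
The fitter is cross-checked against an independent reference implementation
in the test suite (agreement ~1e-8 on coefficients and SEs).

Subsets are ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting the
intercept. Averaging uses Akaike weights with shrinkage: absent terms
contribute zero coefficients (pulling weakly supported effects toward zero),
unconditional SE = Σᵢ wᵢ √(seᵢⱼ² + (βᵢⱼ − β̄ⱼ)²), 95 % CI = β̄ ± 1.959964 SE
(the exact normal quantile, verified to reproduce published CI bounds to
four decimals), and importance(j) = Σ wᵢ over subsets containing j.

Prediction: the exponential form exp(Σ β̄ⱼ zⱼ) omits the intercept (RSF
convention — only relative values are mapped, and 1.0 is sample-mean
habitat); the logistic form includes it. Both induce the same ranking. The
hot-day optimum is −β̄₁/(2β̄₂) on the standardized scale, mapped to days/yr
through the stored mean/SD.

## Validation

The RSF plot index: withheld predictions are binned, and the Pearson
correlation between bin prediction midpoints and the observed fraction of
presence records per bin measures proportionality. Choices the index leaves
open, and the defaults here:

- **Bins**: 10 by default, configurable and reported in all outputs.
- **Midpoint**: interval centre for equal-interval bins; median predicted
  value within the bin for quantile bins (quantile interval centres are
  artifacts when the score distribution is skewed).
- **Pooling**: the k withheld folds of an iteration are pooled before
  binning, yielding one r per iteration per method; per-fold binning is
  available through `rsf_plot_index` directly.
- **Folds**: drawn over the union of presence and background records with
  labels preserved; k = 4 by default, fold sizes within 1.

Predictions for the index use the logistic form, whose bin means are
directly comparable to observed presence proportions under calibration.
Constant predictions or fewer than two non-empty bins raise a degenerate-
binning error rather than returning a meaningless correlation.

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes, with
all randomness flowing from one root seed through a fixed
`SeedSequence.spawn` order (fields, flow, land cover, snow, stations,
partition, occupancy):

- spatially autocorrelated fields (Gaussian-filtered white noise,
  per-field correlation lengths; zero length degenerates to white noise);
- station series with a seasonal cycle, a north–south gradient, and the
  adiabatic lapse built into station means, so hot/cold-day counts vary
  coherently in space;
- occupancy spread with a known truth: year-1 occupancy seeds the top 1 %
  of the true linear predictor, adjacent watersheds colonize with
  probability logistic(η), occupied stays occupied, and Poisson-rate
  long-distance introductions beyond the dispersal threshold carry ground-
  truth labels. The default intercept (−3.0) keeps terminal occupancy near
  a quarter to a third of watersheds, matching the survey regime where the
  background sample (2 × presence) remains drawable from all units;
- polygons: each occupied watershed emits the union of the 60 % (default)
  of its cells nearest its centroid. Real survey polygons are hand-drawn;
  this emission rule is a stand-in that exercises both aggregation criteria.

What the landscapes do **not** emulate: real hydrology (watersheds are
Voronoi cells), demographic dynamics (colonization is a contact process,
not births/deaths), observation error in surveys, and the exact covariance
structure of real covariates. Passing tests show the machinery is correct
under the stated generative model, not that the ecological conclusions
transfer to any particular real landscape.

For coverage and calibration testing, the record-level generator
(`simulate_discrimination_data`) draws standardized covariates from an
equicorrelated Gaussian (ρ = 0.2) and labels records from the logistic model
itself, so the discrimination function is the *exact* truth. The landscape
spread model cannot play that role: its colonization mechanism (repeated
yearly contact trials) does not have the fitted discrimination function as
its likelihood, so landscape-based fits recover the suitability ordering but
not the coefficients exactly. Suites that assert CI coverage of true
coefficients (50 replicates at 1500 presence + 3000 background) and
cross-validation calibration (10 iterations × 4 folds) therefore use the
record-level generator; introduction-flag recovery (20 replicates) uses the
full landscape simulator, whose labels are its ground truth.

## Numerical and degenerate-input conventions

- Constant covariate columns on the standardization sample raise an error
  naming the column; all-identical predictions raise a degenerate-binning
  error; a grid with no retained water raises an explicit error.
- Station selection ties at equal distance break by station id.
- AICc requires n > k + 1 and raises otherwise.
- kfold requires k ≥ 2 and at least k records.
- Weights are normalized against the minimum AICc before exponentiation, so
  ledgers with large AICc ranges do not underflow to all-zero weights.
- Problem sizes in the test suite (60–80-watershed landscapes, 1500-presence
  record designs, 10 cross-validation iterations) were chosen to exercise
  every code path at comfortable desk scale; all scale parameters are
  arguments, and nothing in the implementation depends on them.

## Known limitations

- Watershed distances are centroid Euclidean in km on a planar grid; no
  geodesy. User-supplied GeoJSON must already be in a planar km projection.
- The introduction detector conditions on the *accepted* occupancy
  reconstruction; around a flagged-but-not-yet-reincluded watershed, its
  satellites colonized in the following year can be transiently
  over-flagged (specificity ≈ 0.98 in simulation, not 1.0).
- No spatial autocorrelation correction in the fit: records are treated as
  independent, as in the original design; SEs are conditional on that.
- The pipeline's covariate standardization uses the estimation sample; the
  natural-scale hot-day optimum therefore depends on which sample was used
  to standardize, and is reported rather than asserted against any fixed
  value.
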