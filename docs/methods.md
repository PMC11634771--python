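# Methods

This note documents the models and procedures implemented in
`foramshift`, their assumptions, the parameters that matter, the
numerical conventions, and what the synthetic-data validation does and
does not demonstrate.

## Census model and conventions

A *subsample* is one plankton aliquot: a location, a calendar date, a
depth interval, a sampling device (net, CPR, pump, trap), a size
fraction (µm window; an empty upper bound means an open top fraction),
an optional filtered volume (m³), and per-species values that are either
raw counts or concentrations (individuals m⁻³).

Conventions fixed across the package:

- Depth intervals and latitude bands are half-open `[low, high)`; a
  band reaching 90° includes 90. Grid cells are half-open and anchored
  at (−90, −180); a point on a cell edge belongs to the cell starting
  there.
- Meteorological seasons are hemisphere-aware (north: DJF winter, MAM
  spring, JJA summer, SON autumn; south offset six months). Latitude 0
  uses the northern convention — the rule must be single-valued and any
  consistent choice at a measure-zero boundary is equivalent.
- Profiles group subsamples sharing device, calendar date and location
  within a tolerance (default 0.01°, configurable); members are ordered
  by upper depth and profiles with overlapping member intervals are
  flagged invalid rather than silently repaired.
- Taxonomic lumping sums morphospecies columns into their target name
  and conserves per-subsample totals exactly; species missing from the
  taxonomy pass through with a logged warning so partial taxonomies
  remain usable. Lumping maps must be idempotent.
- CSV dialect: comma-separated UTF-8, `.` decimal, ISO-8601 dates.
  Invalid rows are rejected with row-indexed diagnostics, never dropped
  silently.

## Size-normalized catch model

Catches from different mesh sizes retain different test-size windows.
The model assumes the cumulative concentration of individuals larger
than size *S* is proportional to `f_max − f(S)`, with

```
f(S) = 1 + (f_max − 1) · (S − S_sup1) / ((S − S_sup1) + (S_half − S_sup1))
```

so a measured window rescales to the ≥ `sz_norm` (default 100 µm)
standard by `C·(f_max − f(sz_norm)) / (f(sz_sup) − f(sz_inf))`. `f` is
strictly increasing and bounded by `f_max`, hence the denominator is
positive for any non-degenerate window.

`f_max` (dimensionless, > 1) and `S_half` (µm) are calibration constants
of the application and must be supplied by the caller; the package
deliberately ships no canonical values. `SYNTHETIC_MODEL`
(`f_max = 3`, `S_half = 200 µm`, `S_sup1 = 100 µm`) exists for tests and
the simulator only. Per-species models are supported through an override
table (all overrides must share `sz_norm`).

Windows lying wholly below `sz_norm` cannot be extrapolated upward and
are flagged `quantifiable = False` with their values left untouched;
windows straddling `sz_norm` are rescaled from their ≥ `sz_norm` part.
A window with an open top and a lower bound at or below `sz_norm`
already measures the standard stock and passes through unchanged. Raw
counts without a usable volume are flagged and excluded from
concentration analyses.

Each measured window independently estimates the full ≥ `sz_norm`
stock. For a contiguous partition of one catch, `normalized_total` sums
the measured concentrations over the combined window before normalizing
once; the factor denominator telescopes, which makes the result exactly
additive over any partition (verified to 1e−9 relative error in the
tests).

## Environmental fields

`GriddedField` holds one variable on a regular (lat, lon, depth, time)
grid; time is numeric decimal years at month centres
(`year + (month − 0.5)/12`). Interpolation is multilinear over the four
axes. Masked (NaN) corner values are excluded by renormalizing the
corner weights over the unmasked corners; an all-masked neighbourhood
returns NaN and the record is flagged, not dropped. Points beyond the
grid clamp to the edge within a tolerance (1 axis unit by default) —
surface samples above the top model level clamp to that level — and
raise beyond it; dates outside the month-centre span clamp
unconditionally. Longitude interpolates across the dateline when the
axis spans the globe.

Ω_calcite is always the ratio of the in-situ carbonate-ion
concentration to its calcite-saturation value; no carbonate-system
solving from alkalinity/DIC is attempted. The depth attached to a
record is the midpoint of its sampled interval (the "averaged sampled
depth"); whether a volume-weighted profile mean would be preferable is
an open question of the source analyses, and the midpoint is the
documented choice here.

NetCDF I/O uses the NETCDF3 (scipy) backend; a long-format CSV reader
exists for small fixtures.

## Diversity

Richness is the count of taxa from a fixed analysis set present
(value > 0) anywhere in a unit. The latitudinal gradient takes the 95th
percentile (linear-interpolation quantile — the default convention of
mainstream statistics software, documented because conventions differ)
of unit richness per 10° bin and fits a smooth curve through the
bin-centre points. The smoother is a penalized cubic smoothing spline
with GCV-selected stiffness; the scientific object is a smooth trend
line, not specific smoother coefficients, so the interface is
smoother-agnostic and the spline is the default. Fewer than 4 populated
bins skips the smoother with a warning.

Modern-vs-pre-industrial change maps pool presence across all units in
a cell (union) before differencing, because water-column profiles and
sediment sites differ in their support; the sign convention is
*modern gain positive*. Cells occupied in only one dataset are reported
separately, never as differences.

## Lateral and vertical migration

The poleward range edge is the 95th percentile of occurrence latitudes
(occurrence = record with concentration > 0; no minimum-abundance cut)
among near-surface (0–100 m) spring/summer records, clipped to 90°. The
literal "maximum of the northernmost 5%" is the overall maximum and is
noise-dominated; it remains available behind `literal_max=True`. At
least 20 occurrences per period are required.

The shift across the cutoff year (default 1990) is converted with
1° latitude = 111.32 km and divided by the difference of the two
periods' median occurrence years to give km yr⁻¹ (the time base of the
original analyses is not stated; period medians are this package's
documented choice). Positive = poleward in the Northern Hemisphere; the
machinery is hemisphere-symmetric but only northern analyses are
claimed.

The depth of maximum abundance of a species in a profile is the
midpoint of the member interval with the highest concentration, ties
breaking shallow; species absent everywhere yield missing. Eligible
profiles have ≥ 4 members within 0–200 m (net profiles, spring/summer —
all defaults overridable). The before/after comparison (cutoff 1997,
the midpoint of multinet-era data) uses a two-group one-way
fixed-effects ANOVA, identical to a two-sided pooled t-test (F = t²);
zero within-group variance maps to `insufficient_data` rather than a
spurious classification.

## Decadal trends, thermal responses, clustering

Decadal series average a species' concentration per half-open calendar
decade ([1940, 1950), …) within a latitudinal band (defaults 0–30,
30–50, 50–90° N; nets and pumps; 0–200 m). The decade means are scaled
by their maximum so values lie in [0, 1] with the largest decade at 1.
Scaling by the maximum rather than min-max is deliberate: the reported
quantity is the percent change relative to the initial level, and a
min-max scaling would pin the smallest decade to zero and force every
monotone decline to read as 100 %. Constant series are flagged
degenerate and excluded rather than normalized to a fabricated value.

The trend is an OLS regression of scaled decade means on decade index;
the p-value is the regression-ANOVA F test of the slope, and
`percent_change = (fitted_first − fitted_last)/fitted_first × 100`
(fitted endpoints rather than raw decade means, for robustness to
single-decade noise; declines are positive). Classification at α = 0.05
by slope sign. The regression runs on decade-bin means (matching the
per-decade presentation of the source analyses); a record-level variant
is a caller-side aggregation choice.

Thermal responses are min-max-normalized mean concentrations per 1 °C
in-situ temperature bin (records above 100 m), optionally split before/
after 1990. Species-by-bin matrices (missing bins zero-filled) are
clustered by principal-coordinate analysis on Euclidean distances —
equivalent to PCA of the centred matrix, and cross-checked against an
independent PCA in the tests — retaining two component scores, followed
by average-linkage agglomerative clustering (the linkage method of the
original analyses is not stated; average linkage is the documented
default).

## Niche envelopes and emergence

The occupied niche of a record set is the convex hull of its
(temperature, Ω_calcite) points after trimming each margin to the 1 %/
99 % quantiles. A hull with marginal trims is simple, reproducible and
conservative; a kernel-density contour would be a reasonable
alternative and the interface accepts any polygon. With the default
trims up to ~4 % of the source points (two tails × two variables) can
fall outside their own envelope, so the envelope is guaranteed to
contain ≥ 95 % of its source points, and "source emergence" is bounded
by the trimmed fraction (exactly 0 with `trim=(0, 1)`).

Projection re-evaluates every historical sampling location (latitude,
longitude, depth midpoint, month-of-year preserved) in the scenario
fields with the calendar year replaced by the horizon year. The
emergence fraction is the share of projected points strictly outside
the envelope (boundary counts as inside). Band summaries build one
envelope from all current points and evaluate emergence per band
(tropical 0–30°, mid 30–50°, high 50–90° N); whether emergence is
monotone from tropical to high latitude is reported as a diagnostic
boolean, never asserted.

## Synthetic world and surveys

The simulator emulates an idealized, zonally uniform North-Atlantic
sector on a 1° latitude grid (longitude is inert), 8 depth levels to
300 m, monthly resolution, 1940–2018 with a scenario extension to 2100:

- Temperature: 28 °C at the equatorial surface, −0.28 °C per degree
  latitude, −0.02 °C m⁻¹ with depth, a 1 °C seasonal cycle peaking in
  August, and linear warming of 0.2 °C decade⁻¹ (0.3 in the scenario
  period). The mild seasonal amplitude keeps the occurrence-latitude
  distribution narrow enough that the range-edge quantile estimator is
  well powered at the default survey size; the amplitude is a scenario
  parameter.
- Ω_calcite: 5.8 at the equatorial surface with linear latitude and
  depth gradients, declining multiplicatively by 1.5 % decade⁻¹;
  `co3satcalc` grows slowly with depth and `co3 = Ω · co3satcalc` by
  construction.
- Species: Gaussian thermal and depth niches, multiplicative decadal
  trends, Poisson counts (`expected concentration × volume`). Poleward
  motion is realized through environmental tracking: the effective
  optimum drifts as `T_opt + (w − g·v)t` (w = warming per year, g =
  meridional gradient, v = injected speed in degrees yr⁻¹), so the
  realized range edge moves at exactly v. A species with `v = w/g` is a
  pure isotherm tracker whose realized thermal optimum is constant —
  those species carry the thermal-optimum ground truth.
- Survey plan: 120 stations per date at uniformly random latitudes
  (continuous station positions avoid quantizing the edge quantile at a
  station spacing), six spring/summer dates per year, 8-interval
  multinet profiles over 0–200 m, 25 m³ per subsample. The mesh plan
  cycles by year between a coarse [150, ∞) fraction, a split
  [100, 150)/[150, ∞) pair (binomially partitioned from one Poisson
  total, conserving counts exactly), and the full [100, ∞) window, so
  harmonization is exercised on every path. Fixed seeds give
  bit-identical output.
- Sediment tables: presence = expected 0–200 m concentration at a
  pre-industrial reference year above a detection threshold
  (0.05 ind m⁻³), deterministic.

The default species set isolates one effect per species: movers with
10/5/0 km yr⁻¹, deepeners with 50/20/0 m between the pre/post-1997
period means, decliners with 25 %/40 % total declines over the
1940s–2010s fitted span, and two isotherm trackers. Deepening rates and
trend rates are back-computed so the *implied* recoverable quantity
(recorded in the truth table) equals the round target under the
default survey plan.

### What the validation shows — and does not

Parameter recovery on these surveys demonstrates that the estimators
are unbiased and correctly calibrated under the generating assumptions:
unimodal Gaussian niches, multiplicative trends, Poisson observation
noise, spatially uniform effort, and a smooth, zonally uniform ocean.
Real census compilations violate most of these: effort is concentrated
along cruise tracks and eras, devices differ systematically in
catchability beyond mesh size, niches can be skewed or bimodal,
preservation and seasonality bias the sediment baseline, and
environmental fields carry model error. Passing recovery tests
therefore validates the *machinery*, not the magnitude of any
real-world estimate. Problem sizes in the tests and acceptance script
(~57,000 profiles per survey, 1000-replicate null calibrations) were
chosen so each experiment completes in seconds to tens of seconds while
leaving the Monte-Carlo error well inside the asserted tolerances.

### Known limitations

- No correction for preservation, ontogeny or seasonal sampling bias.
- No species-distribution modelling; the range edge is a pure
  occurrence quantile.
- The ANOVA on depths of maximum abundance treats interval midpoints as
  continuous values; with coarse profiles the depths are strongly
  discretized and the F test is only asymptotically exact.
- The emergence metric depends on the envelope construction; a convex
  hull can overstate the occupied niche for curved clouds (and the
  idealized simulator produces a thin, strongly curved cloud, which is
  why synthetic emergence saturates faster than observational clouds
  would).
- Southern-hemisphere edge estimation is mechanically supported but
  untested against ground truth.
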