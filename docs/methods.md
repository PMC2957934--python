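# Methods

## The temporal model

The daily mean ambient endotoxin concentration E(t) (EU/m³) at a
monitoring site is modelled during the dry season (May–October; the wet
season is November–March and April belongs to neither) as

    E(t) = β₀ + β₁ E(t−1) + β₂ E(t−1)³ + β₃ RH(t) + β₄ RH(t)²
         + β₅ R12(t) + β₆ WS(t−1) + β₇ WS(t−1)² + ε(t)

fitted by ordinary least squares with classical standard errors (robust
HC1 errors behind a flag). The measurement day runs 2000 hours of the
previous calendar day to 2000 hours of the labelled day, matching a
24-hr filter sampler changed each evening; all daily covariates follow
that window. RH(t) is the 24-hr mean relative humidity (%); WS(t−1) is
the single wind-speed reading at 2000 hours of day t−1 (m/s); R12(t) is
the 12-hr recirculation index described below. The single lag removes
the serial correlation of the daily series (checked by a Ljung–Box test
on the residuals); the cubic lag term bends the response at high
concentrations, making the deterministic map E↦β₀+β₁E+β₂E³ contractive
around its fixed point, so the process is stationary with a well-defined
operating level. Default coefficient values (the generator's truth) are
β = (2.822, 0.6901, −0.0084, −0.0122, −0.0010, 1.4705, −0.1618,
−0.0211), giving a dry-season operating point near 4 EU/m³ under the
default synthetic meteorology.

Before fitting, the series is imputed: values above a configurable
outlier threshold (default 20 EU/m³) are set missing, then every missing
day whose two calendar neighbours are present is replaced by the
neighbour mean; longer gaps stay missing, and present non-outlier values
are never altered. The lag column is built on the full calendar before
the season filter, so the first May day may use 30 April as its lag.

### Recirculation index

For a window of hourly wind vectors (from-which direction convention,
converted to transport vectors u = −s·sin θ, v = −s·cos θ), the wind run
is S = Σ|Vᵢ| and the net transport L = |ΣVᵢ|; the recirculation factor
is R = 1 − L/S ∈ [0, 1]. R is invariant to rotation, to uniform speed
scaling and to time reversal; it is 0 for collinear same-direction flow
and 1 when transport cancels. A window is valid with ≥ 9 of 12 hours
present (75%, configurable); a dead-calm window (S = 0) is missing. The
daily covariate is the mean of six overlapping 12-hr windows (starting
1200, 1600, 2000 of day t−1 and 0000, 0400, 0800 of day t, with "2400
day t−1" ≡ "0000 day t", half-open hourly intervals labelled by start);
the day is missing if any window is missing, since averaging only the
valid windows would bias the index toward calm periods. Single-station
vector integration is assumed throughout; multi-station trajectories are
out of scope.

### Model selection

Model selection is a greedy search over term sets by deletion,
substitution and addition moves under V-fold cross-validated squared
error — a cross-validation surrogate for data-adaptive selection
algorithms of the deletion/substitution/addition family. Folds are
contiguous blocks of the time-ordered rows (the seed rotates the block
offset) to respect serial dependence. A move is accepted only if it
lowers the CV loss by at least `min_rel_improve` (default 1%), and
near-ties within that margin resolve toward the smaller term set:
without the parsimony tie-break, a substitution that removes a weak term
can smuggle in an unrelated covariate on fold noise. With the defaults,
five pure-noise candidates added to the true term library are excluded
in ≈ 95% of replicates while the informative terms are retained.

### Residual whiteness

`check_autocorrelation` reports the residual autocorrelations at lags
1..K (default 10) with the marginal ±1.96/√n band for plotting, but the
pass/fail flag is an omnibus Ljung–Box test at the 5% level: requiring
every lag to sit inside the marginal band would falsely reject ≈ 40% of
genuinely white series at K = 10 (1 − 0.95¹⁰).

## Spatial statistics

For one analyte and season, the network is a dates × sites matrix.
Between a site pair over p valid shared days the coefficient of
divergence is COD = √(p⁻¹ Σ((xᵢ−yᵢ)/(xᵢ+yᵢ))²): 0 for identical series,
→1 for maximal divergence, and |r−1|/(r+1) for series in constant ratio
r (0.14 at r = 1.33, 0.40 at r = 2.33). Days with xᵢ+yᵢ = 0 contribute
no term (0/0); a day where exactly one value is 0 contributes 1. The
daily spatial CV is the across-site sample standard deviation over the
across-site mean (ddof = 1 by default and switchable, since either
convention is defensible), computed on days with at least 4 reporting
sites (CV on 2–3 sites is unstable; configurable). Pearson correlations
of each site against the central monitor are tabulated per analyte with
an average row; r² bands classify agreement as high (≥ 0.8), moderate
(0.5–0.8) or poor (< 0.5). Geometric-mean summaries substitute
0.01 EU/m³ — the field-blank equivalent concentration — for zeros before
the log transform.

## Concentration mapping

Daily surfaces are inverse-distance-weighted interpolations
(power 2, all stations, 1-m snap distance) on a node-registered grid
with 0.25-km spacing spanning 50 × 60 km centred on the central monitor
(201 × 241 nodes). IDW was chosen as the minimal "simple" interpolator:
it is exact at stations, continuous elsewhere, and every node value is a
convex combination of the inputs, so surface extrema never exceed input
extrema. Only days with ≥ 6 reporting sites are mapped (configurable);
period-average maps are node-wise means of the daily maps (mapping
before temporal averaging, because with few qualifying days the
alternative order would let a single day's station set reshape the
average). Since IDW is linear in the station values, with a constant
station set the two orders agree to rounding; with varying station sets
they do not, and the mapped-then-averaged surface is the one reported.
Accuracy is assessed by leave-one-out validation: each site-day is
predicted from the remaining sites with the same interpolator, recording
the signed percentage error (mean = bias) and absolute percentage error
(mean = average error); zero observations are excluded from percentage
aggregates and counted. Tertile maps rank the qualifying days by the
central site's concentration (ties to the lower tertile, counts
differing by at most one) and average each third separately.

## Land-use buffer regression

Raster land-cover areas within 10-km and 20-km circular buffers use the
cell-centre-in-circle rule, which converges to the exact area as the
cell shrinks (≈1% error for a 10-km buffer at 0.25-km cells); CAFO
source polygons are intersected with the buffer circle exactly via
shapely. Each category is regressed separately against site
concentrations (category-wise r² is the reported quantity; multivariable
LUR is a non-goal), day by day for the daily analysis — days need ≥ 3
sites and a non-constant predictor — and once on period-average
concentrations restricted to days passing the ≥ 6-site mapping filter.
`aggregate_categories` builds composite predictors (e.g. agriculture =
cropland + pasture) for testing the generator's driver directly.

## The synthetic-data generator

The generator emulates a multi-year campaign in a flat agricultural
valley; all randomness flows from explicit integer seeds and identical
seeds reproduce every file bit-for-bit.

**Meteorology.** Hourly RH, temperature, wind speed and direction.
Dry-season days draw a daily-mean RH around 22% (sd 4.5%, AR(1)
persistence 0.3, plus a mild May→July→October cycle), wet-season days
around 70%, April 33%; a diurnal cycle peaks at dawn. Wind is a steady
~1.8 m/s northwesterly, except during stagnation episodes — dry-season
runs of 2–4 days occurring at rate 0.35 — when speeds drop to ~0.8 m/s
and the direction reverses diurnally (daytime northwesterly, nocturnal
drainage flow rotated by a per-episode angle of 120–180°), producing
recirculation indices of ~0.25–0.45 against ~0.06 on steady days.
A `season_mode="dry"` switch generates the dry regime for every calendar
day, for simulations of an uninterrupted run of dry-season days.

**Landscape.** A 50 × 60 km domain at 0.25-km cells: an urban core at
the centre, cropland to the west, south and (farther out) east, pasture
in the southwest, grassland and forest to the north/northeast — i.e.
agriculture on three sides and native vegetation on the fourth — with
CAFO rectangles in the west/southwest, parks and schools inside the
core. Sites: one central monitor, 10 schools within 7 km of it, and
residences across the urban fringe and agricultural belt, the first
pinned far west so the network spans the gradient. Coordinates are local
planar km (origin at the southwest corner); at this 20-km scale no
geodesy is needed.

**Concentrations.** The central endotoxin series follows the temporal
model exactly, with Gaussian innovations (sd 1.0 EU/m³) truncated at
zero — truncation rather than resampling, a simplification that matters
on < 0.5% of dry-season days at the default operating point. Every other
site adds a land-use offset plus Gaussian site noise (sd 1.2 EU/m³).
Recorded offsets are exactly linear in the 20-km cropland + pasture
area, δᵢ = 0.005·(agᵢ − min ag) EU/m³ (all ≥ 0); generation applies them
relative to the central site (δᵢ − δ_central), so the cross-site mean
surface is linear in agricultural area while the central series remains
uncontaminated. Co-pollutants: PM2.5 is a regional AR(1) field with
small site noise (cross-site r ≈ 0.98); EC is a shared daily driver
scaled by proximity to the urban core (r ≈ 0.9); coarse PM shares the
endotoxin spatial driver plus its own regional term (r ≈ 0.65); and
PM10 = PM2.5 + PMc identically. The resulting correlation ordering —
PM2.5 > EC > PMc > endotoxin, endotoxin the most heterogeneous — is the
qualitative structure the spatial stages are designed to resolve.
Missingness is independent Bernoulli (3% per site-day per measured
channel; PM10 missing when either component is), plus one forced
singleton gap and one forced 25 EU/m³ outlier day at the central site to
exercise the imputation rule.

**What the generator does not emulate.** Real topography and land-cover
taxonomies, wind fields with spatial structure across the network,
emission dynamics (the land-use signal is a static additive offset),
sampler-level measurement error models, and seasonal population changes
in the bioaerosol itself. Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes, not that the assumed
structure is a complete description of field data.

## Calibration choices and known limitations

The generator's defaults are a deliberate compromise. With the
coefficient vector and unit innovation sd fixed, the share of variance
the model explains is controlled by the meteorological variability: wide
persistent humidity and wind excursions raise R² toward the ~0.5 seen in
field fits, but they also push the process toward the zero-truncation
boundary and inflate the finite-sample bias of OLS with a lagged
response. The defaults favour estimator calibration: the operating point
sits near 4 EU/m³ (dry-season means 3.5–4 EU/m³, within the observed
range for such networks), truncation affects ≲ 0.5% of days, and a
single dry-season fit yields R² ≈ 0.25–0.35.

Even so, refitting the 8-term model on 615 simulated days carries an
irreducible Hurwicz-type small-sample bias: across many replicates the
mean lag coefficient sits ≈ 0.014 below its generating value (≈ 2%) and
the humidity coefficient ≈ 0.007–0.011 below, with the deficit
redistributed across the collinear intercept/RH/RH² block. Both vanish
as the series lengthens and are exactly zero in noiseless fits, so they
are properties of the estimator at this sample size, not implementation
defects. Parameter-recovery checks at n = 615 should therefore expect
the lag and humidity terms near, and occasionally beyond, two
Monte-Carlo standard errors from truth; the recovery simulation runs in
perpetual dry regime (a single uninterrupted block of dry-season days)
because a multi-year calendar embedding pays an additional
autoregressive start-up bias at each season boundary.

Numerical conventions: dates are ISO-8601 and a measurement day is
labelled by its end date; missing values are empty CSV fields; grids are
written as ESRI ASCII with row 0 at the south edge in memory; IDW snap
distance is 1 m; random streams derive from `numpy.random.default_rng`
with user-visible integer seeds.
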