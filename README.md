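# endoair

Tools for characterising the temporal and spatial variability of ambient
endotoxin — lipopolysaccharide from Gram-negative bacteria, measured in
endotoxin units per cubic metre (EU/m³) — across a daily multi-site
monitoring network in an urban area surrounded by agricultural land.
Airborne endotoxin matters for respiratory epidemiology (asthma onset
and exacerbation in children in particular), yet unlike the regulated
particulate pollutants it is rarely monitored at more than one location,
so exposure studies need to know how far one central monitor generalises
in time and space.

The package implements the full analysis chain and a seeded synthetic-data
generator with the statistical structure the analysis assumes, so every
stage is testable end-to-end without access to monitoring data:

* **Meteorological features** (`endoair.met`) — hourly wind and humidity
  records become daily covariates, chiefly the 12-hr air-recirculation
  index `R = 1 − L/S` (net transport over wind run; 0 = straight-line
  flow, 1 = fully recirculating air), averaged over six staggered 12-hr
  windows per measurement day.
* **Temporal model** (`endoair.temporal`) — a lagged nonlinear OLS model
  for the daily dry-season (May–October) concentration:

      E(t) = β₀ + β₁E(t−1) + β₂E(t−1)³ + β₃RH(t) + β₄RH(t)²
           + β₅R12(t) + β₆WS(t−1) + β₇WS(t−1)² + ε(t)

  with singleton-gap/outlier imputation, residual whiteness diagnostics,
  cross-validated deletion/substitution/addition model selection, and
  transfer of the variable forms to other sites.
* **Spatial statistics** (`endoair.spatial`) — pairwise site regressions,
  coefficients of divergence (COD), daily spatial coefficients of
  variation, and central-site Pearson correlation tables per analyte
  (endotoxin, PM2.5, PM10, coarse PM, elemental carbon).
* **Concentration mapping** (`endoair.mapping`) — inverse-distance-weighted
  daily surfaces on a 0.25-km grid over a 50 × 60 km domain, time-averaged
  after mapping, with leave-one-out accuracy assessment and tertile maps.
* **Land-use regression** (`endoair.landuse`) — land-cover areas within
  10-km and 20-km circular buffers of each site (cell-centre rule for the
  raster, exact circle–polygon intersection for CAFO sources) regressed
  against daily and period-average concentrations.
* **Synthetic data** (`endoair.synth`) — seeded hourly meteorology with
  dry-season stagnation episodes, a landscape with agriculture on three
  sides of an urban core, and multi-site concentrations whose recorded
  ground truth (coefficients, site offsets, noise levels) supports
  parameter-recovery testing.

## Worked example

```python
import endoair as ea

# a 3.5-year synthetic campaign (May 2001 start), 23-site network
ds = ea.simulate_dataset(n_days=1280, start_date="2001-05-01", seed=0)

model = ea.EndotoxinLagModel.from_dataframe(ds.conc, "CENTRAL", ds.features)
fit = model.fit()
print(fit.to_frame().round(4))
print(fit.nobs, fit.n_imputed, round(fit.rsquared_adj, 3))
```

prints the coefficient table of the dry-season fit at the central monitor
(734 days used, 47 imputed, adjusted R² = 0.227):

```
                 estimate      se       p
intercept          2.1523  0.8275  0.0095
lag                0.7693  0.0893  0.0000
lag_cubed         -0.0104  0.0015  0.0000
mean_rh            0.0034  0.0615  0.9553
mean_rh_sq        -0.0012  0.0013  0.3515
recirc12           1.9848  0.3140  0.0000
ws_2000_prev       0.0505  0.4265  0.9058
ws_2000_prev_sq   -0.0551  0.1502  0.7140
```

The lag and recirculation terms dominate, as they should: yesterday's
concentration and stagnant, recirculating air are the main drivers of a
high-endotoxin day (the generating lag and recirculation coefficients,
0.6901 and 1.4705, sit within ~1.6 standard errors of these estimates).
`fit.check_autocorrelation()` confirms the single lag leaves white
residuals (Ljung–Box p = 0.36). The spatial stages on the same dataset:

```python
snap = ea.snapshot(ds.conc, "endotoxin", "dry")
cv, summary = ea.daily_cv(snap)            # median 0.30, range 0.12-1.01
snaps = {a: ea.snapshot(ds.conc, a, "dry")
         for a in ("endotoxin", "pmc", "ec", "pm25")}
ea.spatial_correlation(snaps, "CENTRAL")   # Average row: pm25 0.98 > ec 0.92
                                           #   > pmc 0.66 > endotoxin 0.57
loo = ea.loo_validate(snap, ds.landscape.sites)
loo.mean_abs_error_pct                     # 41% for endotoxin vs 4% for pm25
```

Endotoxin is the most spatially heterogeneous analyte in the network —
lowest cross-site correlation, largest spatial CV, largest leave-one-out
mapping error — while PM2.5 behaves regionally, and the land-use buffer
regression recovers the agricultural signal (mean daily r² 0.25 at 20 km
vs 0.08 at 10 km; 0.99 for the period-average concentrations, where the
daily noise has averaged out).

A `click` CLI exposes the same stages
(`endoair simulate | features | fit-temporal | spatial-stats | map |
landuse | run-all`); `run-all` writes every table, grid (.asc) and a JSON
manifest with seeds and checksums so a rerun is verifiably identical.

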