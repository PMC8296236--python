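# heatattr

Estimation of heat-attributable mortality from multi-city daily
warm-season time series, using a two-stage distributed-lag nonlinear
model (DLNM) with cross-validated selection of the best of eight daily
temperature metrics.

The pipeline, per country:

1. **First stage** — for each city and each temperature metric, fit a
   quasi-Poisson regression of daily deaths on a tensor-product
   cross-basis of natural cubic splines in exposure (knots at the 10th,
   75th and 90th percentiles of the pooled regional distribution) and in
   lag (0–10 days, two log-spaced internal knots), adjusting for
   day-of-week and a seasonal/long-term natural spline with four degrees
   of freedom per year.
2. **Second stage** — reduce each fit to its lag-cumulated
   exposure–response curve, pool the curves by multivariate
   random-effects meta-analysis, and shrink city curves toward the pool
   by best linear unbiased prediction (BLUP).
3. **MMT & attribution** — locate the minimum-mortality temperature
   (MMT) and its percentile (MMP), then compute the heat- (HAF),
   extreme-heat- (≥ P90, EHAF) and moderate-heat- (MMT–P90, MHAF)
   attributable fractions from daily excess risks `m_i · (1 − 1/RR_i)`.
4. **Metric selection** — leave-one-year-out cross-validation per metric;
   the metric with the highest pooled out-of-sample R² is selected
   overall, and per city.

Because the original mortality series are available only on request, the
package ships a first-class synthetic-data generator
(`heatattr.synthetic`) producing multi-city panels with a known lagged
heat effect, known MMT and known true attributable fractions, which
powers the entire test suite.

## Metrics

`tmean, tmax, tmax_day, tmin, tmin_night, tmean_app, tmax_app, tmin_app`
— the apparent-temperature variants combine air temperature with dew
point (Kalkstein–Valimont form by default, Steadman vapour-pressure form
via config; relative humidity is converted with the Magnus formula).

## CLI

```sh
# generate a synthetic two-city country (CSV panels + truth.json)
heatattr simulate --out data/ --n-cities 2 --n-years 21 --seed 1

# full analysis: MMT/MMP, HAF/EHAF/MHAF and CV tables per country
heatattr run --config config.yaml --data-dir data/ --out results/

# leave-one-year-out CV for a single metric
heatattr cv --metric tmean --data-dir data/ --out cv.json
```

Input CSVs use the canonical dialect (UTF-8, comma-separated, header
row, ISO dates): columns `city, date, deaths, tmean, tmax, tmax_day,
tmin, tmin_night` plus either the eight metric columns directly or
humidity inputs (`dewpoint_mean`/`rh_mean`, optionally time-resolved
variants) from which the apparent metrics are derived. Files named
`COUNTRY__CITY.csv` are grouped by country. `config.yaml` mirrors
`heatattr.StudyConfig` field for field.

## Library layout

| module | contents |
| --- | --- |
| `heatattr.data_io` | `CityPanel`, CSV read/write, validation, `run_pipeline` |
| `heatattr.metrics` | the eight metric derivations, apparent temperature |
| `heatattr.dlnm_basis` | natural cubic splines, cross-basis, lag cumulation |
| `heatattr.regression` | design assembly, quasi-Poisson IRLS, prediction |
| `heatattr.pooling` | multivariate meta-analysis, BLUP |
| `heatattr.curves_attribution` | RR curves, MMT/MMP search, HAF/EHAF/MHAF |
| `heatattr.crossval` | LOYO splits, R²/RMSE scoring, metric selection |
| `heatattr.synthetic` | seeded panel generator with known ground truth |
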