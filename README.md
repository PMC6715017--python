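# searchrhythms

Weekly, seasonal, and geographic pattern analysis for normalized
search-volume time series, built for infodemiology studies of health
contemplations — the motivating case is interest in "sundowning"
(late-day agitation in dementia), whose search volume carries a weekly
rhythm, a winter peak, and a latitude gradient.

Google Trends reports relative search volume (RSV): daily query counts
normalized to integers on a 0–100 scale.  This package answers three
questions about such a series and its state-level companion table:

1. **Weekly (circumseptan) pattern.**  The daily series is decomposed with a
   continuous Morlet wavelet transform (ω₀ = 6) and reconstructed from all
   periodic components with period < 14 days, with the series mean added
   back, so trend and seasonality cannot confound day-of-week comparisons.
   On the reconstructed series an OLS day-of-week factor model (Monday
   reference) gives the percent effect of each day,

   percent(day) = 100 · β_day / β_Intercept(Monday),

   with 95% percentile confidence intervals and SDs from a nonparametric
   case bootstrap (resampling days with replacement, stratified by weekday;
   default 5000 replicates), plus a pooled Sunday-versus-rest contrast.
2. **Seasonal pattern.**  Per calendar year, the winter mean (Dec/Jan/Feb)
   is compared with the summer mean (Jun/Jul/Aug) by a paired t-test across
   years: t = mean(d) / (sd(d)/√n), d = winter − summer.
3. **Geographic pattern.**  Per-state search index is regressed on state-
   center latitude and on the percent of daylight hours with sunshine, as
   two separate simple regressions on z-scored variables, reporting the
   standardized slope β (equal to the Pearson r), its SE, R², and a
   two-sided p; predictors are screened for skew (adjusted Fisher–Pearson,
   threshold 1.0) and log10-transformed when skewed.

Because RSV extracts are not exactly reproducible, validation is built on a
first-class synthetic module (`searchrhythms.simulate`) that generates
Trends-like series and state tables with *planted* effects, so every
estimator has a parameter-recovery test surface.

## Worked example

```python
from searchrhythms import (SeriesSpec, GeoSpec, generate_daily_series,
                           generate_geo_dataset, DayOfWeekModel,
                           SeasonalContrastModel, GeoAssociationModel)

# one year of synthetic daily RSV with a planted +10.9% Sunday uplift
series = generate_daily_series(SeriesSpec(), seed=42)
print(DayOfWeekModel(series).fit(n_boot=5000, seed=42).summary())
```

```
Day-of-week percent effects vs Monday (band-reconstructed series)
n_obs = 364, n_boot = 5000, CI level = 95%
day         percent   ci_low  ci_high     sd  sig
Tuesday       -0.11    -1.96     1.65   0.93
Wednesday     -0.25    -2.20     1.60   0.97
Thursday       0.03    -1.72     1.72   0.88
Friday        -2.48    -4.23    -0.80   0.89  *
Saturday      -0.99    -2.91     0.92   0.95
Sunday        10.38     8.14    12.58   1.12  *
Sunday vs rest: +11.08% [9.30, 12.96] (SD 0.92)
```

Sunday is estimated 10.4% above Monday (CI [8.1, 12.6]) and 11.1% above the
pooled rest of the week — the planted +10.9% uplift, recovered through the
full wavelet + bootstrap path.  The Friday reading illustrates the expected
occasional false positive among the remaining days at the 95% level.

```python
long = generate_daily_series(SeriesSpec(n_days=1461, start_date="2014-01-01"), seed=42)
print(SeasonalContrastModel(long).fit().summary())
print(GeoAssociationModel(generate_geo_dataset(GeoSpec(), seed=42)).fit().summary())
```

```
Seasonal contrast over 4 years (calendar winter grouping)
winter (DJF) mean 78.9 (SD 2.5); summer (JJA) mean 33.0 (SD 0.8)
paired t(3) = 54.93, two-sided p = 1.33e-05

State-level simple regressions (n = 50 states)
predictor       beta      se     R2           p  log10
Latitude       0.701   0.103  0.491    1.48e-08  no
PercentSun    -0.325   0.136  0.106      0.0212  no
```

The winter/summer ratio reflects the generator's annual cosine (amplitude
0.455, peak mid-January), and the geographic fits recover the planted
standardized slopes (+0.648 for latitude, −0.429 for percent sunshine)
within single-sample error.

## Command line

```sh
searchrhythms simulate --seed 3 --out-daily daily.csv --out-geo states.csv
searchrhythms weekly   --input daily.csv --seed 3 --stdout
searchrhythms seasonal --input daily.csv --stdout
searchrhythms geo      --input states.csv --stdout
searchrhythms report   --daily daily.csv --geo states.csv --seed 3 --out-dir out/
```

`report` writes `report.json` (all three analyses with provenance: inputs,
config hash, seed, version) plus per-stage CSVs.  Readers accept the Google
Trends export dialect (metadata preamble, `Day,<query>: (<region>)` header,
ISO dates, `<1` read as 0.5) and infer daily/weekly/monthly cadence; the
weekly analysis requires daily cadence.

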