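# Methods

This note records the models implemented in `searchrhythms`, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
validation does and does not establish.

## Data model

The canonical series is a pandas Series of normalized search volume
(integers 0–100 in real exports) on a gap-free daily `DatetimeIndex`, at
least 28 days long.  Day of week is always derived from the calendar date,
never from a position index, so arbitrary start dates behave like real
exports.  The state table carries one row per state: search index (0–100),
state-center latitude (degrees N), and percent of daylight hours with
sunshine (0–100).

## Wavelet band-pass reconstruction

Weekly effects are estimated on a band-limited reconstruction of the series
rather than on the raw values, because slow structure (trend, annual
seasonality) aliases into weekday contrasts: each weekday samples a ramp at
a different phase, so e.g. a declining spring series makes Sundays look
systematically lower than Mondays.  The band-pass removes everything slower
than two weeks before the factor model is fitted.

Conventions:

- Mother wavelet: Morlet with central frequency ω₀ = 6 and normalization
  π^(−1/4), the de facto default of the standard continuous-wavelet
  literature; it makes Fourier period ≈ 1.033 × scale.
- Scale grid: dyadic, s_j = s₀·2^(j·dj) with dj = 1/20, covering periods
  2–32 days by default (Nyquist-limited below; an octave of margin above
  the weekly band).  Period ↔ scale conversion uses the factor
  4π/(ω₀+√(2+ω₀²)) and is exactly invertible.
- Transform: the mean-centered series is zero-padded to the next power of
  two that is at least twice its length (so the convolution is linear, not
  circular) and multiplied per scale by the analytic Morlet kernel in the
  frequency domain.  The kernel is built as the DFT of the *daily-sampled*
  wavelet: spectral mass above the Nyquist frequency is folded onto the
  aliased bins.  The fold matters only at the smallest scales, but it
  matters a great deal there — without it the implied time kernel acquires
  long sinc tails and components near the 2-day limit (e.g. the third
  harmonic of a weekly comb, period 7/3 days) are attenuated by ~25%,
  which propagates into a visible downward bias of the weekly effect
  estimates.
- Reconstruction: the standard delta-function sum
  dj·√δt/(C_δ·ψ₀(0)) · Σ_j Re(W_j(t))/√s_j with the published C_δ = 0.776,
  restricted to scales with period in [min, max) — half-open so that
  complementary bands add back to the full reconstruction exactly — plus
  the stored series mean.  "Below 14 days" is implemented literally as
  period < 14.
- Cone of influence: per time point, the largest trustworthy period given a
  √2·s e-folding distance to the nearer edge.  Coefficients inside the coi
  are *kept* in the reconstruction (the least destructive choice, and the
  common default of continuous-wavelet software); the coi vector is
  exposed so analyses and tests can mask edges.

Fidelity is checked against independent oracles: an FFT periodogram for
peak location, a hard FFT band-pass for band isolation (r > 0.999 on
noise-free mixtures, well above the 0.95 test threshold), and a brute-force
time-domain convolution for individual coefficients.

## Day-of-week effects

On the reconstructed series, OLS of value on an intercept plus six weekday
indicators (Monday reference).  The design is saturated, so coefficients
equal weekday-mean differences exactly; this identity is verified against a
group-mean oracle rather than assumed.  Effects are reported as the ratio
percent(day) = 100·β_day/β_Monday, which is scale-free — multiplying the
series by any positive constant leaves all percents unchanged.

Uncertainty: nonparametric case bootstrap.  Daily observations are
resampled with replacement *within weekday strata*, which guarantees every
replicate design is fittable; each replicate's six ratios (and the pooled
Sunday-versus-rest ratio) are recomputed from the resampled weekday means,
exploiting the saturated-design identity for speed.  95% percentile
intervals and the bootstrap SD are reported; 5000 replicates by default; a
seed is required (there is no hidden global RNG).  Alternatives (residual
bootstrap, weekly block bootstrap, BCa intervals) are deliberately not
implemented but the scheme is isolated in two small functions so they can
be swapped in.  No multiple-testing adjustment is applied across the six
day coefficients; with six 95% intervals, one spurious "significant"
weekday in roughly a quarter of null series is expected behavior, not a
defect.

The Sunday-versus-rest contrast refits with a single Sunday indicator, so
its intercept is the pooled non-Sunday mean (observed stratum weights).

Known bias: the bootstrap ignores residual autocorrelation, and the
band-pass slightly reshapes a weekly comb (its near-Nyquist harmonic sits
at the edge of the analyzed band), leaving a small downward bias of order
a quarter of a percentage point at a +10.9% planted uplift — well inside
the bootstrap interval width at realistic noise levels (coverage ≈ 97% in
the recovery study).

## Seasonal contrast

Per calendar year, mean search volume over Dec/Jan/Feb versus Jun/Jul/Aug;
the month lists are taken literally, so December of year Y belongs to year
Y's winter by default (`grouping="calendar"`); the meteorologically
contiguous alternative (December joins the following winter) is available
because the two differ at series edges.  Years missing either window are
dropped and logged.  The paired t statistic is the closed form
mean(d)/(sd(d)/√n) with a two-sided p from the t distribution (df = n−1);
identical differences raise a degenerate-test error rather than returning
an infinite statistic.  The seasonal analysis runs on the raw series (the
weekly band-pass would remove the very signal of interest), and the
month-window means are cadence-agnostic, so weekly or monthly exports are
accepted.

## Geographic associations

The skew screen replaces visual density-plot inspection with a numeric
rule: adjusted Fisher–Pearson sample skewness (the bias-corrected g₁), with
|skew| > 1.0 triggering a log10 transform of that predictor; the threshold
is configurable and ∞ disables it.  Only predictors are screened, not the
response.  Each predictor is fitted in its own simple regression with both
sides z-scored, so the reported β is standardized and equals the Pearson
correlation, and R² = β² by construction; both identities are asserted in
tests at 1e-10, and slope/SE/p are verified against a hand-coded
normal-equations OLS.  The standardized-β reading also reproduces the
observation that reported (β, R²) pairs in this literature track β² ≈ R².
A multivariable fit is intentionally out of scope here; the two predictors
are strongly collinear in real geography, and the simple-regression
summaries are what the analysis reports.

## Synthetic data

`SeriesSpec` builds a latent daily series

latent(t) = baseline · (1 + trend·t/365) · (1 + A·cos(2π(doy−peak)/365.25))
· (1 + u·1[Sunday]) · exp(e_t),

with e_t a stationary Gaussian AR(1) (innovation SD `noise_sd`, lag-1
correlation `noise_ar1`), then normalizes to the Trends dialect:
round(100·v/max v), integers, maximum exactly 100.  Multiplicative
log-AR(1) noise keeps values positive and mimics the heteroscedastic,
relative character of search-volume fluctuation; the rounding is kept
because integer quantization is a real nuisance the estimators must
tolerate (it contributes up to ~1 percentage point of distortion to a
noise-free uplift, and dithers away under realistic noise).

Defaults are the study conditions the package emulates: +10.9% Sunday
uplift; annual cosine amplitude 0.455 (winter/summer ratio ≈ 2.7) peaking
on day-of-year 15; 2% yearly trend; noise SD 0.05 with AR(1) 0.3; 364 days
(52 exact weeks) from Monday 2016-01-04.  The noise magnitude and
autocorrelation are stand-ins chosen to look like a mid-volume Trends
series; nothing in the emulated study constrains them.

`GeoSpec` draws latitude uniformly (default 27–48°N, the contiguous-US
span), builds percent sunshine with an exact in-sample correlation to
latitude (default 0, so planted partial slopes equal marginal ones), and
sets the standardized index to β_lat·z(lat) + β_sun·z(sun) + noise.  By
default the residual SD is derived so the index has unit variance — this
is what makes planted slopes directly comparable to fitted standardized
coefficients, and it is why slope/correlation combinations implying
negative residual variance are rejected.  The index is then mapped
affinely onto 0–100 (50 + 15·z, clipped; clipping is a <0.1% tail event at
the default scale).

What the synthetic validation does **not** establish: real Trends noise is
not log-AR(1); real exports at multi-year range are weekly, not daily;
Trends renormalizes between downloads, so two real extracts of the same
query differ; and state search indices are spatially autocorrelated, which
the independent-noise generator does not emulate (and the regressions do
not model).  Passing recovery tests therefore demonstrate correctness of
the estimators under the stated generative model, not robustness to every
property of real search data.

## Problem sizes and determinism

The recovery studies use 200 generator seeds with 500 bootstrap replicates
(weekly), 100 seeds of 13 years (seasonal), and 200 fifty-state tables
(geographic) — sizes at which the Monte Carlo error of the reported means
is an order of magnitude below the tolerances being checked, while the full
study still runs in seconds.  Every stochastic step takes an explicit seed;
given (inputs, config, seed) the whole report is bit-reproducible except
for its timestamp.
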