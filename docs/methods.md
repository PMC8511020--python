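# Methods

This note documents the models, conventions and numerical choices behind
`ensogrowth`, in the order the pipeline runs them, and closes with what the
synthetic validation does and does not establish.

## Exposure model

The ENSO exposure of a child is a scalar per *tropical year* — May of
calendar year *t* through April of *t* + 1 — defined as the arithmetic mean
of the eight monthly index values May–December of *t*. The May boundary
respects the typical event life cycle (onset in late boreal spring, peak
near year's end, decay the following spring) and the sharp drop in
persistence across the boreal-spring "spring barrier": a calendar-year mean
would blend the decay of one event with the onset of the next. Interviews
in January–April inherit the *previous* tropical year's exposure. The mean
requires all eight months; a partial window raises rather than silently
averaging fewer values.

State labels (El Niño / La Niña / neutral) follow the Oceanic Niño Index
convention: monthly anomalies relative to a reference climatology, a
centered 3-month rolling mean, and a ±0.5 °C threshold on the extreme
smoothed anomaly within the tropical year. Numerical details that the
convention leaves open are fixed as follows: rolling windows centered on
the edge months of the tropical year borrow the adjacent month outside the
window when the record supplies it and are dropped otherwise; if both
thresholds are crossed within one tropical year, the larger absolute
excursion wins. The reference climatology is either static (full-record
per-month means, the default for synthetic data) or "moving" in the NOAA
CPC style, implemented as 30-year base periods advancing every 5 years and
clipped at the record edges; the choice is a parameter, and which one was
used is visible in the exposure-table provenance.

Event anomalies for attribution are OLS residuals of the yearly May–December
means on a linear trend in tropical year. The fit window defaults to the
full supplied series (the window is a parameter; no single convention
dominates here).

## Teleconnection detection

For calendar month *m*, a pixel's month-*m* values across years are Pearson-
correlated with the index at month *m* − lag (default lag 2, crossing the
year boundary when needed). Correlating within calendar month removes mean
seasonality by construction; because shared slow trends would still inflate
the correlation, a per-month linear year trend is removed from both series
by default before correlating. Two-sided p-values use the t distribution
with n − 2 degrees of freedom, reduced by one more when the trend is
removed, so the null rejection rate stays nominal — the suite checks that
the fraction of zero-loading pixels flagged matches the binomial tail
P(Bin(12, 0.05) ≥ 3) ≈ 1.96%. No multiplicity correction is applied across
pixels or months; the ≥ 3-months rule is itself the guard against isolated
false positives. Zero-variance pixel-months are marked degenerate and never
count as significant.

Aggregation deliberately mirrors two differently-phrased rules: a country is
temperature-teleconnected when the population-weighted share of flagged
pixels is **at least** 50% (weak inequality), while an admin-1 unit carries
the positive-precipitation flag when the land-area-weighted share of pixels
with ≥ 3 significant *positive* months is **strictly above** 50%. The
asymmetry is intentional and tested at the boundary.

## Panel model and estimator

The estimating equation is

```
Y_ict = α + β_n·NINO_t + β_p·[NINO_t · I(PosPrecip_i)] + γX_ic
        + f(t_region) + FE_cr + ε_ict
```

with country-specific slopes for mother's education (years) and mother's age
at birth (years), interview-month indicators and linear survey-year trends
both specific to each of five world regions, and fixed-effect cells for
country × urban/rural. The urban/rural indicator itself lives in the cells
(a separate country-interacted urban control would be exactly collinear;
if requested it is pruned and logged). Supplementary variants are spec
toggles: decade fixed effects instead of linear trends, lagged exposure
terms, exposure × age-category interactions, and an unweighted mode.

Estimation is weighted least squares. The fixed-effect cells are absorbed
by weighted within-cell demeaning (default) or included as explicit dummy
columns; the two routes are algebraically identical and the suite asserts
agreement to ~1e−9 on both coefficients and standard errors. The solver is
a rank-revealing pivoted QR: columns numerically collinear (relative
tolerance 1e−10) are pruned with their names logged, and a saturated design
(rank zero after demeaning) is an error. Reference categories are the first
sorted month/decade per region; slope estimates are invariant to this.
Weighted R² and the weighted outcome mean refer to the full model including
the absorbed cells, and all quantities are invariant to rescaling the
weights by any positive constant.

### Two-way clustered variance

Scores are aggregated within tropical years (common global shock per year)
and within admin-1 units (serial and spatial correlation), and combined by
inclusion–exclusion: V = V_year + V_admin − V_year×admin. Each term gets a
CR1-style small-sample multiplier G/(G−1)·(N−1)/(N−K), with K counting all
estimated parameters including absorbed cells. Confidence intervals use the
normal ±1.96 critical value by default, with a t(G_min − 1) option.

The inclusion–exclusion difference is not positive semi-definite in general.
On realistic samples, sparse nuisance dummies (single month-region cells)
routinely come out with non-positive variance — independent implementations
of the same formula show the same behavior. The estimator therefore
distinguishes: a non-positive variance on any *exposure-block* coefficient
(the terms of scientific interest) is a hard error, while nuisance terms
get NaN standard errors and are listed in
`EstimationResult.negative_variance_terms`. For deliberately small samples
(decade/region subsamples) a spectral fix is available and used by the
subsample driver: the combined meat matrix is projected onto the PSD cone
by zeroing negative eigenvalues, standard practice in multi-way-clustering
implementations.

### FWL machinery, placebo, curves

The Frisch–Waugh–Lovell identity — the weighted slope of residualized
outcome on residualized exposure equals the joint-fit coefficient — is used
three ways: as an exactness test (agreement to ~1e−15), as the fast path
for permutation refits, and for the residual-curve visualization. The
placebo test permutes the year→exposure mapping wholesale (within-year
structure untouched) and reports the two-sided rank p-value
(1 + #{|β*| ≥ |β̂|})/(n_perm + 1). Because residualization is linear in the
per-year exposure values, the permutation basis is residualized once and
each refit reduces to quadratic forms in a length-Y vector, making hundreds
of permutations cost milliseconds. The residual curve is an Epanechnikov
kernel-weighted local polynomial (degree 1 by default — the standard choice
for boundary behavior; degree is a parameter) with bandwidth 0.7 in
unscaled exposure-residual °C, fit separately for the negative/neutral and
positive precipitation subsamples with the estimation weights entering the
kernel weights; pointwise 95% bands use the local sandwich variance with a
locally pooled residual variance, and grid points with fewer than
degree + 2 in-support observations return NaN.

## Weighting schemes

`average_country` normalizes the survey sampling weights so that all of a
country's observations — pooling its surveys — sum to exactly one; every
country then contributes equally (the estimand is the effect in the average
sample country). The alternative reading, per-survey normalization first,
is available as an option and still yields unit country totals.
`average_child` multiplies the normalized weights by the country's under-5
population. Both schemes correct for countries having different numbers of
surveys of different sizes.

## Attribution arithmetic

All attribution outputs are linear: per-child shift = anomaly ×
coefficient; children crossing a threshold = probability shift ×
population; intervention coverage = total σ-deficit divided by a per-child
effect size, with CI bounds dividing by the effect-size CI (order
reverses). The SDG pace is 100·prevalence/(target − base) with base year
2017 by default (midpoint of the 2015–2018 prevalence window) and target
2030. Headline numbers are reported at two significant figures, and — as in
the published chains this mirrors — rounding happens at each reporting
boundary (the probability shift is rounded to 1.9 pp *before* scaling by
the 311 M under-5 population, giving 5.9 M); unrounded values are always
emitted alongside. Intervention effect sizes are external published inputs
shipped as an editable YAML config, never hard-coded; the shipped values
are the per-child WAZ treatment effects consistent with the
meta-analytic literature on nutrition interventions.

## The synthetic world

The generator emulates the *structure* of the study inputs, not their
realism, and every parameter is planted and recoverable:

* **Index**: seasonal cycle plus an AR(1) anomaly (coefficient 0.9,
  innovation SD 0.45 °C) whose innovation SD is modulated by
  1 + 0.5·cos(2π(m−12)/12), concentrating variance in November–January.
  This yields tropical-year May–December means with SD ≈ 0.8 °C, matching
  the dispersion of the observed index (large events reach ±2 °C).
* **Grid**: pixel value = deterministic climatology + loading × lag-2 index
  anomaly + Gaussian noise; precipitation uses signed loadings and a floor
  at zero. Blocks with zero loading (4 of 20 countries), positive
  precipitation loading (1/3 of admin units in teleconnected countries) and
  negative loading are always present. The balanced positive/negative admin
  split keeps the interaction coefficient estimable at the scaled-down
  sample sizes used in validation; in the real world positive-precipitation
  areas are a small minority, which the generator does not reproduce.
* **Surveys**: waves rotate round-robin (each country every 4 years),
  interview months uniform (optionally ENSO-dependent, to exercise the
  survey-timing robustness check), admin units uniform, cluster-level
  log-normal sampling weights (SD 0.3 — a stand-in; real design effects are
  not emulated), and outcomes generated exactly from the panel equation
  with planted β_n = −0.0251 σ/°C and interaction +0.0733 σ/°C for WAZ
  (magnitudes of the published estimates), country×urban intercepts around
  −0.93, small region trends and month effects, and iid child noise.
  0.56% of records per outcome are quality-flagged (set to improbable
  magnitudes) and 0.57% set missing, to exercise filtering. The exposure
  effect is applied only in countries with nonzero temperature loading —
  teleconnection is the causal pathway — and the sample rule excludes the
  others, mirroring the design.
* **Child noise SD 0.3σ** is a deliberate validation choice, set by a power
  calculation: with the measured design factor SE(β̂_n) ≈ noise·2.46/√n (at
  the realistic index scale), n = 200,000 children over 33 tropical years
  puts a 10%-of-β_n recovery check at ≈ 2.3 standard errors. Real survey
  residual dispersion is ~1σ, roughly three times larger; at that level no
  sample of this size could pin the coefficient to 10%, so passing recovery
  tests here demonstrates correctness of the estimator, not attainable
  precision on real data.
* Common year-level and admin-level shocks default to zero (iid noise);
  the confidence-interval coverage validation switches them on
  (SD 0.03σ and 0.02σ) because clustered inference is only meaningfully
  stressed when within-cluster correlation exists.

One integer seed determines everything; independent `SeedSequence` streams
for the index, geography, grid noise, nuisance parameters and survey draws
keep artifacts bit-reproducible and mutually stable when sizes change.

## Validation scales

The suite validates at sizes chosen to balance statistical resolution
against run time: exactness checks at n ≤ 5,000; dense-oracle equivalence
at ≤ 1,000 rows; point recovery at 200,000 children; CI coverage over 200
replicates of 20,000 children (accepted band 85–98%); placebo null
uniformity over 40 replicates × 99 permutations and power over 10
replicates × 199 permutations; teleconnection calibration on 3,000 null
pixels and 400 signal pixels over 30 years. The full suite runs in about
three minutes on one core.

## Known limitations

* The generator's demography is schematic: no age/sex gradients in
  outcomes, no spatial correlation beyond admin shocks, no
  mortality/selection processes, and threshold-outcome prevalences are
  lower than real populations because of the quiet noise choice above.
* Teleconnection detection and estimation share one index realization per
  world; detection errors (absent at the planted signal-to-noise) would
  propagate into the estimation sample definition, a dependence real
  applications share.
* The spectral PSD fix changes small-sample inference in subsample runs; it
  is reported where used and never applied silently to the main fit.
* Logistic variants of the threshold-outcome models and spatial-HAC
  standard errors are out of scope; the linear probability model is the
  supported path for threshold outcomes.
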