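# Methods

## The data model

One record is a roost × month observation of birds arriving at dusk,
stratified by flock size.  `pairs` counts dyads (units of two birds);
`family_flock_birds` counts every individual arriving in flocks of 3–6;
`fledglings` is the same birds minus the two parental birds of each flock.
A record is internally consistent when

* every non-missing count is a non-negative integer,
* `all_parrots = singles + 2·pairs + family_flock_birds + large_flock_birds`
  whenever all strata are present,
* `n = (family_flock_birds − fledglings)/2` is a non-negative integer and,
  when `n > 0`, each flock has 3–6 birds, i.e. 1–4 young
  (`n ≤ fledglings ≤ 4n`).

Validation reports violations per record and never mutates data.  Missing
cells (empty or `-`) stay missing; pooled counts sum over the roosts
reporting a given month, and a pooled stratum is missing only when every
roost missed it.  Whether observers could record an adults-only small
flock is not documented for this design; the identity above deliberately
excludes that case, since a 3–6 bird flock with no young contradicts the
family-flock definition (a parental pair plus its fledged young).

## Medians and interquartile ranges

All central tendencies are median/IQR.  Quartiles use linear interpolation
at index `h = (n−1)p` (the numpy/R type-7 default).  This convention
reproduces every published 5-year annual summary row exactly; rows with 4
or 6 contributing years can differ from the printed IQR by < 1 count
because the original table was computed from unrounded monthly means.

## Seasonal–trend decomposition

A monthly series on a contiguous calendar grid (gaps as NaN) is split
additively into `seasonal + trend + remainder`:

1. **seasonal** — month-wise means of the detrended series (the January
   mean, February mean, …), centred so the 12 values sum to zero.  Without
   centring the series level would be shared ambiguously between seasonal
   and trend.
2. **trend** — degree-1 loess of the deseasonalised series on time, with
   tricube weights `w = (1 − (d/d_max)³)³` over the `q = ceil(span·n)`
   nearest months.  The default span puts 19 months in the window, the
   conventional trend window for a period-12 series with a strictly
   periodic seasonal.
3. **remainder** — the residual, reported missing at months that were
   interpolated before fitting.

Steps 1–2 are alternated.  The alternation is a linear contraction
(measured factor ≈ 0.17 per pass on study-length series), and a fixed small
number of passes leaves visible leakage of a linear trend into the monthly
means; the implementation therefore iterates until the trend changes by
less than 1e−8 (relative to the series scale), capped at 50 passes, which
recovers a noiseless `trend + seasonal` input to ~1e−6.  A fixed pass count
can still be forced via `n_iter`.  Internal gaps are linearly interpolated
before fitting (and flagged); leading/trailing gaps are trimmed, never
extrapolated.  At least 24 observations and at least one observation in
every calendar month are required.  There is no robustness (outlier
re-weighting) pass and no high/low-pass post-smoothing of the seasonal —
the procedure is deliberately the plain three-step scheme.

Seasonal components are summarised as range-standardised profiles
`(s − min)/(max − min)` on [0, 1]; a constant seasonal has no profile and
raises instead of dividing by zero.

## Permutation inference

Linear models use ordinary least squares with treatment-coded factors and
sequential (type-I) sums of squares in declared term order; `r² = 1 −
SSE/SST`.  Nested model projections use orthonormal bases from SVD, so
aliased terms are detected by rank (a term adding no rank raises a design
error naming it).  A constant response yields F = 0, r² = 0 by convention.

p-values come from resampling.  Single-term models permute the raw
response.  Models with nuisance terms use Freedman–Lane: to test term *j*,
fit the model without *j*, permute its residuals, add them back to its
fitted values, and recompute term *j*'s sequential F on the reconstructed
response.  The nuisance space excludes any interaction containing term *j*,
which would otherwise absorb the tested effect.  With `B` permutations,

```
p = (1 + #{F* ≥ F_obs}) / (B + 1)
```

so p is floored at `1/(B+1)`; ties count as exceedances (conservative).
The default is `B = 4999`.  In calibration simulations the rejection rule
is `p ≤ α`, the convention under which a permutation test is exact on the
p-value grid; simulations here confirm `P(p ≤ α) ≈ α` across α for the
trend test under an exchangeable null.  Because the resampling scheme of
the original analysis software is not fully documented, permutation
p-values are comparable across implementations only in significance
category, not digit-for-digit.

ANCOVA follows the parallelism protocol: fit the factor × covariate
interaction first; if its permutation p ≥ α (default 0.05) drop it and
report the additive parallel-slopes model, otherwise keep the interaction
model, flagged accordingly.

## Trends

The time covariate is months elapsed since the first included observation
(0-based), shared across roosts in grouped fits, so a per-year slope is
exactly 12× the per-month slope.  Missing months keep their calendar
position.  Family-flock responses (`n_family_flocks`,
`mean_fledglings_per_flock`) are derived per record; records without a
family flock have no mean-per-flock and are dropped from that response.
The default roost subset for grouped fits excludes the fifth roost, whose
occupancy collapsed during monitoring and whose decline would otherwise
dominate the common slope.  Classical t/F statistics are reported alongside
permutation p-values and labelled, since both appear in this literature.

## Demography estimators

Annual summaries fix the denominator window to June–July and the singleton
window to August–September.  Each window's mean is taken over its available
months (for two months the mean and median coincide, resolving the
wording ambiguity between the two in the source tables).  Percentages are
`100 · stratum_mean / all_parrots`; years with no June–July totals have no
summary and are excluded from across-year medians rather than zero-filled.
`expected_recruits` rounds half-up to whole birds.  The fledge rate
defaults to 1.0 young per laying female (the long-term estimates for this
population, 0.9–0.95, are treated as ≈ 1 when equating the singleton
proportion with a fledged-young proportion) and is configurable.
`post_fledging_loss` clamps to [0, 1] and warns when the fledgling-based
estimate exceeds the singleton-based one (possible under sampling noise).

## The synthetic generator

Each roost × stratum follows a log-linear negative-binomial model:
`count ~ NB(mean = exp(a + b·t + s[month]), dispersion θ)` with a zero-sum
12-value template `s`, a per-month log trend `b`, and NB dispersion θ
(mean–dispersion parameterisation; θ → ∞ is the Poisson limit).  Singleton
counts in August–September additionally receive a binomial draw with
success probability φ (the breeding fraction) out of the roost's expected
June–July total of that year.  Family flocks are drawn as flock counts;
each flock independently carries 1–4 young from a categorical distribution
(default (0.6, 0.3, 0.08, 0.02), mean ≈ 1.52 young/flock), so
`family_flock_birds = 2n + fledglings` and the stratification identity
holds by construction.  Whole months are deleted with a per-roost
missingness probability.  All draws flow from one seeded numpy Generator,
so tables are bit-reproducible.

The default configuration mirrors the five-roost study design: windows of
61/61/61/38/28 months from mid-2004; totals peaking June–July and
singletons August–September; pairs ≈ 55% and large flocks ≈ 35% of birds;
baseline (non-breeding) singletons ≈ 0.3% of the total, so the
August–September singleton peak is produced by the φ mechanism itself;
family flocks ≈ 3% of the total in flock units with fledglings declining
at 0.01/month on the log scale; the shortest-run roost declining steeply
(−0.08/month); φ = 0.05, θ = 8, 4% missing months.  A `deterministic` mode
emits rounded expected values for noise-free checks, and `null_config()`
gives an exchangeable null (equal 60-month windows, no trends, flat
templates, φ = 0, no missingness) for type-I-error calibration — under a
seasonal or composition-shifting configuration the trend-test null would
not hold by construction, so calibration is defined against the
exchangeable case.

What the generator does **not** emulate: movement of birds between roosts
(the 2008 influx in the real data), observer error, adults-only small
flocks, and any mortality process linking the singleton- and
fledgling-based recruitment estimates — so the generator's implied
post-fledging loss is not calibrated to the real 20–25% and passing
recovery tests says nothing about those features of real data.

## Problem sizes and numerical choices in the test suite

Recovery experiments use 10–20 replicates of the full five-roost design;
type-I-error calibration uses 200 replicates of the exchangeable null with
499 permutations per test; the exhaustive-enumeration oracle uses all 720
permutations of six observations; loess is checked against an explicit
per-point weighted-least-squares solve at 1e−10 and against an independent
lowess implementation at machine precision.  Seasonal rank-order recovery
is evaluated on the across-replicate mean profile with tie-aware ranks,
because the cosine templates contain exactly tied month pairs whose mutual
order is undefined and adjacent months differ by less than single-replicate
noise at the default dispersion.

## Known limitations

* The decomposition assumes additivity on the count scale; strongly
  multiplicative seasonality would call for a log transform upstream.
* No autocorrelation-aware or mixed models: inference treats months as
  exchangeable under the null, as in the original analysis style.
* The singleton estimator is a *minimum* breeding proportion: baseline
  non-breeding singletons bias it upward slightly (visible in the
  generator, where recovery is within half a percentage point).
* Percentage denominators use June–July totals of the same calendar year;
  roost-years missing that window drop out of the medians entirely.
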