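# Methods

This note documents the models implemented in `oge`, the choices made where
the design was genuinely open, the synthetic-data generator's assumptions,
and the numerical conventions.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Sentiment statistics

**GMS.** The geolocalized mean sentiment of a city-day-topic cell scores
posts +1 / 0 / −1 (positive / neutral-or-mixed / negative) and averages,
equivalently `(P − N) / T`.  Mixed-sentiment posts are pooled with neutral:
both carry zero weight, and the statistic's magnitude shrinks as their share
grows.  A cell with no posts is a *missing value*, never zero — zeros would
fabricate neutrality on silent days and bias every downstream difference.

**Topic matching** is plain lowercase substring containment against fixed
keyword lists (e.g. the stem `quarantin`, the phrase `social distanc`).
There are no word boundaries, so false positives such as *chinatown* →
China, or *lockdown* also matching the economy keyword *dow*, are accepted
consequences of the rule.  Every post also counts toward `overall` exactly
once, regardless of how many subtopics it matches.  A pooled `national`
pseudo-city aggregates counts over all posts irrespective of location
(pooled counts, not an average of city GMS values).

**Coherence.** The five subtopic GMS values per city form a vector in R⁵ in
the fixed order (distancing, China, TA, economy, mask); φ(t) is the mean
pairwise angle between city vectors.  A vector is unusable on a day when
any component is missing or all components are exactly zero (its direction
is undefined); the day's normalizer is the number of pairs actually used
rather than the nominal n(n−1)/2.  Days with fewer than two usable vectors
are missing.  Cosines are clamped to [−1, 1] (tolerance 1e-12) before
arccos, and cosines within that tolerance of ±1 snap to exactly 0°/180° so
collinear vectors don't accumulate ~1e-6-degree arccos noise.

**Moving averages** (7-day for GMS display, 3-day for coherence) are
trailing by default — a smoothed value never uses future data — with the
divisor equal to the number of present values in the window; a centered
variant is available as an option.

## Stationarization

For any series pair entering a correlation or regression, both members are
Augmented Dickey-Fuller tested and *jointly* first-differenced until each
rejects the unit-root null at α = 0.05, so both always sit at the same
integration order.  Choices the protocol leaves open:

* ADF regression: constant, no deterministic trend (sentiment and mobility
  series have nonzero means but no mandated trend); lag length by AIC.
  Both are exposed as parameters.
* `max_order = 3`: more differencing than the worst case ever observed in
  practice indicates a degenerate series, and is an explicit error.
* Missing values: interior gaps are dropped for testing; a difference
  across a gap is a missing value, never a long-lag difference.
* Epidemic series are truncated to start at their first nonzero count
  before testing (the leading zero plateau is trivially nonstationary
  relative to the growth phase and carries no information).

## Intervention analysis

The stationarized GMS series is fit by exact maximum likelihood (state-space
ARIMA) with the four policy indicators as exogenous regressors, scanning
(p, q) over a grid and keeping the lowest-BIC converged fit.  Conventions:

* **Indicators are not differenced.**  The dependent series is differenced
  as needed, but the binary z_{kt} enter as defined: differencing a one-day
  impulse would manufacture a spurious −1 the following day.
* **Z_k = β̂_k / σ̂(β̂_k)**, two-sided against the standard normal; the 0.05
  critical value 1.959964 is used throughout.
* **Covariance:** observed information matrix (`cov_type="oim"`).  The
  default outer-product-of-gradients covariance degenerates for one-day
  impulse dummies — the dummy absorbs its own residual, so its
  per-observation score vanishes at the MLE and the OPG standard error
  diverges.  The OIM standard error behaves like the asymptotic σ_ε.
* **MA sign:** the estimation backend uses the plus convention; reported MA
  coefficients are negated to follow the model equation's minus convention.
* **BIC ties** (within 1e-9) break toward smaller p + q, then smaller q —
  parsimony first, matching the BIC's intent.
* Non-converged grid cells are skipped with a warning; indicator columns
  with no variation (an event outside the window, a city without a shelter
  order) are dropped and recorded rather than fit.
* All four indicators are fit jointly in one model, not one event at a
  time.
* Residual diagnostics: instead of visual ACF/PACF inspection, a Ljung-Box
  check on the selected fit's residuals is available from the fitted
  statsmodels results object; it is reported, never a gate.

Per-city sensitivity is the count of events with |Z| past the critical
value; cross-policy comparisons regress one event's per-city Z on
another's by OLS after omitting cities with |Z| > 10 (extreme outliers
reflect near-zero standard errors, not strong responses).

## Association analysis

Pearson correlations are computed after joint stationarization; a pair
needs at least 10 overlapping observations or it is skipped at panel level.
Granger testing is the literal two-step procedure: (1) the BIC-optimal lag
p of the *univariate* autoregression of the mobility series, scanned over
1..14 (reported significant lags cluster up to about two weeks; the floor
is 1 because an order-0 autoregression is degenerate), then (2) a Wald
chi-squared test of the p added GMS-lag coefficients in the augmented OLS
regression.  A likelihood-ratio variant is available behind a flag.  No
multiple-testing correction is applied by default — panel tables carry raw
0.05 flags — with Benjamini-Hochberg available as an option.

## Synthetic-data generator

The generator emulates exactly the structure the analysis assumes:

* **Latent sentiment** per (city, topic): AR(1) with coefficient 0.5,
  innovation sd 0.1, mean −0.3 (city-level crisis sentiment is persistently
  somewhat negative), started from the stationary distribution.
  Innovations share a common factor across cities with weight √ρ (default
  ρ = 0.5), so ρ is exactly the cross-city innovation correlation.  Policy
  effects add an impulse or step to the latent of every topic.
* **Link:** sentiment class probabilities are a softmax of
  (a + b·x, 0, a − b·x) with a = 0, b = 1 — bounded away from 0/1, with
  p_pos − p_neg monotone in the latent x.  Any bounded monotone link would
  do; softmax is the simplest with both properties.
* **Volumes:** negative-binomial daily post counts (mean 600, dispersion
  10) mimic overdispersed daily feeds; each post lands in one subtopic
  bucket (share 0.08 each) or a no-topic bucket.  Post text is minimal —
  a topic keyword plus a serial number — just enough for substring matching
  to recover the intended topic exactly.
* **Mobility:** M_t = baseline + c·latent_{t−lag} + AR(1) noise,
  independently for driving and walking.  Defaults (baseline 100 % of a
  reference day, c = −20, lag 2, noise sd 2) put the series on the scale of
  percent-of-baseline route-request volumes.
* **Epidemic:** rounded logistic cumulative curves with exact leading zeros
  before a per-city onset day, optional Gaussian reporting noise (which may
  produce negative daily counts; these are retained as-is, matching how
  real reporting corrections are handled).
* Scenario defaults are the real study's conditions — 49 cities, daily from
  2020-02-26 to 2020-05-01, volumes above the 500-post/day inclusion
  threshold.  All generators are pure functions of (spec, seed).

What the generator does *not* emulate: real language (texts are synthetic
markers), geographic spatial correlation beyond the single common factor,
weekday/weekend volume seasonality, and sentiment-classifier bias.  Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under the assumed data-generating structure, not that the
substantive conclusions transfer to any particular real feed.

## Study conditions used by the verification suites

The statistical acceptance tests (`tests/test_acceptance.py`) use these
problem sizes, chosen to estimate each rate to within a couple of percent
of Monte-Carlo error:

* **Calibration** (no injected effect): 100 five-city panels of 200 days
  for the intervention z-scores (500 city-level fits, four indicators
  each); 500 replicate pairs for the Pearson and Granger nulls at n = 200.
  Each nominal-0.05 rate must land in [0.03, 0.07].
* **Recovery:** a −0.8 latent impulse at daily volume 1000 over 200 days,
  200 replicates, through the full GMS → differencing → BIC scan → z-score
  pipeline with the scan restricted to (p, q) ∈ [0, 2]² (the generator's
  ARMA core is low-order, and the small grid keeps the 200-replicate study
  tractable); required sign-and-significance rate ≥ 90 %.  Granger
  coupling 0.8 at lag 2 with unit-scale mobility noise (sd 0.1, matching
  the latent innovation scale, per the low-noise coupling scenario), 200
  replicates, required detection ≥ 95 %.
* **Order recovery:** I(0)/I(1)/I(2) at n = 200, 500 replicates, required
  ≥ 85 % each.
* **Oracles:** coherence against an explicit pair loop (tolerance 1e-10,
  100 random vector sets); the Granger Wald statistic against an
  independent restricted-vs-full least-squares computation at n = 5000
  (relative tolerance 1 %).

## Known limitations

* The ARMAX scan treats non-convergence as a skipped cell; a pathological
  series where every cell diverges raises rather than guessing.
* The two-step Granger procedure reuses the univariate BIC lag; it does not
  re-select the lag jointly, and tests one direction only (GMS → mobility).
* Confidence-weighted sentiment scores and covariance-transformed
  (Mahalanobis) coherence are deliberately out of scope; the plain
  statistics are the analysis's contract.
* The ADF specification (constant, no trend, AIC lags) is a documented
  default, not a discovered truth; both knobs are exposed.
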