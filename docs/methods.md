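# Methods

## The question and the model

`emosync` tests whether the emotional state of one city's residents predicts
the emotional state of another city's residents *more strongly when residents
of the two cities are in closer physical contact* — the signature that
emotional contagion operates through in-person channels rather than through
shared shocks alone.

The unit of analysis is a city × two-hour period. For an emotion or
sentiment measure `S`, the model is a lagged-dependent-variable panel
regression with time fixed effects:

    S_it = β1 S_i,t-1 + β2 MED_i,t-1 + β3 CONT_i,t-1
           + β4 MED_i,t-1 · CONT_i,t-1 + Δ_t + ε_it

* `S_it` — mean user-standardized measure over all tweets by city *i*'s
  residents in period *t* ("ambient" emotion);
* `MED_i,t-1` — mean degree-weighted emotion: the contact-weighted average
  of the other six cities' ambient measures at *t−1*;
* `CONT_i,t-1` — city *i*'s total contact with all other cities at *t−1*,
  z-scored over the estimation sample;
* `Δ_t` — one fixed-effect level per two-hour period of the sample
  (emotion × period levels in the pooled long form), absorbing region-wide
  shocks;
* `β4` — the focal interaction. A positive β4 means inter-city synchrony
  strengthens with contact. β2 captures contact-independent synchrony, and
  β1 within-city persistence.

Because common shocks are absorbed by Δ_t and routine diurnal patterns can
be absorbed by city × hour-of-day effects (robustness specification), β4 is
identified by whether *deviations* of a city's emotion co-move with its
neighbors' deviations more in high-contact periods. This is a predictive,
not a causal, quantity: shared-exposure and homophily stories can produce
the same pattern, which is why the package's validation is built around
synthetic data with a *known* β4.

## Measurement pipeline

**Scoring.** Tweets are tokenized (URLs and @-mentions dropped, `#` stripped
with the hashtag word kept, lowercased, split on non-alphanumerics; no
stemming or negation handling). Sentiment is the sum of matched valence
weights from a pluggable TSV lexicon (a mean-of-matches variant exists
behind a flag). Each of the ten emotion categories (anger, anticipation,
disgust, fear, joy, sadness, surprise, trust, negative, positive) is counted
as the number of matching words and dichotomized to a presence flag; the
flag, not the count, is the measure carried forward. Widely used emotion
lexicons cannot be redistributed, so lexicons are external files; a toy
lexicon ships for tests.

**User standardization.** Each measure is z-scored within user (sample sd,
n−1) before any aggregation, so composition effects — who happens to tweet
in a given period — cannot masquerade as city-level dynamics. Users with
fewer than two tweets or zero variance contribute z = 0 rather than missing
values, keeping cell means defined. The dichotomous flags are standardized
*as* 0/1 indicators, i.e. dichotomization happens before standardization.

**Panels.** Periods are `(day − 1)·12 + floor(hour/2)` in one configured
study timezone (default US Eastern; the study region spans one zone). Cells
need at least `min_tweets = 50` tweets to enter the analysis; the filter is
applied per (city, period) cell, since the measures are per city. A
config switch is not provided for the across-city interpretation; the
retained-cell counts are reported so users can audit the filter.

**Contact.** For POI *m* with visitor home-city shares `p_im`, hour-of-day
monthly totals `V_km`, and day shares `P_lm`, the contact between cities
*i ≠ j* on day *l*, hour *k* is `p_im · p_jm · V_km · P_lm`, summed over
POIs and then over adjacent hour pairs to the two-hour grid. The formula is
applied literally — `V` in visitor units, `P` as a day share — and the
implied monthly volume per POI is written to a validation report rather
than second-guessed. The hour index is hour-of-day (24 values), matching
how monthly POI files publish hourly aggregates. Self-contact is excluded;
an out-of-region visitor remainder (`Σ_i p_im < 1`) is allowed and simply
scales contact down.

**Exposure.** MED is a *normalized* weighted mean (divide by the summed
weights): on the measures' z scale a weighted sum would be orders of
magnitude off the observed dispersion of the exposure variable. Weights are
the contact levels at t−1, the same period as the values being averaged. If
every partner weight is zero the unweighted mean of retained partners is
used and flagged; if no partner is retained the cell is missing. Missing
partner cells are dropped from the average, not imputed. A row enters
estimation only when the city's own t and t−1 cells are both retained.
`CONT` is standardized globally (not within city); tweet volume is
log-count, centered and scaled within city.

## Estimation

Fixed effects are absorbed by group demeaning; crossed schemes (e.g. period
plus city × hour-of-day in the robustness model) use alternating projections
iterated to a 1e−10 sup-norm tolerance. Slopes are therefore identical to
the explicit dummy-variable regression, which the test suite verifies to
1e−8 on random panels for every scheme. The absorbed parameter count uses
the exact two-factor rank formula `L1 + L2 − (connected components)`;
observations isolated in their cells are absorbed to zero and carry no slope
information.

Standard errors are classical by default (the residual degrees of freedom
subtract the absorbed levels), with city-clustered errors available — with
seven clusters these are indicative at best, which is why they are not the
default. Reported fit statistics: Gaussian log-likelihood, AIC = 2k − 2lnL
and BIC = k·ln n − 2lnL with k counting slopes, absorbed levels, and the
error variance; pseudo-R² is the squared correlation between fitted values
(fixed effects included) and the observed DV — the definition is stated in
every summary because other conventions exist.

The five-model battery per measure set: (1) lag + MED; (2) lag +
interaction; (3) lag + MED + CONT + interaction (preferred); (4) model 3
plus city × hour-of-day(-emotion) effects, keeping the base period effects;
(5) model 3 plus tweet volume and tweet volume × MED. Pooled batteries run
on long-form stacks of per-emotion tables (all ten; positive = joy, trust,
positive; negative = anger, disgust, sadness, negative; tense =
anticipation, fear, surprise) with emotion × period effects.

## The synthetic data-generating process

Real inputs of both kinds are restricted, so validation uses a generator
that mirrors the analysis assumptions and plants a known β4.

* **Mobility**: 60 POIs; home shares Dirichlet(concentration 5 on the POI's
  own city, 1 elsewhere) scaled by a 10% out-of-region share; lognormal
  monthly volumes over a mid-afternoon-peaked 24-hour profile; near-uniform
  Dirichlet day shares. These choices produce contact series with realistic
  diurnal structure and enough cross-city weight heterogeneity for MED to
  differ across cities.
* **Latent emotion**: the model equation run forward per measure with
  β1 = 0.3, β2 = 0.1, β3 = 0, β4 planted (default 0.5), period-shock sd
  0.05, innovation sd 0.8; a 24-period burn-in is discarded. Contagion
  effects observed in the field are small and short-lived, so the planted
  values are illustrative magnitudes chosen for testability, not empirical
  calibration. Stability is guarded at runtime (the recursion errors out if
  it diverges; |β1| ≥ 1 is rejected outright).
* **Tweets**: 150 users per city; per-user lognormal activity multipliers
  (sd 0.5) on a base rate of 0.6 tweets per user per two-hour period with a
  ±30% diurnal profile. The rate is set so that city-period cells clear the
  50-tweet retention filter at the simulated user base — the real corpus
  has an order of magnitude more users tweeting less often; what matters
  for the pipeline is the per-cell tweet count. Each tweet contains one
  graded valence word equal to the latent sentiment plus a per-user offset
  (sd 0.3) and noise (sd 0.5), quantized to a 0.25-step lexicon ladder;
  each emotion word appears with probability clamp(0.2 + offset_u +
  0.3 · latent, 0.01, 0.99); filler words, occasional mentions and URLs
  exercise the tokenizer. Emotion is driven by the *city-period* latent
  state only — user heterogeneity enters through base rates and offsets,
  which user standardization must remove (itself a tested property).

What the generator does **not** emulate: real text (bags of signature words
only), network homophily, within-POI agent dynamics, retweet cascades, bot
traffic, or differential-privacy noise in mobility data. Passing recovery
tests therefore show that the *pipeline and estimator* are sound under the
model's own assumptions; they say nothing about whether real tweets measure
real emotion.

## Monte-Carlo design and problem sizes

Calibration and recovery run the full text-level pipeline per replicate.
The experiments keep the full cross-sectional structure (7 cities × 150
users) and shorten the panel to 10 days (120 periods): the null rejection
rate is a size property and is invariant to panel length, and the recovery
bias at 120 periods is already well inside Monte-Carlo error. At these
sizes one replicate is ≈ 0.5 s, so 500-replicate calibration completes in a
few minutes.

Measured behaviour at these conditions: under β4 = 0 the nominal-5% test
for β̂4 rejects at ≈ 0.05–0.06 with reported SEs matching the sampling
spread; under β4 = 0.5 the mean estimate is within two Monte-Carlo SEs of
0.5 with power ≈ 0.95. A small attenuation of β̂4 is expected in principle
(MED is measured with sampling noise from finite cell sizes — an
errors-in-variables effect); at the default emission noise the observed
shortfall is of the order 0.01–0.03 (2–6% of the planted value), comparable
to Monte-Carlo resolution at the replication counts used. Users who crank
`valence_noise_sd` up or
`tweet_rate` down should expect visible attenuation of β̂4 — that is a
property of the estimator under measurement error, not a bug.

## Numerical conventions and degenerate inputs

* sd everywhere uses the n−1 denominator; z-scores of degenerate users (or
  zero-variance covariate columns) are set to 0 with a warning, never NaN.
* Alternating-projection demeaning: tolerance 1e−10 sup-norm, hard iteration
  cap with an error naming the iteration count.
* Collinearity after absorption raises an error naming the offending
  regressor (detected by rank-restoring column deletion).
* Exact fits (zero residual variance) report SE 0 and a clamped, finite
  log-likelihood.
* Empty tweet tables produce an empty panel with a warning; an empty POI
  collection is a hard error before any downstream stage runs.
* All randomness flows through one `numpy` Generator per run; a fixed seed
  reproduces every artifact byte for byte.

## Known limitations

* Classical SEs ignore spatial correlation of residuals across cities
  within a period; with seven cities cluster-robust inference is fragile,
  and no spatial HAC correction is offered.
* The ≥50-tweet filter interacts with the diurnal tweeting profile: at low
  rates, night periods drop out first and the panel develops systematic
  gaps (handled correctly by the lag logic, but reducing n).
* The literal contact formula can double-count monthly volume if a
  patterns file's hourly totals are not month-level aggregates; the
  validation report surfaces the implied volume but the package does not
  rescale.
* Lexicon-based measurement is shallow by construction: no negation,
  sarcasm, emoji, or multilingual handling.
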