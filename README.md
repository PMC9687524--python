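# emosync

Tools for asking whether the emotions of one city's residents track the
emotions of neighboring cities' residents *more strongly when the two
populations are in closer physical contact* — the observable footprint of
in-person emotional contagion at metropolitan scale.

The package is aimed at computational social scientists working with
geocoded short-text corpora (tweet-like records) and aggregated POI
mobility data (SafeGraph-Patterns-style visitation marginals). Because both
input kinds are typically restricted, the package ships a first-class
synthetic data generator with a *planted* contagion coefficient, so every
stage — scoring, aggregation, contact estimation, regression — is testable
end to end without access to the original data.

## The model

For an emotion/sentiment measure S observed per city *i* and two-hour
period *t*:

    S_it = β1 S_it−1 + β2 MED_it−1 + β3 CONT_it−1
           + β4 MED_it−1 · CONT_it−1 + Δ_t + ε_it

* **S_it** — "ambient" emotion: the mean of *user-standardized* per-tweet
  measures (continuous sentiment, or a 0/1 emotion-presence flag) over all
  tweets by city *i*'s residents in period *t*, for cells with ≥ 50 tweets.
* **MED** (mean degree-weighted emotion) — the contact-weighted average of
  the other cities' ambient measures.
* **CONT** — the city's total contact with all other cities, estimated per
  POI *m*, hour *k*, day *l* as `p_im · p_jm · V_km · P_lm` from visitor
  home-origin shares, monthly hour-of-day totals, and day shares, summed
  over POIs and aggregated to two-hour bins; z-scored.
* **Δ_t** — period fixed effects (emotion × period in pooled models),
  absorbed by iterative demeaning.

**β4 is the focal quantity**: positive β4 means inter-city emotional
synchrony is conditional on contact. The package fits five-model batteries
(lag-only through volume-controlled robustness specifications) for general
sentiment, all ten emotion categories pooled, and the positive / negative /
tense emotion groupings.

## Worked example

Simulate a corpus with a planted interaction of 0.5 (7 cities, 150 users
per city, 10 days), run the complete pipeline, and fit the preferred
specification:

```python
from emosync import SynthConfig
from emosync.synthetic_data import single_pipeline_run

cfg = SynthConfig(days=10)           # beta4 defaults to 0.5
fit = single_pipeline_run(cfg, seed=7)
print(fit.summary_frame().round(4))
```

```
            estimate      se       t       p stars
term
S_lag         0.3369  0.0949  3.5483  0.0004   ***
MED_lag       0.5274  0.4953  1.0648  0.2873
CONT_lag     -0.0904  0.1206 -0.7497  0.4537
MED_x_CONT    0.4919  0.1487  3.3084  0.0010   ***
```

The `MED_x_CONT` row is β̂4: this realization estimates 0.49 against the
planted 0.5, and the lag estimate 0.34 sits near the planted β1 = 0.3. The
fit carries `n_obs = 812` city-periods (a few night cells drop below the
50-tweet filter), 119 absorbed period effects, and a pseudo-R² of 0.29.

The same stages are scriptable from the shell:

```
emosync simulate --seed 5 --days 10 --out-dir data/
emosync run-all --config config.yaml      # score→panel→contact→assemble→fit
emosync recover --planted 0,0.5 --reps 50 --out recovery.csv
```

`run-all` writes the ambient panel, the contact series, per-measure
estimation tables, the long-form stacks, tidy coefficient tables with
significance stars, JSON fit summaries (n, k, log-likelihood, AIC, BIC,
pseudo-R²), and a manifest of row counts.

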