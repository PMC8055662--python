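# oge — online geolocalized emotion analysis

`oge` analyses the *online geolocalized emotion* (OGE) of cities during a
crisis: daily sentiment statistics computed from sentiment-labelled,
geotagged social-media posts, and their statistical coupling to policy
events, human mobility and epidemic indicators.  It is aimed at
computational social scientists and epidemiological modellers who have a
feed of per-post sentiment labels (positive / neutral / negative / mixed)
with city assignments and want a tested, reproducible pipeline from raw
records to intervention and causality tables.

## The statistics

**Geolocalized mean sentiment (GMS).** For city *C*, day *t* and topic
*topic* (keyword-matched subtopics plus "overall"), with P positive, M
neutral-or-mixed and N negative posts, T = P + M + N:

    G_C(t) = (P − N) / T  ∈ [−1, 1]

**GMS coherence.** Each city's five subtopic GMS values form a vector in
R⁵; the coherence φ(t) is the average pairwise angle (degrees, via cosine
similarity) between all usable city vectors on day t.  Low φ means cities'
topic-sentiment profiles point the same way.

**Stationarization.** Before any pairwise analysis, both series are
ADF-tested and jointly first-differenced until each rejects the unit-root
null at 0.05 (at most 3 differences; epidemic series are first truncated at
their first nonzero count).

**Policy intervention (ARMAX).** The stationarized GMS series is modelled
as

    G_t = Σᵢ αᵢ G_{t−i} − Σᵢ γᵢ ε_{t−i} + Σₖ βₖ z_{kt} + ε_t

where z_{kt} are binary policy indicators — one-day impulses for three
federal announcements and a step over the local shelter-in-place interval.
(p, q) is selected by BIC over a grid (default [0,7]²) and each policy's
standardized effect size Z_k = β̂_k / σ̂(β̂_k) is judged against the standard
normal at the 0.05 level.

**Association.** Pearson correlations between differenced series (city
pairs; GMS vs mobility/epidemic indicators), and two-step Granger
causality: the BIC-optimal univariate AR lag p of the mobility series is
reused in

    M_t = Σᵢ αᵢ M_{t−i} + Σᵢ ωᵢ G_{t−i} + ε_t

and ω₁ = … = ω_p = 0 is tested with a chi-squared (Wald) statistic.

A synthetic-data module generates city panels with known ground truth
(latent AR sentiment with injectable policy effects, lag-coupled mobility,
logistic epidemic curves) in the exact file dialects the readers consume,
so the whole pipeline is testable without any download.

## Worked example

```python
import datetime as dt
from oge import synthetic as sy, ingest, measures, stationarity, intervention

spec = sy.ScenarioSpec(
    n_cities=3, start=dt.date(2020, 2, 26), end=dt.date(2020, 4, 15),
    volume_mean=60,
    policy_effects=(sy.PolicyEffectSpec(k=1, effect=-0.8),),  # national emergency
)
posts, events = sy.generate_policy_scenario(spec, seed=7)
posts, kept = ingest.filter_cities(posts, (spec.start, spec.end), min_daily_avg=10)
table = measures.gms_table(ingest.daily_topic_counts(posts))

y = measures.gms_series(table, "city_00", "overall").dropna()
y_st, order = stationarity.difference_to_stationary(y)      # order -> 0
z = intervention.build_policy_indicators(events, "city_00", y_st.index)
model = intervention.scan_armax(y_st, z, p_max=2, q_max=2)
print(model.p_, model.q_, dict(model.zscores_.round(2)))
```

prints

```
0 0 {'national_emergency': -4.06, 'distancing_extension': -1.66}
```

i.e. the BIC scan selects a white-noise ARMA core, the injected −0.8 latent
impulse on the national-emergency date is recovered as a significantly
negative effect (Z = −4.06 < −1.96), and the inert extension announcement is
not significant.  (The reopening-guidelines indicator falls outside this
shortened window and is dropped as an all-zero column.)

The same analysis runs from the shell on a YAML config:

```sh
oge all --config run.yaml --seed 7 --outdir results/
```

writing `gms.csv`, `coherence.csv`, `effects.csv`, `pairwise_corr.csv`,
`offline_corr.csv`, `granger.csv` and a run manifest; identical config and
seed give byte-identical numeric outputs.

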