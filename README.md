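# scatdiet

Scat DNA metabarcoding is the workhorse for studying the diet of elusive
carnivores: prey DNA amplified from faeces with universal primers reveals
what was eaten without observing a single kill. But a detection is not a
consumption record — whether prey DNA shows up in a scat subsample
depends on how long before defecation the prey was eaten, what fraction
of the daily ration it made up, how long the scat weathered outdoors
before sampling, the prey species, and the individual animal. `scatdiet`
is a tested pipeline for quantifying exactly those effects from captive
feeding trials, so that field studies can correct for them.

It takes a feeding schedule and taxon-assigned amplicon read tables (plus
negative controls), reduces them to presence/absence calls, and fits a
hierarchical Bayesian Bernoulli-logit detection model

    Y[s,i,j] ~ Bernoulli(p[s,i,j])
    logit p = β0_s + β1_s·pr0 + β2_s·pr1 + β3_s·pr2 + β4_s·pr3
              + β5·degradation_day + β6·individual + α_i

where `pr0..pr3` are the proportions of prey *s* fed on the defecation
day and the three preceding days, `α_i` is a per-scat random intercept,
and the species-indexed coefficient families are pooled hierarchically
(β_k[s] ~ N(μ_k, σ_k²), μ_k ~ N(0, 100), σ_k ~ U(0, 10)). Inference uses
an in-package adaptive Metropolis-within-Gibbs sampler validated against
deterministic grid integration, with Gelman–Rubin convergence
diagnostics. Posterior products include species-level detection-vs-lag
curves, the meal proportion required for a target detection probability,
and gut-transit bounds from a spike feeding. A synthetic-data module
generates schedules, detections and contaminated read tables with known
truth, so every stage is testable end to end. See `docs/methods.md` for
the full model description and design choices.

## Worked example

Simulate a feeding trial at a realistic scale (two individuals, five prey
species, 26 scats each subsampled at nine degradation days from 0 to 60),
fit the model, and inspect the headline posterior:

```python
import pandas as pd
import scatdiet as sd

species = ["sp1", "sp2", "sp3", "sp4", "sp5"]
schedule = sd.generate_feeding_schedule(20, ["A", "B"], species, seed=1)
params = sd.example_true_parameters(species, seed=2)
scat_days = [pd.Timestamp("2017-11-03") + pd.Timedelta(days=d) for d in range(3, 16)]
detections = sd.simulate_detections(schedule, params, scat_days,
                                    degradation_days=[0, 3, 5, 12, 15, 20, 27, 48, 60],
                                    seed=3)
model_input = sd.build_model_input(detections, schedule)
draws = sd.run_mcmc(model_input, n_chains=3, n_iter=4000, n_burnin=1000, seed=4)
print(f"max Rhat: {sd.gelman_rubin(draws).max_rhat:.3f}")
print(sd.headline_summary(draws).round(2))
```

```
max Rhat: 1.041
              mean    sd  ci2.5  ci97.5
Day 0/pr fed  0.27  0.60  -0.86    1.40
Day 1/pr fed  4.54  1.35   1.73    7.31
Day 2/pr fed  1.75  0.80   0.22    3.39
Day 3/pr fed  0.30  0.97  -1.70    2.20
Degradation  -0.17  0.02  -0.20   -0.14
Cheetah      -0.74  0.58  -1.89    0.39
```

The rows are the species-averaged effects of meal proportion at feeding
lags 0–3 (logit scale), the per-day degradation slope, and the individual
contrast. The fit recovers the generating values (4.43, 1.82, … ;
degradation −0.16): detection is driven mostly by what was eaten *one
day* before defecation and decays slowly as the scat ages. Derived
quantities follow the same pattern:

```python
curve = sd.species_detection_vs_day(draws, "sp1", proportion=0.5)
print(curve.to_frame().round(3))
need = sd.proportion_for_target_probability(draws, species=None, lag_day=1, target_p=0.5)
print(f"{need['median']:.2f} of the daily ration = {need['grams_median']:.0f} g")
```

```
   feeding_lag   mean     sd   q2.5    q25    q50    q75  q97.5
0          0.0  0.345  0.241  0.025  0.143  0.294  0.511  0.872
1          1.0  0.790  0.196  0.264  0.700  0.853  0.939  0.991
2          2.0  0.535  0.259  0.069  0.322  0.549  0.756  0.953
3          3.0  0.309  0.237  0.017  0.113  0.246  0.464  0.856
0.29 of the daily ration = 512 g
```

— a half-ration meal of `sp1` is most detectable in scats deposited the
next day (posterior mean 0.79), and a prey item needs roughly 30% of the
daily ration (here ~500 g) for even odds of detection at that lag.

The same stages are scriptable from the shell via the `scatdiet` CLI
(`simulate`, `filter`, `build`, `fit`, `summarize`, `curves`, or `all`
with a YAML/JSON config); every stage writes a run manifest with its seed
so artifacts reproduce byte for byte. The feeding schedule of the captive
cheetah trial the model was designed around ships with the package
(`sd.load_study_schedule()`), both verbatim and with a documented
correction of three typo'd proportions.

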