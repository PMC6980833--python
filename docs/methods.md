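# Methods

## The problem

Scat DNA metabarcoding infers a carnivore's diet from prey DNA amplified
out of faeces. Detection of a prey species in a scat subsample is not a
clean readout of consumption: it depends on how long before defecation the
prey was eaten, how large the meal was, how long the scat weathered
outdoors before subsampling, which prey species it was, and which
individual produced the scat. `scatdiet` implements the full inferential
chain for a captive feeding trial of this kind — two cheetahs fed six prey
species in known daily proportions, scats subsampled fresh and repeatedly
as they degraded outdoors — from taxon-assigned read tables to posterior
detection curves.

## Presence/absence calling

Amplicon sequencing depth varies enormously between subsamples, so read
counts are reduced to binary presence/absence before modelling. The rules,
in pipeline order:

1. **Abundance/length filter** — drop rows with fewer than 10 reads or
   sequences shorter than 80 bp (likely sequencing error or chimaeras).
   Boundary behaviour is pinned by tests: exactly 10 reads / exactly 80 bp
   are *kept*, consistent with reading "below 10" as a strict inequality.
2. **Taxonomic reassignment** — family-level assignments are collapsed
   onto the known species (Felidae → *Acinonyx jubatus*, Leporidae →
   *Oryctolagus cuniculus*, Equidae → *Equus caballus*, Cervidae →
   *Cervus* spp); rows from non-target taxa are dropped and tallied. Read
   totals are conserved up to the reported drops.
3. **Control-aware presence call** — a prey species is present in a
   subsample iff it has ≥1 read there and its matched negative control
   carries fewer than 10 reads of it; an absent control row counts as
   zero. Controls may be per-library or per-batch; the control mapping is
   a column, defaulting to batch controls as produced by the simulator.
   The consumer is tracked through filtering (for read-share reporting)
   but never emitted as a prey row.
4. **Burn-in exclusion** — scats deposited in an individual's first three
   trial days have unknown prior diet and are excluded, as are species
   fed only within that window (in the study, turkey).

## The detection model

For species *s* in a subsample of scat *i* taken at degradation day *j*:

    Y[s,i,j] ~ Bernoulli(p[s,i,j])
    logit p  = β0_s + β1_s·pr0 + β2_s·pr1 + β3_s·pr2 + β4_s·pr3
               + β5·degradation_day + β6·individual + α_i

where `pr0..pr3` are the proportions of species *s* in the individual's
daily ration on the defecation day and the three preceding days (0 when
not fed), `degradation_day` is on its raw day scale (0–60), `individual`
is a 0/1 indicator over the two animals in sorted label order, and `α_i`
is a per-scat random intercept absorbing repeated subsampling of the same
scat.

The lag window is fixed at 3 days, matching the observed gut-transit
ceiling (a single spike feeding was last detected 72 h later). Lag 0 uses
the feeding on the same calendar date as deposition; overnight scats are
assigned to their collection date.

**Priors.** The species-indexed families β0..β4 are pooled
hierarchically: β_k[s] ~ N(μ_k, σ_k²), μ_k ~ N(0, 100),
σ_k ~ Uniform(0, 10); α_i ~ N(0, σ_α²) with σ_α ~ Uniform(0, 10). β5 and
β6 take N(0, 100) priors directly: each is a single scalar, and a
hierarchical pool needs at least two exchangeable units. The intercepts
β0_s are pooled like the slope families; "variance 100" is read literally
as variance (SD 10), not as a precision. The species-averaged lag effects
reported by `headline_summary` are the hyper-means μ1..μ4.

## Sampling

Inference is by adaptive Metropolis-within-Gibbs, written in-package and
validated against deterministic grid integration rather than against any
external sampler:

- every scalar gets a Gaussian random-walk proposal; step sizes are tuned
  every 50 iterations during burn-in toward a 30–45% acceptance rate and
  frozen afterwards;
- hyper-means μ_k are conjugate Gibbs draws;
- σ_k and σ_α are updated on the log scale with the Jacobian term, the
  proposal reflected below log 10;
- two *translation moves* propose shifting all β0_s against all α_i, and
  β6 against the α_i of the second individual's scats. These leave the
  linear predictor — hence the likelihood — unchanged, so they are
  accepted on the prior ratio alone. They exist because the likelihood
  only identifies the sums β0_s + α_i (and β6 + α over one individual's
  scats); single-site updates mix very slowly along these flat ridges,
  and without the moves the reduced-scale recovery fits did not converge
  within their iteration budget;
- chains start from overdispersed prior draws with per-chain seeds
  spawned from the user seed (SD priors truncated to (0.5, 10) at
  initialisation only, so species coefficients never start collapsed
  onto their hyper-mean); a non-finite initial posterior triggers a
  bounded number of re-draws.

Per-scalar updates recompute the likelihood only over the rows the
coefficient enters (a species' rows, a scat's rows), with the
y-dependent part reduced to a precomputed inner product and the softplus
term cached per row — one full-scale fit (3 × 20,000 iterations, ~2,000
rows) takes under a minute on one core.

Defaults mirror the study's analysis: 3 chains, 20,000 total iterations
with the first 5,000 as burn-in, no thinning. `n_iter` counts total
iterations per chain (so 15,000 draws are kept per chain by default).

**Diagnostics.** The Gelman–Rubin statistic is computed from the standard
between/within-chain variances, Rhat = sqrt(((n−1)/n·W + B/n)/W), with a
convergence threshold of 1.1; the degenerate all-chains-identical case is
floored at 1.0 with a warning; a split-chain mode halves each chain first.
Effective sample sizes come from arviz. The log likelihood accumulates
per-row terms with exact (fsum) summation so it is bit-for-bit invariant
to row permutations, and uses `logaddexp` so linear predictors beyond
±700 stay finite.

## Derived quantities

- **Detection vs feeding lag** (per species or species-averaged via the
  hyper-means): per posterior draw, invert the logit at the chosen meal
  proportion; the scat effect is marginalised by drawing a fresh
  α ~ N(0, σ_α) per draw with a documented seed. Default conditioning is
  a fresh scat (degradation 0) and the reference individual.
- **Proportion for a target detection probability**: the logistic is
  inverted per draw, `(logit(p*) − other terms)/slope`, at α = 0; draws
  with |slope| below tolerance are excluded and counted, and solutions
  outside [0, 1] are reported as tallies rather than clipped silently. A
  grams equivalent uses a configurable daily intake (default 1750 g, the
  mean of the two study animals' 1700/1800 g rations).
- **Spike-diet window**: for a prey fed exactly once, the maximum
  gut-transit time is the latest fresh-scat detection (day resolution ×
  24 h); the minimum is an interval because the first post-spike scat is
  deposited overnight — a first detection k days after a morning feeding
  brackets minimum passage as ((k−1)·24+8, k·24−2) h, i.e. (8, 22) h for
  a next-day detection.

## Synthetic data

The generator is the package's test bed and defines the conditions under
which every downstream stage is verified:

- **Schedules**: each individual's daily ration is split among 1–3 of the
  species with flat-Dirichlet proportions (the trial's published schedule
  gives no generative recipe; Dirichlet(1,…,1) is the maximally
  uninformative choice on the simplex). The real trial's schedule is also
  bundled, both verbatim and with a documented typo correction
  (three printed "0.6" values that break the unit-sum constraint read as
  "0.06", after which every daily ration sums to exactly 1).
- **Detections** are drawn from the model above with known coefficients;
  the generating probability is stored next to each Bernoulli draw, since
  real data has no ground truth to recover. The documented generating
  coefficients centre the lag effects at (0.01, 4.43, 1.82, 1.04) across
  lags 0–3 with between-species SD 1, degradation slope −0.16/day,
  individual contrast −1.19, and scat-effect SD 1 — a weak same-day
  signal peaking one day post-feeding and decaying thereafter, matching
  the magnitudes this kind of trial reports. The intercept hyper-mean is
  −1.0 (modest fresh-scat detectability).
- **Read tables**: per subsample, total reads are Poisson (default mean
  10,000) split multinomially — the consumer taxon at 54% (the dominance
  observed in real scat libraries), detected prey sharing the remainder
  equally, undetected prey at zero. Negative controls are per batch of 10
  subsamples with Poisson per-taxon contamination. No per-species
  read-abundance model conditional on proportion eaten is published; the
  equal multinomial split is a stand-in, which is why presence/absence
  (not read counts) is the modelled quantity.

What the generator does *not* emulate: PCR/sequencing error producing
short or chimeric sequences (lengths are drawn directly, with an optional
short-read fraction purely to exercise the length filter), index
hopping, read-depth dependence on scat age, or correlated contamination.
Passing the round-trip and recovery tests therefore demonstrates the
pipeline's internal consistency under the model's own assumptions, not
robustness to those artefacts in field data.

## Verification scale

The sampler-validity check integrates a single-intercept reduction on a
deterministic grid and requires MCMC agreement within 3 Monte-Carlo
standard errors. Parameter recovery runs 20 independent replicates at the
study's data scale (26 scats, 5 species, 16 degradation days ≈ 2,080
rows) with reduced chains (3 × 4,000, 1,000 burn-in), requiring ≥90%
coverage of generating coefficients by nominal 95% intervals and
Rhat < 1.1 in every fit; the acceptance script runs one fit at the full
3 × 20,000 setting. These sizes keep the whole suite to a few minutes on
one core while leaving the binomial tolerance on the coverage check
(540 checks) tight enough to be informative.

## Known limitations

- The individual covariate supports exactly two animals (a single 0/1
  contrast), as in the trial design.
- `reassign_taxa` matches taxon labels exactly; there is no
  lowest-common-ancestor logic, because input is already taxon-assigned.
- The multinomial read split ignores meal size, so read *counts* from the
  simulator carry no dose information beyond presence.
- With only 5 species informing each σ_k, the hyper-SD posteriors are
  heavy-tailed; they mix adequately but their summaries are
  prior-sensitive, which is inherent to the design, not the sampler.
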