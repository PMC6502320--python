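# Methods

## Problem and data model

Two surveillance systems each record an incomplete list of the persons in a
closed population who have a condition. Source A is an
insurance/administrative channel, source B a clinical one. After exact
linkage on a shared person key, each observed person falls into one of
three capture-history cells — both lists, A only, B only — and the
never-observed cell is unknown. All estimators in this package infer the
size of that fourth cell.

Assumptions inherited from classical two-list capture–recapture: the
population is closed over the study window, linkage is error-free, capture
by one source is independent of capture by the other, and catchability is
homogeneous — either globally (pooled estimators) or within demographic
strata (stratified and Bayesian estimators). Violations matter
directionally: positive source dependence inflates the overlap and biases
the estimate downward; catchability heterogeneity ignored by pooling
typically does the same.

## Linkage and stratification (`registry`)

- Deduplication keeps the first record per person and source; a later
  duplicate disagreeing on gender or by more than one year of age is logged
  (strict mode raises), since it suggests a key collision. One year of age
  discrepancy is tolerated: age is age at first capture and a window can
  straddle a birthday.
- Cross-source demographic conflicts are resolved in favour of source A by
  default (administrative civil-status fields are verified at
  registration); configurable via `prefer_source`.
- Age classes default to ≤84, 85–89, ≥90. The source analysis wrote the
  classes with ages 84 and 90 unassigned; the contiguous partition keeping
  the interior 85–89 class intact is used. Records with missing
  demographics are excluded from stratified tables with a logged count
  (strict mode raises).

## Closed-form estimators (`estimators`)

Lincoln–Petersen and Chapman with the variance formulas given in the
README; 95% intervals are Wald (`N̂ ± 1.96·SE`), matching how such results
are conventionally printed, with no log transform. Point estimates,
interval bounds and the `1.96·SE` half-width are rounded half-up to
integers; full-precision values are retained internally and used for
downstream rates. The stratified estimator sums per-stratum estimates and
variances, assuming independence between strata and no finite-population
correction; a stratum with zero overlap falls back to Chapman (which stays
finite) and is logged.

## Bayesian M_t model (`bayes`)

Per stratum *s*, data augmentation with a super-population of `M_s`
potential individuals:

    z_i ~ Bernoulli(ψ_s),  y_iA ~ Bernoulli(z_i p_sA),  y_iB ~ Bernoulli(z_i p_sB)
    N_s = Σ_i z_i,  N_total = Σ_s N_s
    priors: p_sA, p_sB ~ Beta(1,1),  ψ_s ~ Uniform(0,1)

Covariates enter as full stratification (3 age classes × 2 genders by
default) rather than a regression on the capture probabilities: this keeps
every update conjugate and matches the "each stratum has its own capture
probabilities per source" structure. Flat priors are chosen deliberately:
mixing `Binomial(M_s, ψ_s)` over a uniform `ψ_s` makes the induced prior on
`N_s` uniform on `{0..M_s}`, so the posterior mode tracks the maximum
likelihood solution and, for a single stratum, the posterior median sits at
the Lincoln–Petersen estimate (the tests assert agreement within 1.5% on
tables of realistic size).

Sampler: captured persons have `z_i = 1` deterministically. The
never-captured augmented individuals are exchangeable given
`(ψ, p_A, p_B)`, so their indicator sum is updated in one
`Binomial(M_s − union_s, ψq/(ψq+1−ψ))` draw with `q = (1−p_A)(1−p_B)` —
algebraically identical to per-individual Bernoulli full conditionals,
orders of magnitude faster. `p`'s and `ψ` get conjugate Beta updates.
Strata are conditionally independent and are updated vectorised within
each sweep.

Numerical/operational choices:

- Defaults: 2 chains, 5,000 burn-in, 25,000 retained draws, thin 1. Chains
  start over-dispersed (5% vs 95% initial latent inclusion) and are seeded
  via `numpy.random.SeedSequence` spawning from one master seed, so runs
  are exactly reproducible and chains independent.
- `M_s` defaults to 10× the observed stratum union. A fit aborts if more
  than 1% of posterior mass for any `N_s` lies at or above `0.95·M_s`
  (augmentation exhausted — the error names the stratum and asks for a
  larger `M_s`). The posterior median is invariant to doubling `M_s`
  within Monte-Carlo error (tested at ±1%).
- HPDI: shortest window of `ceil(prob·n)` sorted pooled draws; ties take
  the lowest lower bound. This differs slightly from arviz's `hdi`
  (floor-based); arviz is used as an independent cross-check, not as the
  implementation.
- Convergence: classic Gelman–Rubin potential scale reduction
  (non-split, between/within variances) per parameter; `r̂ > 1.1` flags the
  fit non-converged (strict mode raises). Constant chains return `r̂ = nan`
  as a degenerate flag and do not count against convergence. Effective
  sample size comes from arviz. Strata with no observed case are dropped
  from the model (nothing identifies them) with a log note.

## Rates (`rates`)

Completeness `100·n_source/N̂` and prevalence `100·N̂/population`, rounded
half-up to one decimal; the unrounded estimate is used when available
(indistinguishable at one decimal from using printed integers).
`age_restricted_estimate` sums stratum estimates wholly above an age
cutoff and refuses a cutoff that splits a stratum — a 65+ analysis
therefore needs a stratification with a boundary at 65, or an externally
supplied 65+ estimate (the pipeline accepts one, since published 65+
numerators often derive from unpublished stratum data).

## Synthetic data (`simulate`)

The generator draws `true_N` persons into age classes (truncated-normal
ages within class bounds, default bounds [40, 110]), assigns gender by a
per-class female fraction, and draws each person's capture pattern from
`P(both) = pA·pB·(1+delta)`, `P(A only) = pA − P(both)`, etc. The
dependence parameter multiplies the joint-capture probability while
preserving both marginals, so dependence bias can be studied without
moving expected list sizes; `delta = 0` recovers exact independence and
infeasible `delta` raises with the feasible bound
`min(pA,pB)/(pA·pB) − 1`. Duplicates can be injected at a configurable
rate to exercise deduplication. Every person, captured or not, is recorded
in a `GroundTruth` object used as the oracle in recovery tests.

`paper_marginals_scenario()` ships a calibrated three-age-class scenario.
The latent population is **not identifiable** from captured-list summaries,
so its constants were fitted once by least squares on the expected-value
equations, under the qualitative mechanism that insurance capture rises
with age while clinic capture falls with it, with within-class age laws
fixed at realistic spreads and class shares bounded to plausible ranges.
The fit reproduces exactly: expected list sizes 3,824 / 2,594, expected
overlap 856, captured-list mean ages 86.1 (A) and 82.2 (B), source-A F/M
ratio 3.20 and source-B female share 71%. Captured-list age standard
deviations come out at 5.2 (A) and 6.7 (B) versus the reported 4.5 and
7.4 — the residual cost of keeping within-class age laws realistic; the
implied true population is 11,557. `fixed_paper_fixture()` is the
deterministic variant emitting *exactly* the published cell counts
(856/2,968/1,738) with demographics drawn from the calibrated cell-specific
distributions.

What the generator does **not** emulate: open populations (entry, death,
migration over the window), linkage errors, diagnostic misclassification,
within-stratum catchability heterogeneity, and the true joint
age×gender×source distribution (only marginals were ever published).
Passing recovery tests on this data therefore validates the estimation
machinery under the model's assumptions, not the assumptions themselves on
real surveillance data.

## Problem sizes in the test suite

Closed-form simulation checks use 200–500 replicates at N = 5,000–10,000
(multinomial cell draws, instant). Bayesian acceptance properties use the
full chain budget (2 × 5,000/25,000) on single-stratum published-scale
data, and 50 replicate fits at N = 1,000 with reduced chains
(2 × 2,500/10,000), exploiting the sampler's vectorisation across
independent strata. The whole suite runs in well under a minute.

## Known limitations

- Exact-key linkage only; probabilistic name-based linkage is out of
  scope, so real-world linkage error propagates unmodelled.
- Two sources only; no log-linear multi-list models or
  dependence-adjusted two-list estimators (dependence is simulated, not
  corrected for).
- The Chapman point estimate printed in the source analysis (11,595) is
  inconsistent with the standard formula, whose printed string appears to
  have lost its denominator; this package implements the standard formula
  (11,581 on the same counts) and matches the printed half-width (559).
- The published stratified (11,945) and covariate-model (15,060) totals
  depend on per-stratum counts that were never published and cannot be
  reproduced; the corresponding machinery is validated on synthetic data
  instead.
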