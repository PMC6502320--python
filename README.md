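# twolist

Two-source capture–recapture analysis for disease surveillance: estimate how
many cases of a condition exist in a region from two incomplete,
independently collected case lists, how complete each surveillance source
is, and what the prevalence rate is.

The motivating setting is Alzheimer's disease surveillance in a French
*département*, where an insurance-based cohort (copayment exemptions and
condition-specific drug claims) and a memory-clinic register each see only a
fraction of cases. The same machinery applies to any pair of case lists
that can be linked on a person key.

## The statistics

Let the linked lists form a 2×2 capture history with `m` persons on both
lists and list sizes `n1`, `n2`. Under closed population, independent
sources and homogeneous catchability:

- **Lincoln–Petersen**: `N̂ = n1·n2/m`, `Var = n1·n2(n1−m)(n2−m)/m³`
- **Chapman** (nearly unbiased): `N̂ = (n1+1)(n2+1)/(m+1) − 1`
- **Stratified**: sum of per-stratum estimates, absorbing between-stratum
  catchability differences (here: gender × age classes ≤84 / 85–89 / ≥90)
- **Bayesian M_t** with data augmentation: per stratum, a super-population
  of `M_s` potential individuals with latent inclusion `z_i ~ Bern(ψ_s)` and
  source-specific capture `y_ij ~ Bern(z_i·p_sj)`; flat priors; conjugate
  Gibbs sampling; the population size is the posterior of `Σ z_i`. Reported
  with mean, median and 95% highest-posterior-density interval, plus
  Gelman–Rubin r̂ across chains.

Completeness of a source is `100·n_source/N̂`; prevalence is `100·N̂/pop`
against a census denominator. A synthetic-data generator with full ground
truth (stratum-specific capture probabilities, marginal-preserving source
dependence `delta`) makes every stage testable without confidential data.

## Worked example

```python
from twolist import (fixed_paper_fixture, dedupe, link_sources,
                     lincoln_petersen, chapman, completeness)

a, b = fixed_paper_fixture(seed=0)       # two lists, published cell counts
t = link_sources(dedupe(a), dedupe(b))   # m=856, a_only=2968, b_only=1738
lp = lincoln_petersen(t)
print(t.union, lp.n_hat, lp.ci_low, lp.ci_high, chapman(t).n_hat,
      completeness(t.n1, lp.n_hat), completeness(t.n2, lp.n_hat))
```

prints

```
5562 11588 11028 12148 11581 33.0 22.4
```

5,562 cases were observed by at least one source, but the overlap pattern
implies about 11,588 exist — so the insurance list saw 33.0% of cases and
the clinic list 22.4%. `examples/` contains narrative scripts for each
capability (closed-form estimation, the Bayesian model, simulation with
dependence bias, the full pipeline); `twolist --help` exposes the same
stages as a command line (`simulate`, `link`, `estimate`, `bayes`,
`report`, `run-all`).

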