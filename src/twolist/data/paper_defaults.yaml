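# Default run configuration for the full pipeline: the published study's
# stratification (age classes <=84 / 85-89 / >=90 crossed with gender), MCMC
# settings (2 chains, 5,000 burn-in, 25,000 retained draws), and census
# denominators for the study area (all ages; 65 and over).
age_breaks: [85, 90]
use_gender: true
seed: 0
mcmc:
  n_chains: 2
  n_burn: 5000
  n_keep: 25000
  thin: 1
population: 1078729
population_65_plus: 234459
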