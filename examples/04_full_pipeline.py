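"""Run the whole pipeline - link, stratify, estimate, Bayes, rates - and
print the consolidated surveillance report."""

import json

from twolist import RunConfig, fixed_paper_fixture, run_pipeline
from twolist.bayes import McmcConfig

records_a, records_b = fixed_paper_fixture(seed=0)
config = RunConfig(
    seed=0,
    mcmc=McmcConfig(n_chains=2, n_burn=5_000, n_keep=25_000, seed=0),
    population=1_078_729,          # census denominator, all ages
    population_65_plus=234_459,    # census denominator, 65 and over
)
report = run_pipeline(config, records_a=records_a, records_b=records_b)

print(json.dumps({k: report[k] for k in ("counts", "completeness_pct",
                                         "prevalence_pct")}, indent=2))
print("LP estimate:", report["estimates"]["lincoln_petersen"]["n_hat"])
print("Bayes posterior mean:", report["bayes_mt"]["mean"])

# completeness_pct: share of the estimated case population each source saw;
# prevalence_pct: estimated cases per 100 residents of the study area.
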