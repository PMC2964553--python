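"""Type-I-error check for all seven matched tests under a stratified null.

Three sub-populations (risk-allele frequencies 0.1/0.3/0.5, prevalences
0.01/0.05/0.02), 150/150/200 cases with two matched controls each, no
genotype-disease association.  2,000 replicates keep the run short; the
Monte-Carlo standard error at a true size of 0.05 is then about 0.005.
"""

import matchtrend as mt

pop = mt.PopulationModel.null(p=(0.1, 0.3, 0.5), k=(0.01, 0.05, 0.02))
scenario = mt.SimulationScenario(pop, r=(150, 150, 200), m=2, n_reps=2000, alpha=0.05, seed=1)
res = mt.rejection_rate(scenario)

print(f"empirical size at alpha = {scenario.alpha} over {res.n_reps} replicates:")
for name, rate in res.rates.items():
    print(f"  {name:8s} {rate:.4f}  (MC se {res.mc_se[name]:.4f})")
print(
    "\nAll rates should sit within ~3 standard errors of 0.05: the matched\n"
    "tests keep their nominal level despite the strong confounding structure."
)
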