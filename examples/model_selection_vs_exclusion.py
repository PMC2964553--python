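"""Selecting vs excluding a genetic model with the stratified HWD contrast.

Under a true recessive model with small effect sizes, the probability of
*selecting* REC from the data is low, but the probability of correctly
*excluding* the opposite extreme (DOM) stays above 90% -- the rationale for
the exclusion-based SGME test.  300 cases, two matched controls each,
spread over three sub-populations.
"""

import matchtrend as mt

print("true model REC; baseline penetrances f0 = (0.01, 0.05, 0.02)")
print(f"{'GRR2':>5} {'P(select REC)':>14} {'P(exclude DOM)':>15}")
for grr2 in (1.1, 1.3, 1.5, 2.0):
    pop = mt.PopulationModel.from_baseline_penetrance(
        p=(0.1, 0.3, 0.5), f0=(0.01, 0.05, 0.02), lambda2=grr2, x_model=0.0
    )
    sc = mt.SimulationScenario(pop, r=(90, 90, 120), m=2, n_reps=4000, seed=3)
    res = mt.selection_exclusion_probs(sc)
    print(f"{grr2:5.1f} {res.rates['selection']:14.3f} {res.rates['exclusion']:15.3f}")

print(
    "\nAt GRR2 = 1.1 the correct model is selected < 20% of the time, yet the\n"
    "wrong extreme is excluded > 97% of the time: with weak effects, excluding\n"
    "the most unlikely model is far more reliable than selecting the right one."
)
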