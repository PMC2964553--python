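"""Power of the robust tests when the genetic model is unknown.

For each true model (REC/ADD/DOM) the homozygote relative risk is first
calibrated so the model-optimal trend test has ~80% power; all tests are
then evaluated at that effect size.  The optimal trend test wins when its
model is true but collapses under the wrong model; the robust tests hold
~65-80% power everywhere.  Replicates are modest to keep the run short.
"""

import matchtrend as mt

OPTIMAL = {"REC": ("mtt0", 0.0), "ADD": ("mtt05", 0.5), "DOM": ("mtt1", 1.0)}
P, K = (0.1, 0.3, 0.5), (0.01, 0.05, 0.02)

print(f"{'model':5} {'GRR2':>6} " + " ".join(f"{t:>8}" for t in mt.MATCHED_TESTS))
for model, (opt, x) in OPTIMAL.items():
    pop = mt.PopulationModel.from_grr(P, K, 1.5, x_model=x)
    sc = mt.SimulationScenario(pop, r=(150, 150, 200), m=2, n_reps=1500, seed=4)
    lam2, _, _ = mt.calibrate_grr(sc, opt, target_power=0.80, tol=0.015)
    pop2 = mt.PopulationModel.from_grr(P, K, lam2, x_model=x)
    res = mt.rejection_rate(
        mt.SimulationScenario(pop2, r=(150, 150, 200), m=2, n_reps=2000, seed=5)
    )
    row = " ".join(f"{res.rates[t]:8.3f}" for t in mt.MATCHED_TESTS)
    print(f"{model:5} {lam2:6.3f} {row}")

print(
    "\nReading the table: each optimal trend test reaches ~0.80 on its own row\n"
    "but drops sharply off-model (mtt1 under REC, mtt0 under DOM).  The robust\n"
    "tests (sgms, sgme, max3, chi2df2) stay near 0.65-0.80 throughout; sgme\n"
    "leads under ADD, max3 under the extreme models."
)
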