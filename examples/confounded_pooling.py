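"""Why matching matters: the unmatched GMS test under hidden stratification.

Two sub-populations differ in allele frequency (0.2 vs 0.4) but have no
genotype-disease association.  Drawing cases mostly from one stratum and
controls mostly from the other, then pooling into a single 2x3 table,
produces a spurious association that the unmatched two-stage GMS test
rejects almost always -- while the same test keeps its size when the arms
are balanced.
"""

import matchtrend as mt

pop_one = mt.PopulationModel.null(p=(0.3,), k=(0.05,))
balanced = mt.SimulationScenario(pop_one, r=(250,), s=(250,), n_reps=2000, seed=2)
res = mt.rejection_rate(balanced, tests=("gms", "gme"))
print(f"single population, 250 vs 250:   GMS size = {res.rates['gms']:.4f}, GME size = {res.rates['gme']:.4f}")

pop_two = mt.PopulationModel.null(p=(0.2, 0.4), k=(0.03, 0.07))
for r1, r2, s1, s2 in [(300, 200, 200, 300), (375, 125, 125, 375)]:
    sc = mt.SimulationScenario(pop_two, r=(r1, r2), s=(s1, s2), n_reps=2000, seed=2)
    res = mt.rejection_rate(sc, tests=("gms", "gme"))
    print(
        f"pooled, cases {r1}/{r2} controls {s1}/{s2}: "
        f"GMS rate = {res.rates['gms']:.4f}, GME rate = {res.rates['gme']:.4f}"
    )
print(
    "\nThe first line is a genuine size (~0.05).  The others are false-positive\n"
    "rates produced purely by confounding, growing with the case/control\n"
    "imbalance across strata -- the motivation for the matched-design tests."
)
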