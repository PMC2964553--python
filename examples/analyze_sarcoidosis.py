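"""Analyze the bundled ACCESS sarcoidosis pair-matched study.

497 case-control pairs, matched on age, race and sex, genotyped at the
KM(1,3) immunoglobulin polymorphism; three strata (Caucasian, Female and
Male African-American).  The script runs the three model-specific matching
trend tests, the robust tests, and the two-stage model-selection/exclusion
tests, and prints what each number says about the marker.
"""

import matchtrend as mt

study = mt.load_access()
print(f"{study.n_cases} matched pairs, {len(study.strata)} strata: {', '.join(study.strata)}\n")

print("model-specific matching trend tests (two-sided p):")
for label, x in (("recessive", 0.0), ("additive", 0.5), ("dominant", 1.0)):
    z = mt.mtt(study, x).z
    print(f"  {label:9s} scores: z = {z:+.3f}  p = {mt.mtt_pvalue(z):.3f}")
print("-> significance depends on the assumed genetic model; a robust test is needed.\n")

chi2 = mt.chi2_2df(study)
max3 = mt.max3(study)
print(f"chi-square (2 df) conditional score test: stat = {chi2.statistic:.3f}, p = {chi2.p_value:.3f}")
print(f"MAX3 (max of |trend tests|):              stat = {max3.statistic:.3f}, p = {max3.p_value:.3f}\n")

z_smrt = mt.smrt(study)
decision = mt.classify_model(z_smrt)
print(f"stratified model reduction test: Z_SMRT = {z_smrt:.3f} -> {decision.label} branch")
print(f"  (|Z_SMRT| <= {decision.threshold:.3f}: both extreme models are excluded)\n")

sgms = mt.sgms(study)
sgme = mt.sgme(study)
rho_star = mt.estimate_correlations(study).rho_star("ADD")
print(f"two-stage selection test (SGMS): p = {sgms.p_value:.4f}")
print(f"two-stage exclusion test (SGME): p = {sgme.p_value:.4f}")
print(f"minimum correlation of the optimal tests rho* = {rho_star:.3f}")
print(
    "\nBoth two-stage tests fall below 0.05 while the component tests disagree:\n"
    "accounting for model uncertainty, there is a marginally significant\n"
    "association between the KM(1,3) marker and sarcoidosis.  rho* ~ 0.6\n"
    "favours the averaged (SGME) test over MAX3 in this regime."
)
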