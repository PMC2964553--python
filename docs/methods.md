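# Methods

## Data model and notation

A matched study consists of `r` matched sets, each with one case and `m`
controls drawn from the same confounder-defined stratum `C_l`
(`l = 1..L`); the total sample size is `(m+1)r`. Genotypes at a bi-allelic
marker are coded 0/1/2 as copies of a declared candidate allele `D`
(`G0 = dd`, `G1 = Dd`, `G2 = DD`). Per-stratum genotype counts are
`(r_0l, r_1l, r_2l)` in cases and `(s_0l, s_1l, s_2l)` in controls, with
`s_l = m r_l`. All two-stage and robust tests are invariant under swapping
the candidate allele (`g -> 2-g`); the declaration only fixes the signs of
component statistics.

## Component statistics

**Matching trend test (MTT).** With scores `(0, x, 1)` on `(G0, G1, G2)`,
the conditional likelihood of the matched sets gives the score statistic in
closed form,

    Z_MTT(x) = U(x) / sqrt(V(x)),
    U(x) = sum_lj ( m X_1lj - sum_k X_2ljk ),
    V(x) = sum_lj { (m+1)(X_1lj^2 + sum_k X_2ljk^2) - (X_1lj + sum_k X_2ljk)^2 },

asymptotically N(0,1) under no association. `x = 0, 0.5, 1` are optimal
under the recessive, additive and dominant models. The implementation is
verified against numeric differentiation of the conditional log-likelihood
(agreement to 1e-6).

**SMRT.** The Hardy-Weinberg disequilibrium coefficient
`Δ = p2 - (p2 + p1/2)^2` vanishes under HWE, rises in cases under a
recessive model and falls under a dominant one. The stratified model
reduction test sums per-stratum case-control HWD differences and
standardises by the null variance estimate
`λ_l = (m+1)(1-p_l)^2 p_l^2 / (r_l m)` at the pooled allele frequency
`p_l`:

    Z_SMRT = sum_l (Δ_case,l - Δ_ctrl,l) / sqrt( sum_l λ_l ).

It is N(0,1) under the null with per-stratum HWE, positive-shifted under
REC and negative-shifted under DOM.

**Model classification.** With threshold `c` (default `Φ⁻¹(0.95)`,
overridable): REC-side if `Z_SMRT > c`, DOM-side if `Z_SMRT < -c`, ADD
otherwise, with both boundaries joining the ADD branch. On the exclusion
reading, the REC side excludes DOM, the DOM side excludes REC, and the
middle branch excludes both extremes.

**Averaged tests.** `Z_MAT(x) = (Z_MTT(x) + Z_MTT(0.5)) / sqrt(2(1+ρ_x,0.5))`
is the maximin-efficiency-robust combination over the pair
{extreme model x, additive}; it backs the exclusion branches of SGME.

**χ²(2 df).** Dummy-coding genotypes as (0,0), (0,1), (1,1) gives a
two-parameter conditional likelihood whose score statistic `U'V⁻U` at the
origin is χ² with 2 df. Singular information is handled with the
Moore-Penrose inverse and df = rank. Verified against a numeric
gradient/Hessian oracle.

## Null correlations

The two-stage and MAX3 p-values need the null correlations among the
component statistics. Plug-in estimates:

* `corr(Z_SMRT, Z_MTT(0)) = ρ_0 ≥ 0` and `corr(Z_SMRT, Z_MTT(1)) = ρ_1 ≤ 0`
  from the limiting covariances under per-stratum HWE, with the pooled
  allele frequency `p_l` substituted; `corr(Z_SMRT, Z_MTT(0.5))` is
  O(1/r) and fixed at 0.
* pairwise MTT correlations `ρ_0,0.5`, `ρ_1,0.5` and `ρ_0,1` from the
  per-subject score covariances with pooled genotype frequencies
  `(r_il + s_il)/((m+1) r_l)` substituted. `ρ_0,1` follows from the same
  per-subject argument (covariance `p_2l(1 - p_1l - p_2l)` per subject);
  it is needed only by MAX3.

All six estimates are validated against empirical null correlations from
5,000-replicate simulations (agreement within 0.02). Two structural facts
matter downstream:

* the three MTTs are linear in just two genotype contrasts (the G1 and G2
  set differences), so their 3×3 correlation matrix is **singular by
  construction** (rank 2);
* the estimates are mutually consistent as a joint 4-variable law only
  under per-stratum HWE; on grossly non-HWE data the HWE-based `ρ_x` and
  the genotype-based pairwise estimates can disagree, and each branch
  triple is projected to the nearest PSD correlation matrix (eigenvalue
  clipping at 1e-10) before integration.

For the unmatched tests the same delta-method pattern is applied at the
pooled table frequencies. The HWDTT-trend correlations use the general
per-subject covariance of the HWD-gradient score `(0, -p, 1-2p)` with the
trend score, which reduces to `± p²q²` under HWE; keeping the general form
makes the estimates track empirical correlations at non-HWE margins too.

## Two-stage p-values

The SGMS statistic is the model-optimal MTT after classification, with the
risk allele determined by the sign of `Z_MTT(0.5)` (zero joining the
flipped branch); SGME replaces the extreme branches by `Z_MAT(0)/Z_MAT(1)`.
The reported two-sided p-value at `t = |statistic|` is the exact
probability of the rejection event

    { |two-stage statistic| > t }

under the joint asymptotic normal law. The event decomposes into eight
disjoint trivariate rectangles over `(Z_MTT(0.5), Z_SMRT, branch statistic)`
— risk-allele sign × SMRT region × exceedance direction — plus the middle
branch, which factorises because `Z_MTT(0.5)` and `Z_SMRT` are
asymptotically independent: `(2Φ(c) - 1) · 2(1 - Φ(t))`. Enumerating the
event explicitly (rather than reusing a one-signed orthant formula with
reflected correlations) makes the two-fold symmetry emerge instead of
being assumed; the analytic value is required to agree with a Monte-Carlo
event-probability oracle within MC error in the test suite. The SGME
covariances follow algebraically from the averaging transform:
`corr(Z_MTT(0.5), Z_MAT(x)) = sqrt((1+ρ_x,0.5)/2)`,
`corr(Z_SMRT, Z_MAT(x)) = ρ_x / sqrt(2(1+ρ_x,0.5))`.

MAX3's p-value is `1 - P(cube)` under the trivariate MTT law; the GMS/GME
p-values use the identical branch-event machinery with the unmatched
components (for a single 2×3 table the component statistics span only two
degrees of freedom, so that law is always rank-2).

## Trivariate-normal integration

Rectangle probabilities are computed by a deterministic quadrature rather
than quasi-random integration, so every reported p-value is reproducible
bit-for-bit:

* regular case — Genz separation-of-variables: each variable is mapped to
  its conditional-CDF coordinate through the Cholesky factor and the
  resulting unit-square integral evaluated with a tensor Gauss-Legendre
  rule under a cosine endpoint map (which removes the `Φ⁻¹` endpoint
  derivative singularity). Absolute error ≈ 1e-10 at the single-rectangle
  default order (128 nodes); batched simulation calls use 32 nodes
  (≲ 1e-4, far below Monte-Carlo noise in rejection rates). Checked
  against `scipy.stats.multivariate_normal.cdf`.
* rank-2 case (smallest eigenvalue below 1e-8; the MAX3 law always, the
  single-table unmatched law always) — the null eigenvector supplies an
  exact linear constraint; one variable is eliminated and the rectangle
  becomes a bivariate-normal polygon integral, evaluated piecewise with
  the kink locations as segment boundaries (scalar path: adaptive
  quadrature to 1e-10; batch path: segmented Gauss-Legendre, ~1e-9).
* perfectly correlated pairs (|ρ| > 1-1e-9) collapse onto one variable.

Infinite limits are truncated at ±8.5 SD (`Φ(-8.5) ≈ 1e-17`).

## Simulator

Within stratum `l`: HWE genotype frequencies `(q_l², 2p_l q_l, p_l²)`,
penetrances `f_il` with genotype relative risks `λ_1l = f_1l/f_0l`,
`λ_2l = f_2l/f_0l`, and prevalence `k_l = Σ_i f_il Pr(G_i|C_l)`. A model
family indexed by `x` sets `λ_1l = 1 + x(λ_2l - 1)`; `x = -0.25` and
`1.25` give the under-recessive and over-dominant models (feasibility
`f_1l ≥ 0`, `f_2l ≤ 1` checked). Case genotypes follow
`p_il = f_il Pr(G_i|C_l)/k_l`; control genotypes follow the standard
retrospective form `q_il = (1-f_il) Pr(G_i|C_l)/(1-k_l)`. Controls are
sampled independently of their case given the stratum — matching is on the
confounder only, and nothing in the model ties control genotypes to the
matched case.

Populations can be specified by `(p, k, λ)` or by baseline penetrances
`(p, f0, λ)` with prevalences derived — the latter matches how the
model-selection experiment is usually parameterized.

**Vectorization.** A replicate's matched data reduce to per-stratum counts
over the `3^(m+1)` (case, controls) genotype configurations; every
statistic — the three MTTs (whose variance needs within-set cross terms,
hence the configuration counts), SMRT, the 2-df score statistic, the
correlation plug-ins and all analytic p-values — is then a vectorized
function of those counts across 10,000+ replicates. Experiments that need
only genotype-count marginals (SMRT selection/exclusion probabilities) use
a cheaper marginal sampler.

**RNG.** One `numpy` Generator per experiment, seeded from the scenario;
every test is evaluated on the same replicate stream, so rates at nested
significance levels are ordered by construction and identical seeds give
identical results. Replicates with degenerate statistics (zero variance)
are counted and reported separately, never silently dropped.

**GRR calibration.** `calibrate_grr` bisects a common `λ_2` until a target
test's simulated power reaches a target (default ±0.01), using common
random numbers across evaluations so the power trace is monotone. This
reconstructs the "optimal test at 80% power" design of the published power
comparisons, whose effect sizes are not printed; those comparisons are
therefore reproduced qualitatively (orderings), not numerically.

## Default study conditions

The bundled experiment settings mirror the published designs: the
three-stratum matched null (150/150/200 cases, m = 2, allele frequencies
0.1/0.3/0.5, prevalences 0.01/0.05/0.02); the model-selection experiment
(300 cases, m = 2, stratum proportions 0.3/0.3/0.4, baseline penetrances
0.01/0.05/0.02, GRR2 swept over 1.1..2.0); the unmatched designs with
250/250 balanced arms (single population, p = 0.3, k = 0.05) and the
two-stratum confounded designs with case/control splits from 300/200 up to
375/125 (p = 0.2/0.4, k = 0.03/0.07). Simulation-based tests in the suite
run scaled-down replicate counts (2,000-4,000) with correspondingly wider
Monte-Carlo bands; the acceptance script uses 10,000 replicates.

## What the simulator does and does not emulate

It generates exactly the stated stratified model: HWE within stratum,
known stratum membership, constant m, a single bi-allelic marker, no
linkage disequilibrium with an unobserved causal locus, no genotyping
error or missingness, and no departure from HWE within strata. Passing
tests therefore demonstrate correctness of the statistics and their
asymptotic null laws under the model's own assumptions — not robustness to
within-stratum HWE violations, cryptic relatedness, or rare-variant
architectures, none of which are generated.

## Known limitations and discrepancies

* The conditional χ²(2 df) score statistic on the bundled sarcoidosis data
  is 5.208 (p = 0.0739), oracle-verified; the originally reported p-value
  for this test is 0.076 (the likelihood-ratio and Wald variants give
  0.072 and 0.077). The exact score test is retained.
* MAX3's p-value is obtained by direct integration of the asymptotic
  trivariate law (0.0551 on the sarcoidosis data); published analyses of
  the same data used a closed-form approximation printing 0.056.
* The unmatched GMS/GME p-value adjustment is re-derived here with the
  same branch-event machinery as the stratified tests (and is exact for
  its stated law, MC-verified). Published type-I-error magnitudes for the
  *confounded* pooled designs differ somewhat (e.g. 0.996 here vs 0.9625
  reported at the strongest imbalance) — the qualitative result, severe
  and monotone inflation, is fully reproduced, but the printed magnitudes
  depend on details of the earlier adjustment formulas that are not
  reproducible from their description.
* Two-sided p-values throughout; the two-stage statistic is reported
  signed, its p-value computed at `t = |statistic|`.
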