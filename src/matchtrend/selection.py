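"""Genetic-model inference and the two-stage SGMS/SGME tests.

A genetic model (recessive / additive / dominant) leaves a signature in the
Hardy-Weinberg disequilibrium (HWD) coefficient

    Delta = Pr(DD) - [Pr(DD) + Pr(Dd)/2]^2,

whose case-control difference is positive under REC and negative under DOM
when D is the risk allele.  The stratified model reduction test (SMRT)
standardises the summed per-stratum case-control HWD differences:

    Z_SMRT = sum_l Delta-hat_l / sqrt( sum_l lambda-hat_l ),
    lambda-hat_l = (m+1)(1 - p-hat_l)^2 p-hat_l^2 / (r_l m),

and is N(0,1) under no association with per-stratum HWE.  With threshold c
(default Phi^-1(0.95)) the model is classified REC-side if Z_SMRT > c,
DOM-side if Z_SMRT < -c, ADD otherwise.

The two-stage tests then apply the matched trend test matched to that
classification — the model-optimal MTT for selection (SGMS), the averaged
MAT for exclusion (SGME) — with Z_MTT(0.5)'s sign determining the risk
allele.  Because the same data drive both stages, the reported p-value is
the exact probability of the full two-stage rejection event under the joint
asymptotic normal law, assembled from trivariate-normal rectangle
probabilities (Z_MTT(0.5) and Z_SMRT are asymptotically independent, which
makes the middle branch separable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .data import MatchedStudy, stratum_summaries
from .matched import (
    CorrelationEstimates,
    DegenerateStatisticError,
    TestResult,
    estimate_correlations,
    mtt,
)
from .mvn import mvn3_rect, nearest_corr

__all__ = [
    "DEFAULT_THRESHOLD",
    "HwdCoefficient",
    "ModelDecision",
    "hwd_delta",
    "smrt",
    "classify_model",
    "sgms",
    "sgme",
    "branch_orthant",
    "two_stage_pvalue",
]

#: Default model-classification threshold c = Phi^-1(0.95).
DEFAULT_THRESHOLD: float = float(norm.ppf(0.95))


@dataclass(frozen=True)
class HwdCoefficient:
    """Hardy-Weinberg disequilibrium coefficient of a genotype frequency triple."""

    delta: float

    def __post_init__(self) -> None:
        if not (-0.25 - 1e-12 <= self.delta <= 0.25 + 1e-12):
            raise ValueError(f"HWD coefficient out of [-0.25, 0.25]: {self.delta}")


@dataclass(frozen=True)
class ModelDecision:
    """Outcome of the SMRT-based model classification."""

    z_smrt: float
    threshold: float
    label: str          # "REC-side" | "ADD" | "DOM-side"
    excluded: tuple[str, ...]


def hwd_delta(freqs) -> HwdCoefficient:
    """Delta-hat = p2 - (p2 + p1/2)^2 for genotype frequencies (p0, p1, p2).

    Invariant under relabelling the alleles (computing Delta from the d
    perspective gives the same value).
    """
    f = np.asarray(freqs, dtype=float)
    if f.shape != (3,) or np.any(f < -1e-12):
        raise ValueError("genotype frequencies must be a non-negative triple")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"genotype frequencies must sum to 1, got {f.sum()!r}")
    return HwdCoefficient(float(f[2] - (f[2] + 0.5 * f[1]) ** 2))


def smrt(study: MatchedStudy) -> float:
    """Stratified model reduction test Z_SMRT."""
    sums = stratum_summaries(study)
    m = study.m
    num = 0.0
    den = 0.0
    for s in sums:
        d_case = hwd_delta(s.case_freqs).delta
        d_ctrl = hwd_delta(s.control_freqs).delta
        num += d_case - d_ctrl
        p = s.pooled_allele_freq
        den += (m + 1) * (1.0 - p) ** 2 * p**2 / (s.r_l * m)
    if den <= 0:
        raise DegenerateStatisticError("all strata monomorphic: Var(Delta-hat) = 0")
    return float(num / np.sqrt(den))


def classify_model(z_smrt: float, c: float = DEFAULT_THRESHOLD) -> ModelDecision:
    """Classify the genetic model from Z_SMRT; |Z_SMRT| = c joins the ADD branch."""
    if not np.isfinite(z_smrt) or c <= 0:
        raise ValueError("classify_model needs finite z_smrt and c > 0")
    if z_smrt > c:
        return ModelDecision(z_smrt, c, "REC-side", ("DOM",))
    if z_smrt < -c:
        return ModelDecision(z_smrt, c, "DOM-side", ("REC",))
    return ModelDecision(z_smrt, c, "ADD", ("REC", "DOM"))


# ---------------------------------------------------------------------------
# the shared branch-event p-value engine
#
# Under H0 the relevant statistics are jointly normal with unit variances:
#   T05 (additive trend), S (model statistic, independent of T05),
#   A0 (REC-branch statistic), A1 (DOM-branch statistic).
# The two-stage statistic is
#   A0*I(T05>0) - A1*I(T05<=0)   if S > c
#   sign(T05) T05                if |S| <= c
#   A1*I(T05>0) - A0*I(T05<=0)   if S < -c
# and the two-sided p-value at t = |observed| is the probability of
# {|two-stage statistic| > t}, a disjoint union of eight trivariate
# rectangles plus the separable middle-branch term.


def _triple_corr(r05_a: float, rs_a: float) -> np.ndarray:
    R = np.array([[1.0, 0.0, r05_a], [0.0, 1.0, rs_a], [r05_a, rs_a, 1.0]])
    if np.linalg.eigvalsh(R)[0] < 0:
        R = nearest_corr(R)
    return R


def two_stage_pvalue(
    t: float,
    c: float,
    r05_a0: float,
    rs_a0: float,
    r05_a1: float,
    rs_a1: float,
) -> float:
    """P(|two-stage statistic| > t) under the joint asymptotic null law.

    ``r05_a*`` and ``rs_a*`` are the null correlations of the branch
    statistics A0/A1 with T05 and with the model statistic S.
    """
    if t < 0 or c <= 0:
        raise ValueError("two_stage_pvalue needs t >= 0 and c > 0")
    inf = np.inf
    R0 = _triple_corr(r05_a0, rs_a0)
    R1 = _triple_corr(r05_a1, rs_a1)
    # rectangles over (T05, S, A); columns: lower triple, upper triple, corr
    terms = [
        # S > c, T05 > 0 -> statistic A0
        (( 0.0,  c,  t), (inf, inf, inf), R0),
        (( 0.0,  c, -inf), (inf, inf, -t), R0),
        # S > c, T05 <= 0 -> statistic -A1
        ((-inf,  c,  t), (0.0, inf, inf), R1),
        ((-inf,  c, -inf), (0.0, inf, -t), R1),
        # S < -c, T05 > 0 -> statistic A1
        (( 0.0, -inf,  t), (inf, -c, inf), R1),
        (( 0.0, -inf, -inf), (inf, -c, -t), R1),
        # S < -c, T05 <= 0 -> statistic -A0
        ((-inf, -inf,  t), (0.0, -c, inf), R0),
        ((-inf, -inf, -inf), (0.0, -c, -t), R0),
    ]
    p = sum(float(mvn3_rect(np.array(lo), np.array(hi), R)) for lo, hi, R in terms)
    # middle branch: |S| <= c independent of |T05| > t
    p += (2.0 * norm.cdf(c) - 1.0) * 2.0 * norm.sf(t)
    return float(min(1.0, max(0.0, p)))


def branch_orthant(t: float, c: float, sigma: np.ndarray, signs: tuple[int, int]) -> float:
    """P(A > t, S in half-line, T05 in half-line) under N(0, sigma).

    ``sigma`` is the correlation matrix of (T05, S, A); ``signs`` gives the
    half-lines for (T05, S): +1 for (0, inf) / (c, inf), -1 for (-inf, 0] /
    (-inf, -c).  Signed correlations are handled by explicit reflection of
    the corresponding variables.
    """
    if t < 0 or c <= 0:
        raise ValueError("branch_orthant needs t >= 0 and c > 0")
    s05, ss = signs
    lo = np.array([0.0 if s05 > 0 else -np.inf, c if ss > 0 else -np.inf, t])
    hi = np.array([np.inf if s05 > 0 else 0.0, np.inf if ss > 0 else -c, np.inf])
    return float(mvn3_rect(lo, hi, np.asarray(sigma, float)))


def _two_stage_statistic(z05: float, s: float, a0: float, a1: float, c: float) -> tuple[float, str]:
    pos = z05 > 0
    if s > c:
        return (a0 if pos else -a1), "REC-side"
    if s < -c:
        return (a1 if pos else -a0), "DOM-side"
    return (z05 if pos else -z05), "ADD"


def sgms(study: MatchedStudy, c: float = DEFAULT_THRESHOLD) -> TestResult:
    """Stratified genetic model selection test.

    Stage 1 classifies the model with Z_SMRT (threshold c) and determines
    the risk allele from the sign of Z_MTT(0.5); stage 2 applies the
    model-optimal MTT.  The p-value accounts exactly for the selection.
    """
    z0 = mtt(study, 0.0).z
    z05 = mtt(study, 0.5).z
    z1 = mtt(study, 1.0).z
    zs = smrt(study)
    corr = estimate_correlations(study)
    stat, branch = _two_stage_statistic(z05, zs, z0, z1, c)
    p = two_stage_pvalue(abs(stat), c, corr.rho0_05, corr.rho0, corr.rho1_05, corr.rho1)
    direction = "risk allele = candidate" if z05 > 0 else "risk allele = other"
    return TestResult("sgms", float(stat), p, branch=branch, direction=direction, correlations=corr)


def sgme(study: MatchedStudy, c: float = DEFAULT_THRESHOLD) -> TestResult:
    """Stratified genetic model exclusion test.

    As :func:`sgms`, but the extreme branches use the averaged tests
    Z_MAT(0)/Z_MAT(1) (each the MERT over the two models left after
    excluding one extreme); in the middle branch both extremes are excluded
    and Z_MTT(0.5) is used.
    """
    z0 = mtt(study, 0.0).z
    z05 = mtt(study, 0.5).z
    z1 = mtt(study, 1.0).z
    zs = smrt(study)
    corr = estimate_correlations(study)
    d0 = 1.0 + corr.rho0_05
    d1 = 1.0 + corr.rho1_05
    if d0 <= 0 or d1 <= 0:
        raise DegenerateStatisticError("1 + rho_x,0.5 <= 0; averaged tests undefined")
    a0 = (z0 + z05) / np.sqrt(2.0 * d0)
    a1 = (z1 + z05) / np.sqrt(2.0 * d1)
    stat, branch = _two_stage_statistic(z05, zs, a0, a1, c)
    # correlations of the averaged branch statistics with T05 and S
    r05_a0 = np.sqrt(d0 / 2.0)
    r05_a1 = np.sqrt(d1 / 2.0)
    rs_a0 = corr.rho0 / np.sqrt(2.0 * d0)
    rs_a1 = corr.rho1 / np.sqrt(2.0 * d1)
    p = two_stage_pvalue(abs(stat), c, r05_a0, rs_a0, r05_a1, rs_a1)
    direction = "risk allele = candidate" if z05 > 0 else "risk allele = other"
    return TestResult("sgme", float(stat), p, branch=branch, direction=direction, correlations=corr)
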