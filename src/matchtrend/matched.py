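"""Component test statistics for 1:m matched case-control genotype data.

The matching trend test (MTT) is the conditional-logistic score test for a
linear genotype-score effect, with scores (0, x, 1) assigned to genotypes
(G0, G1, G2); x = 0, 0.5, 1 gives the tests optimal under the recessive,
additive and dominant models.  In closed form

    Z_MTT(x) = U(x) / sqrt(V(x)),
    U(x) = sum_lj ( m X_1lj - sum_k X_2ljk ),
    V(x) = sum_lj { (m+1)(X_1lj^2 + sum_k X_2ljk^2) - (X_1lj + sum_k X_2ljk)^2 },

where X_1lj is the case score and X_2ljk the control scores in set j of
stratum l.  Under no association Z_MTT(x) ~ N(0, 1).

Also here: the MERT-style matching averaged tests MAT(0)/MAT(1), the 2-df
conditional score test on dummy-coded genotypes, MAX3 with its asymptotic
trivariate-normal p-value, and the plug-in estimates of the null
correlations among the component statistics that the two-stage and MAX3
p-values require.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .data import MatchedStudy, stratum_summaries
from .mvn import mvn3_rect, nearest_corr

__all__ = [
    "MttResult",
    "CorrelationEstimates",
    "TestResult",
    "DegenerateStatisticError",
    "mtt",
    "mtt_pvalue",
    "mat",
    "chi2_2df",
    "max3",
    "estimate_correlations",
]


class DegenerateStatisticError(ValueError):
    """Raised when a statistic's null variance is zero (no usable contrast)."""


class MttResult(NamedTuple):
    z: float
    u: float
    v: float


@dataclass(frozen=True)
class CorrelationEstimates:
    """Plug-in estimates of the null correlations among the component tests.

    ``rho0``/``rho1`` are corr(Z_SMRT, Z_MTT(0)) and corr(Z_SMRT, Z_MTT(1));
    corr(Z_SMRT, Z_MTT(0.5)) is asymptotically zero and fixed at 0.
    ``rho0_05``, ``rho1_05``, ``rho0_1`` are the pairwise MTT correlations.
    """

    rho0: float
    rho1: float
    rho0_05: float
    rho1_05: float
    rho0_1: float
    rho05: float = 0.0

    def mtt_corr_matrix(self) -> np.ndarray:
        """Correlation matrix of (Z_MTT(0), Z_MTT(0.5), Z_MTT(1))."""
        R = np.array(
            [
                [1.0, self.rho0_05, self.rho0_1],
                [self.rho0_05, 1.0, self.rho1_05],
                [self.rho0_1, self.rho1_05, 1.0],
            ]
        )
        if np.linalg.eigvalsh(R)[0] < 0:
            R = nearest_corr(R)
        return R

    def rho_star(self, model: str) -> float:
        """Minimum correlation of the model-optimal test with the other two MTTs."""
        model = model.upper()
        if model == "REC":
            return min(self.rho0_05, self.rho0_1)
        if model == "ADD":
            return min(self.rho0_05, self.rho1_05)
        if model == "DOM":
            return min(self.rho1_05, self.rho0_1)
        raise ValueError(f"model must be REC, ADD or DOM, got {model!r}")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one association test."""

    name: str
    statistic: float
    p_value: float
    branch: str = "n/a"
    direction: str = "n/a"
    correlations: CorrelationEstimates | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")

    def to_record(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "branch": self.branch,
            "direction": self.direction,
        }


def _scores(g: np.ndarray, x: float) -> np.ndarray:
    # genotype code 0/1/2 -> score 0/x/1
    table = np.array([0.0, x, 1.0])
    return table[g]


def mtt_components(study: MatchedStudy, x: float) -> tuple[float, float]:
    """Numerator U(x) and null variance V(x) of the matching trend test."""
    m = study.m
    u = 0.0
    v = 0.0
    for _, cases, ctrls in study.stratum_arrays():
        cs = _scores(cases, x)
        ks = _scores(ctrls, x)
        ks_sum = ks.sum(axis=1)
        u += float(np.sum(m * cs - ks_sum))
        tot = cs + ks_sum
        v += float(np.sum((m + 1) * (cs**2 + (ks**2).sum(axis=1)) - tot**2))
    return u, v


def mtt(study: MatchedStudy, x: float) -> MttResult:
    """Matching trend test Z_MTT(x) with components U(x), V(x)."""
    u, v = mtt_components(study, x)
    if v <= 0:
        raise DegenerateStatisticError(
            f"V({x}) = 0: every matched set is internally homogeneous under scores (0, {x}, 1) "
            "(marker monomorphic or no within-set genotype contrast)"
        )
    return MttResult(u / np.sqrt(v), u, v)


def mtt_pvalue(z: float) -> float:
    """Two-sided normal p-value, p = 2(1 - Phi(|z|))."""
    return float(2.0 * norm.sf(abs(z)))


def estimate_correlations(study: MatchedStudy) -> CorrelationEstimates:
    """Plug-in null-correlation estimates from the stratum summaries.

    corr(Z_SMRT, Z_MTT(x)) uses the pooled allele-frequency plug-in p-hat_l
    (HWE form); the pairwise MTT correlations use the pooled genotype
    frequencies p-hat_il = (r_il + s_il) / ((m+1) r_l).
    """
    sums = stratum_summaries(study)
    rl = np.array([s.r_l for s in sums], dtype=float)
    p = np.array([s.pooled_allele_freq for s in sums])
    if np.all((p <= 0) | (p >= 1)):
        raise DegenerateStatisticError("all strata are monomorphic; correlations undefined")
    q = 1.0 - p

    # corr(SMRT, MTT(x)): numerator sum p^2 q^2; denominators from the
    # limiting variances of Delta-hat and U(x) under HWE.
    A = np.sum(p**2 * q**2)
    B = np.sum(p**2 * q**2 / rl)
    C0 = np.sum(rl * p**2 * (1.0 - p**2))
    C1 = np.sum(rl * p * (2.0 - p) * q**2)
    if B <= 0 or C0 <= 0 or C1 <= 0:
        raise DegenerateStatisticError("degenerate correlation denominators (monomorphic strata)")
    rho0 = A / np.sqrt(B * C0)
    rho1 = -A / np.sqrt(B * C1)

    # pairwise MTT correlations with pooled genotype-frequency plug-ins
    pg = np.array([s.pooled_genotype_freqs for s in sums])  # (L, 3)
    p1, p2 = pg[:, 1], pg[:, 2]
    v0 = np.sum(rl * (p2 - p2**2))
    v05 = np.sum(rl * (0.25 * p1 + p2 - (0.5 * p1 + p2) ** 2))
    v1 = np.sum(rl * ((p1 + p2) - (p1 + p2) ** 2))
    if v0 <= 0 or v05 <= 0 or v1 <= 0:
        raise DegenerateStatisticError("degenerate MTT variance under some scoring")
    c0_05 = np.sum(rl * (p2 - 0.5 * p1 * p2 - p2**2))
    c1_05 = np.sum(rl * (0.5 * p1 + p2 - 0.5 * p1**2 - 1.5 * p1 * p2 - p2**2))
    c0_1 = np.sum(rl * p2 * (1.0 - p1 - p2))
    return CorrelationEstimates(
        rho0=float(rho0),
        rho1=float(rho1),
        rho0_05=float(c0_05 / np.sqrt(v0 * v05)),
        rho1_05=float(c1_05 / np.sqrt(v1 * v05)),
        rho0_1=float(c0_1 / np.sqrt(v0 * v1)),
    )


def mat(study: MatchedStudy, x: float, corr: CorrelationEstimates | None = None) -> float:
    """Matching averaged test Z_MAT(x) = (Z_MTT(x) + Z_MTT(0.5)) / sqrt(2(1+rho_x,0.5)).

    The MERT over the {extreme model x, additive} pair; x must be 0 or 1.
    """
    if x not in (0, 1):
        raise ValueError("MAT is defined for x = 0 (REC side) or x = 1 (DOM side)")
    corr = corr or estimate_correlations(study)
    rho = corr.rho0_05 if x == 0 else corr.rho1_05
    if 1.0 + rho <= 0:
        raise DegenerateStatisticError(f"1 + rho_{x},0.5 <= 0; MAT undefined")
    zx = mtt(study, x).z
    z05 = mtt(study, 0.5).z
    return float((zx + z05) / np.sqrt(2.0 * (1.0 + rho)))


_DUMMY = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0]])  # G0, G1, G2 -> (x1, x2)


def chi2_2df(study: MatchedStudy) -> TestResult:
    """Conditional-logistic score test with two dummy-coded genotype effects.

    Genotypes are coded (0,0), (0,1), (1,1); the score statistic U'V^-U at
    beta = 0 is chi-square with 2 df (df = rank(V) when the information is
    singular, via the Moore-Penrose inverse).
    """
    m = study.m
    U = np.zeros(2)
    V = np.zeros((2, 2))
    for _, cases, ctrls in study.stratum_arrays():
        wc = _DUMMY[cases]                       # (r_l, 2)
        wk = _DUMMY[ctrls]                       # (r_l, m, 2)
        wbar = (wc + wk.sum(axis=1)) / (m + 1)
        U += np.sum(wc - wbar, axis=0)
        ww = np.einsum("ji,jk->ik", wc, wc) + np.einsum("jmi,jmk->ik", wk, wk)
        V += ww / (m + 1) - np.einsum("ji,jk->ik", wbar, wbar)
    rank = np.linalg.matrix_rank(V, tol=1e-12)
    if rank == 0:
        if np.allclose(U, 0.0):
            return TestResult("chi2_2df", 0.0, 1.0)
        raise DegenerateStatisticError("zero conditional information in both genotype contrasts")
    stat = float(U @ np.linalg.pinv(V) @ U)
    p = float(chi2_dist.sf(stat, df=rank))
    branch = "n/a" if rank == 2 else f"rank-deficient (df={rank})"
    return TestResult("chi2_2df", stat, p, branch=branch)


def max3(study: MatchedStudy, corr: CorrelationEstimates | None = None) -> TestResult:
    """MAX3 = max(|Z_MTT(0)|, |Z_MTT(0.5)|, |Z_MTT(1)|) with asymptotic p-value.

    The p-value is 1 - P(|Z1|<=t, |Z2|<=t, |Z3|<=t) under the trivariate
    normal null law with the estimated pairwise MTT correlations.
    """
    z = np.array([mtt(study, x).z for x in (0.0, 0.5, 1.0)])
    t = float(np.max(np.abs(z)))
    corr = corr or estimate_correlations(study)
    R = corr.mtt_corr_matrix()
    inside = float(mvn3_rect(-t * np.ones(3), t * np.ones(3), R))
    direction = "risk allele = candidate" if z[1] > 0 else "risk allele = other"
    return TestResult("max3", t, min(1.0, max(0.0, 1.0 - inside)), direction=direction, correlations=corr)


def max3_pvalue_mc(t: float, R: np.ndarray, n_draws: int = 1_000_000, seed: int = 0) -> float:
    """Monte-Carlo fallback/oracle for the MAX3 exceedance probability."""
    rng = np.random.default_rng(seed)
    Z = rng.multivariate_normal(np.zeros(3), R, size=n_draws, method="cholesky")
    return float(np.mean(np.max(np.abs(Z), axis=1) > t))
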