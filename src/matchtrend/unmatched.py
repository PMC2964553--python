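"""Unmatched-design counterparts: CATT, HWDTT, and the two-stage GMS/GME.

For a 2x3 case-control genotype table, the Cochran-Armitage trend test with
scores (0, x, 1) is

    T_x = sum_i a_i (s r_i - r s_i) / n  /  sqrt( (rs/n)[sum a^2 n_i/n - (sum a n_i/n)^2] ),

and the Hardy-Weinberg disequilibrium trend test contrasts the case and
control HWD coefficients, standardised by the null variance
(1/r + 1/s) p^2 (1-p)^2 at the pooled allele frequency p.

GMS selects the model whose trend test to apply from T_HWDTT (threshold c),
with T_0.5 determining the risk allele; GME replaces the extreme-branch
trend tests by the averaged tests T*_x = (T_x + T_0.5)/sqrt(2(1+rho_x,0.5)).
P-values reuse the branch-event trivariate-normal machinery of
:mod:`matchtrend.selection`, with plug-in null correlations specialised to
independent case/control sampling.  These tests assume a single source
population in HWE; applied to data pooled over hidden strata they can be
badly anti-conservative, which is the motivation for the matched-design
tests in :mod:`matchtrend.matched` / :mod:`matchtrend.selection`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .data import UnmatchedTable
from .matched import CorrelationEstimates, DegenerateStatisticError, TestResult
from .selection import DEFAULT_THRESHOLD, _two_stage_statistic, two_stage_pvalue
from .selection import hwd_delta

__all__ = [
    "UnmatchedResult",
    "catt",
    "hwdtt",
    "gms",
    "gme",
    "unmatched_correlations",
]


@dataclass(frozen=True)
class UnmatchedResult(TestResult):
    """Two-stage unmatched test outcome, with the component statistics."""

    t0: float = np.nan
    t05: float = np.nan
    t1: float = np.nan
    t_hwdtt: float = np.nan


def catt(table: UnmatchedTable, x: float) -> float:
    """Cochran-Armitage trend test with scores (0, x, 1); N(0,1) under H0."""
    a = np.array([0.0, x, 1.0])
    rc = table.case_counts
    sc = table.control_counts
    r, s, n = table.r, table.s, table.n
    pooled = (rc + sc) / n
    u = float(np.sum(a * (s * rc - r * sc)) / n)
    var = (r * s / n) * (np.sum(a**2 * pooled) - np.sum(a * pooled) ** 2)
    if var <= 0:
        raise DegenerateStatisticError(f"zero CATT variance under scores (0, {x}, 1)")
    return u / float(np.sqrt(var))


def hwdtt(table: UnmatchedTable) -> float:
    """HWD trend test: (Delta_case - Delta_control)/sqrt((1/r + 1/s) p^2 q^2).

    Positive values point to a recessive, negative to a dominant model (for
    the candidate allele as risk allele).
    """
    p = table.pooled_allele_freq
    if not (0.0 < p < 1.0):
        raise DegenerateStatisticError("monomorphic table: HWDTT undefined")
    dp = hwd_delta(table.case_counts / table.r).delta
    dq = hwd_delta(table.control_counts / table.s).delta
    v0 = (1.0 / table.r + 1.0 / table.s) * p**2 * (1.0 - p) ** 2
    return float((dp - dq) / np.sqrt(v0))


def unmatched_correlations(table: UnmatchedTable) -> CorrelationEstimates:
    """Plug-in null correlations among (T_HWDTT, T_0, T_0.5, T_1).

    All correlations come from the delta method at the pooled genotype
    frequencies: each statistic is asymptotically a mean contrast of a
    per-subject score (the HWD gradient for T_HWDTT, the trend score for
    T_x), so the null correlation is the per-subject score correlation.
    Both case/control arms contribute (1/r + 1/s) factors that cancel.
    Under HWE the T_HWDTT cross-correlations reduce to closed forms in the
    allele frequency (+/- p^2 q^2 covariances, zero against the additive
    score); the general form is kept so the estimates track the empirical
    correlations at non-HWE margins too.
    """
    p = table.pooled_allele_freq
    if not (0.0 < p < 1.0):
        raise DegenerateStatisticError("monomorphic table")

    g = (table.case_counts + table.control_counts) / table.n
    p1, p2 = g[1], g[2]
    pbar = p2 + 0.5 * p1
    # per-subject HWD-gradient score: 0, -pbar, 1-2*pbar on G0, G1, G2
    e_g = -p1 * pbar + p2 * (1.0 - 2.0 * pbar)
    v_g = p1 * pbar**2 + p2 * (1.0 - 2.0 * pbar) ** 2 - e_g**2
    if v_g <= 0:
        raise DegenerateStatisticError("degenerate HWD-gradient variance")

    def cov_g_trend(x: float) -> float:
        e_ga = -x * p1 * pbar + p2 * (1.0 - 2.0 * pbar)
        return e_ga - e_g * (x * p1 + p2)

    def v_obs(x: float) -> float:
        return x**2 * p1 + p2 - (x * p1 + p2) ** 2

    v0, v05, v1 = v_obs(0.0), v_obs(0.5), v_obs(1.0)
    if min(v0, v05, v1) <= 0:
        raise DegenerateStatisticError("degenerate trend variance")
    c0_05 = p2 - 0.5 * p1 * p2 - p2**2
    c1_05 = 0.5 * p1 + p2 - 0.5 * p1**2 - 1.5 * p1 * p2 - p2**2
    c0_1 = p2 * (1.0 - p1 - p2)
    return CorrelationEstimates(
        rho0=float(cov_g_trend(0.0) / np.sqrt(v_g * v0)),
        rho1=float(cov_g_trend(1.0) / np.sqrt(v_g * v1)),
        rho0_05=float(c0_05 / np.sqrt(v0 * v05)),
        rho1_05=float(c1_05 / np.sqrt(v1 * v05)),
        rho0_1=float(c0_1 / np.sqrt(v0 * v1)),
    )


def _components(table: UnmatchedTable) -> tuple[float, float, float, float, CorrelationEstimates]:
    t0 = catt(table, 0.0)
    t05 = catt(table, 0.5)
    t1 = catt(table, 1.0)
    th = hwdtt(table)
    return t0, t05, t1, th, unmatched_correlations(table)


def gms(table: UnmatchedTable, c: float = DEFAULT_THRESHOLD) -> UnmatchedResult:
    """Genetic model selection test for an unmatched 2x3 table."""
    t0, t05, t1, th, corr = _components(table)
    stat, branch = _two_stage_statistic(t05, th, t0, t1, c)
    p = two_stage_pvalue(abs(stat), c, corr.rho0_05, corr.rho0, corr.rho1_05, corr.rho1)
    direction = "risk allele = candidate" if t05 > 0 else "risk allele = other"
    return UnmatchedResult(
        "gms", float(stat), p, branch=branch, direction=direction, correlations=corr,
        t0=t0, t05=t05, t1=t1, t_hwdtt=th,
    )


def gme(table: UnmatchedTable, c: float = DEFAULT_THRESHOLD) -> UnmatchedResult:
    """Genetic model exclusion test for an unmatched 2x3 table."""
    t0, t05, t1, th, corr = _components(table)
    d0 = 1.0 + corr.rho0_05
    d1 = 1.0 + corr.rho1_05
    if d0 <= 0 or d1 <= 0:
        raise DegenerateStatisticError("1 + rho_x,0.5 <= 0; averaged tests undefined")
    a0 = (t0 + t05) / np.sqrt(2.0 * d0)
    a1 = (t1 + t05) / np.sqrt(2.0 * d1)
    stat, branch = _two_stage_statistic(t05, th, a0, a1, c)
    p = two_stage_pvalue(
        abs(stat), c,
        float(np.sqrt(d0 / 2.0)), float(corr.rho0 / np.sqrt(2.0 * d0)),
        float(np.sqrt(d1 / 2.0)), float(corr.rho1 / np.sqrt(2.0 * d1)),
    )
    direction = "risk allele = candidate" if t05 > 0 else "risk allele = other"
    return UnmatchedResult(
        "gme", float(stat), p, branch=branch, direction=direction, correlations=corr,
        t0=t0, t05=t05, t1=t1, t_hwdtt=th,
    )
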