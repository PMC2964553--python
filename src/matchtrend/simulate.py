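"""Stratified-population simulator and simulation experiments.

The population model: confounders define L strata; within stratum l the
marker is in HWE with risk-allele frequency p_l, the disease has prevalence
k_l, and the penetrances f_il = Pr(case | G_i, C_l) follow genotype relative
risks lambda_1l = f_1l/f_0l, lambda_2l = f_2l/f_0l.  A one-parameter model
family indexed by x sets lambda_1l = 1 + x (lambda_2l - 1): x = 0, 0.5, 1
give the recessive, additive and dominant models, and x = -0.25 / 1.25 the
under-recessive / over-dominant models (feasibility f_1l >= 0, f_2l <= 1 is
checked).

Case genotypes are drawn from p_il = f_il Pr(G_i|C_l) / k_l and control
genotypes from q_il = (1 - f_il) Pr(G_i|C_l) / (1 - k_l); controls are
matched on the stratum only, hence independent of their case's genotype
given the stratum.

Experiments (type-I error / power, model selection-vs-exclusion
probabilities, GRR calibration) run fully vectorised over replicates: each
replicate's matched data reduce to per-stratum counts over the 3^(m+1)
(case, controls) genotype configurations, from which every statistic and
analytic p-value in the package is computed in batch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .data import MatchedSet, MatchedStudy, UnmatchedTable
from .mvn import mvn3_rect, nearest_corr
from .selection import DEFAULT_THRESHOLD

__all__ = [
    "PopulationModel",
    "SimulationScenario",
    "ExperimentResult",
    "penetrances",
    "genotype_distributions",
    "simulate_matched",
    "simulate_unmatched_pooled",
    "rejection_rate",
    "selection_exclusion_probs",
    "calibrate_grr",
    "MATCHED_TESTS",
    "UNMATCHED_TESTS",
]

MATCHED_TESTS = ("mtt0", "mtt05", "mtt1", "sgms", "sgme", "max3", "chi2df2")
UNMATCHED_TESTS = ("catt0", "catt05", "catt1", "gms", "gme")

_MODEL_X = {"REC": 0.0, "ADD": 0.5, "DOM": 1.0}


def penetrances(k: float, p: float, lambda1: float, lambda2: float) -> tuple[float, float, float]:
    """Penetrances (f0, f1, f2) matching prevalence k under HWE at frequency p."""
    q = 1.0 - p
    denom = q**2 + 2.0 * p * q * lambda1 + p**2 * lambda2
    f0 = k / denom
    f1, f2 = f0 * lambda1, f0 * lambda2
    if f1 < 0 or f2 > 1.0 or f0 <= 0 or f0 > 1.0:
        raise ValueError(
            f"infeasible penetrances (f0={f0:.4g}, f1={f1:.4g}, f2={f2:.4g}) "
            f"for k={k}, p={p}, GRRs=({lambda1}, {lambda2})"
        )
    return f0, f1, f2


@dataclass(frozen=True)
class PopulationModel:
    """Stratified disease-marker population (HWE within stratum)."""

    p: tuple[float, ...]
    k: tuple[float, ...]
    lambda1: tuple[float, ...]
    lambda2: tuple[float, ...]
    x_model: float | None = None   # model-family index, if built from one

    def __post_init__(self) -> None:
        L = len(self.p)
        if not (L == len(self.k) == len(self.lambda1) == len(self.lambda2)) or L == 0:
            raise ValueError("p, k, lambda1, lambda2 must have equal positive length")
        for pl, kl in zip(self.p, self.k):
            if not (0.0 < pl < 1.0 and 0.0 < kl < 1.0):
                raise ValueError("allele frequencies and prevalences must lie in (0, 1)")
        for l in range(L):
            penetrances(self.k[l], self.p[l], self.lambda1[l], self.lambda2[l])

    @property
    def L(self) -> int:
        return len(self.p)

    @classmethod
    def null(cls, p: Sequence[float], k: Sequence[float]) -> "PopulationModel":
        """No-association model: all GRRs equal to 1."""
        L = len(p)
        return cls(tuple(p), tuple(k), (1.0,) * L, (1.0,) * L, x_model=None)

    @classmethod
    def from_grr(
        cls, p: Sequence[float], k: Sequence[float], lambda2: float | Sequence[float], x_model: float
    ) -> "PopulationModel":
        """Model family lambda_1l = 1 + x (lambda_2l - 1), common x across strata."""
        L = len(p)
        l2 = tuple(lambda2) if np.ndim(lambda2) else (float(lambda2),) * L
        l1 = tuple(1.0 + x_model * (v - 1.0) for v in l2)
        return cls(tuple(p), tuple(k), l1, l2, x_model=float(x_model))

    @classmethod
    def from_baseline_penetrance(
        cls, p: Sequence[float], f0: Sequence[float], lambda2: float | Sequence[float], x_model: float
    ) -> "PopulationModel":
        """Specify baseline penetrances f_0l directly; prevalences are derived."""
        L = len(p)
        l2 = tuple(lambda2) if np.ndim(lambda2) else (float(lambda2),) * L
        l1 = tuple(1.0 + x_model * (v - 1.0) for v in l2)
        k = []
        for pl, f0l, l1l, l2l in zip(p, f0, l1, l2):
            q = 1.0 - pl
            k.append(f0l * (q**2 + 2.0 * pl * q * l1l + pl**2 * l2l))
        return cls(tuple(p), tuple(k), l1, l2, x_model=float(x_model))

    def model_label(self) -> str | None:
        if self.x_model is None:
            return None
        for lab, x in _MODEL_X.items():
            if abs(self.x_model - x) < 1e-12:
                return lab
        return f"x={self.x_model}"


def genotype_distributions(population: PopulationModel, stratum: int) -> tuple[np.ndarray, np.ndarray]:
    """Case and control genotype triples (p_il, q_il) for one stratum.

    p_il = f_il Pr(G_i|C_l) / k_l and q_il = (1 - f_il) Pr(G_i|C_l) / (1 - k_l).
    """
    p = population.p[stratum]
    k = population.k[stratum]
    f = np.array(penetrances(k, p, population.lambda1[stratum], population.lambda2[stratum]))
    q = 1.0 - p
    g = np.array([q**2, 2.0 * p * q, p**2])
    case = f * g / k
    ctrl = (1.0 - f) * g / (1.0 - k)
    if abs(case.sum() - 1.0) > 1e-9 or abs(ctrl.sum() - 1.0) > 1e-9:
        raise ValueError("genotype distributions do not normalise; infeasible parameters")
    return case / case.sum(), ctrl / ctrl.sum()


@dataclass(frozen=True)
class ExperimentResult:
    """Rates (or probabilities) per test with Monte-Carlo standard errors."""

    rates: dict
    mc_se: dict
    n_reps: int
    seed: int
    errors: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SimulationScenario:
    """One simulation experiment: population + sampling + replication plan.

    ``r`` gives per-stratum case counts.  For matched designs each case gets
    ``m`` stratum-matched controls; for unmatched pooled designs ``s`` gives
    per-stratum control counts and the stratum labels are discarded before
    analysis.
    """

    population: PopulationModel
    r: tuple[int, ...]
    m: int = 1
    s: tuple[int, ...] | None = None
    n_reps: int = 10_000
    alpha: float = 0.05
    c: float = DEFAULT_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.r) != self.population.L:
            raise ValueError("per-stratum case counts r must match the number of strata")
        if any(v <= 0 for v in self.r) or self.m < 1:
            raise ValueError("case counts and m must be positive")
        if self.s is not None and len(self.s) != self.population.L:
            raise ValueError("per-stratum control counts s must match the number of strata")
        if self.n_reps < 1 or not (0.0 < self.alpha < 1.0):
            raise ValueError("need n_reps >= 1 and 0 < alpha < 1")


# ---------------------------------------------------------------------------
# single-study samplers


def simulate_matched(scenario: SimulationScenario, rng: np.random.Generator | None = None) -> MatchedStudy:
    """Draw one matched study: r_l cases and m r_l stratum-matched controls."""
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    pop = scenario.population
    sets: list[MatchedSet] = []
    for l in range(pop.L):
        case_p, ctrl_p = genotype_distributions(pop, l)
        cases = rng.choice(3, size=scenario.r[l], p=case_p)
        ctrls = rng.choice(3, size=(scenario.r[l], scenario.m), p=ctrl_p)
        lab = f"S{l + 1}"
        sets.extend(
            MatchedSet(lab, int(cases[j]), tuple(int(g) for g in ctrls[j]))
            for j in range(scenario.r[l])
        )
    return MatchedStudy(tuple(sets))


def simulate_unmatched_pooled(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> UnmatchedTable:
    """Draw per-stratum cases/controls and pool into one 2x3 table."""
    if scenario.s is None:
        raise ValueError("unmatched pooled sampling needs per-stratum control counts s")
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    pop = scenario.population
    rc = np.zeros(3, dtype=int)
    sc = np.zeros(3, dtype=int)
    for l in range(pop.L):
        case_p, ctrl_p = genotype_distributions(pop, l)
        rc += rng.multinomial(scenario.r[l], case_p)
        sc += rng.multinomial(scenario.s[l], ctrl_p)
    return UnmatchedTable(*map(int, rc), *map(int, sc))


# ---------------------------------------------------------------------------
# vectorised batch machinery


def _set_types(m: int) -> np.ndarray:
    """All (case, control_1..m) genotype configurations, shape (3^(m+1), m+1)."""
    return np.array(list(itertools.product(range(3), repeat=m + 1)), dtype=np.int64)


def _matched_batch_counts(
    pop: PopulationModel, r: Sequence[int], m: int, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial set-configuration counts, shape (n_reps, L, T)."""
    types = _set_types(m)
    T = types.shape[0]
    counts = np.empty((n_reps, pop.L, T), dtype=np.int64)
    for l in range(pop.L):
        case_p, ctrl_p = genotype_distributions(pop, l)
        probs = case_p[types[:, 0]] * np.prod(ctrl_p[types[:, 1:]], axis=1)
        counts[:, l, :] = rng.multinomial(r[l], probs, size=n_reps)
    return counts


_DUMMY = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0]])


def _matched_batch_stats(counts: np.ndarray, m: int) -> dict:
    """Per-replicate statistics from set-configuration counts.

    Returns z-statistics for the three MTTs, the SMRT, the 2-df conditional
    score statistic, and the plug-in correlation estimates, all vectorised.
    """
    n_reps, L, T = counts.shape
    types = _set_types(m)
    caseg = types[:, 0]
    ctrlg = types[:, 1:]

    cnt = counts.astype(float)
    pooled_l = cnt.sum(axis=2)                                   # r_l per stratum (constant)

    # genotype count marginals per stratum
    case_onehot = np.eye(3)[caseg]                               # (T, 3)
    ctrl_tally = np.zeros((T, 3))
    for j in range(m):
        ctrl_tally += np.eye(3)[ctrlg[:, j]]
    r_il = np.einsum("nlt,ti->nli", cnt, case_onehot)
    s_il = np.einsum("nlt,ti->nli", cnt, ctrl_tally)

    out: dict = {"r_il": r_il, "s_il": s_il}

    # MTT components per score
    zs = {}
    for key, x in (("0", 0.0), ("05", 0.5), ("1", 1.0)):
        a = np.array([0.0, x, 1.0])
        cs = a[caseg]
        ks = a[ctrlg]
        ksum = ks.sum(axis=1)
        ut = m * cs - ksum
        vt = (m + 1) * (cs**2 + (ks**2).sum(axis=1)) - (cs + ksum) ** 2
        U = np.einsum("nlt,t->n", cnt, ut)
        V = np.einsum("nlt,t->n", cnt, vt)
        with np.errstate(divide="ignore", invalid="ignore"):
            zs[key] = np.where(V > 0, U / np.sqrt(V), np.nan)
    out["z0"], out["z05"], out["z1"] = zs["0"], zs["05"], zs["1"]

    # SMRT
    rl = pooled_l                                                # (n, L)
    case_f = r_il / rl[..., None]
    ctrl_f = s_il / (m * rl[..., None])
    d_case = case_f[..., 2] - (case_f[..., 2] + 0.5 * case_f[..., 1]) ** 2
    d_ctrl = ctrl_f[..., 2] - (ctrl_f[..., 2] + 0.5 * ctrl_f[..., 1]) ** 2
    phat = (2.0 * (r_il[..., 2] + s_il[..., 2]) + r_il[..., 1] + s_il[..., 1]) / (
        2.0 * (m + 1) * rl
    )
    lam = (m + 1) * (1.0 - phat) ** 2 * phat**2 / (rl * m)
    den = lam.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["smrt"] = np.where(den > 0, (d_case - d_ctrl).sum(axis=1) / np.sqrt(den), np.nan)

    # 2-df conditional score statistic
    wc = _DUMMY[caseg]
    wk = _DUMMY[ctrlg]
    wbar = (wc + wk.sum(axis=1)) / (m + 1)
    ut2 = wc - wbar                                              # (T, 2)
    it2 = (
        np.einsum("ti,tk->tik", wc, wc) + np.einsum("tji,tjk->tik", wk, wk)
    ) / (m + 1) - np.einsum("ti,tk->tik", wbar, wbar)
    U2 = np.einsum("nlt,ti->ni", cnt, ut2)
    I2 = np.einsum("nlt,tik->nik", cnt, it2)
    det = I2[:, 0, 0] * I2[:, 1, 1] - I2[:, 0, 1] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (
            U2[:, 0] ** 2 * I2[:, 1, 1]
            - 2.0 * U2[:, 0] * U2[:, 1] * I2[:, 0, 1]
            + U2[:, 1] ** 2 * I2[:, 0, 0]
        ) / det
    out["chi2"] = np.where(det > 1e-12, stat, np.nan)

    # plug-in correlations (vectorised mirror of matched.estimate_correlations)
    q = 1.0 - phat
    A = (phat**2 * q**2).sum(axis=1)
    B = (phat**2 * q**2 / rl).sum(axis=1)
    C0 = (rl * phat**2 * (1.0 - phat**2)).sum(axis=1)
    C1 = (rl * phat * (2.0 - phat) * q**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rho0"] = A / np.sqrt(B * C0)
        out["rho1"] = -A / np.sqrt(B * C1)
    pg = (r_il + s_il) / ((m + 1) * rl[..., None])
    p1, p2 = pg[..., 1], pg[..., 2]
    v0 = (rl * (p2 - p2**2)).sum(axis=1)
    v05 = (rl * (0.25 * p1 + p2 - (0.5 * p1 + p2) ** 2)).sum(axis=1)
    v1 = (rl * ((p1 + p2) - (p1 + p2) ** 2)).sum(axis=1)
    c0_05 = (rl * (p2 - 0.5 * p1 * p2 - p2**2)).sum(axis=1)
    c1_05 = (rl * (0.5 * p1 + p2 - 0.5 * p1**2 - 1.5 * p1 * p2 - p2**2)).sum(axis=1)
    c0_1 = (rl * p2 * (1.0 - p1 - p2)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rho0_05"] = c0_05 / np.sqrt(v0 * v05)
        out["rho1_05"] = c1_05 / np.sqrt(v1 * v05)
        out["rho0_1"] = c0_1 / np.sqrt(v0 * v1)
    return out


def _two_stage_statistic_batch(z05, s, a0, a1, c):
    pos = z05 > 0
    upper = np.where(pos, a0, -a1)
    lower = np.where(pos, a1, -a0)
    middle = np.abs(z05)
    return np.where(s > c, upper, np.where(s < -c, lower, middle))


def _two_stage_pvalue_batch(t, c, r05_a0, rs_a0, r05_a1, rs_a1, nodes=32, chunk=2000):
    """Vectorised branch-event p-value; mirrors selection.two_stage_pvalue."""
    t = np.asarray(t, float)
    n = t.shape[0]
    out = np.empty(n)
    inf = np.inf
    for lo_i in range(0, n, chunk):
        sl = slice(lo_i, min(lo_i + chunk, n))
        tt = t[sl]
        k = tt.shape[0]
        R0 = np.zeros((k, 3, 3))
        R0[:, 0, 0] = R0[:, 1, 1] = R0[:, 2, 2] = 1.0
        R1 = R0.copy()
        R0[:, 0, 2] = R0[:, 2, 0] = r05_a0[sl]
        R0[:, 1, 2] = R0[:, 2, 1] = rs_a0[sl]
        R1[:, 0, 2] = R1[:, 2, 0] = r05_a1[sl]
        R1[:, 1, 2] = R1[:, 2, 1] = rs_a1[sl]
        R0 = nearest_corr(R0)
        R1 = nearest_corr(R1)

        def rect(l0, l1, u0, u1, R, third_low):
            lo = np.empty((k, 3))
            hi = np.empty((k, 3))
            lo[:, 0], hi[:, 0] = l0, u0
            lo[:, 1], hi[:, 1] = l1, u1
            if third_low:
                lo[:, 2], hi[:, 2] = tt, inf
            else:
                lo[:, 2], hi[:, 2] = -inf, -tt
            return mvn3_rect(lo, hi, R, nodes=nodes)

        p = (
            rect(0.0, c, inf, inf, R0, True)
            + rect(0.0, c, inf, inf, R0, False)
            + rect(-inf, c, 0.0, inf, R1, True)
            + rect(-inf, c, 0.0, inf, R1, False)
            + rect(0.0, -inf, inf, -c, R1, True)
            + rect(0.0, -inf, inf, -c, R1, False)
            + rect(-inf, -inf, 0.0, -c, R0, True)
            + rect(-inf, -inf, 0.0, -c, R0, False)
        )
        p += (2.0 * norm.cdf(c) - 1.0) * 2.0 * norm.sf(tt)
        out[sl] = np.clip(p, 0.0, 1.0)
    return out


def matched_pvalues_batch(stats: Mapping[str, np.ndarray], c: float, tests: Iterable[str]) -> dict:
    """Analytic p-values per replicate for the requested matched tests."""
    pv: dict[str, np.ndarray] = {}
    z0, z05, z1 = stats["z0"], stats["z05"], stats["z1"]
    for name, z in (("mtt0", z0), ("mtt05", z05), ("mtt1", z1)):
        if name in tests:
            pv[name] = 2.0 * norm.sf(np.abs(z))
    if "chi2df2" in tests:
        pv["chi2df2"] = chi2_dist.sf(stats["chi2"], df=2)
    if "max3" in tests:
        n = z0.shape[0]
        tmax = np.nanmax(np.abs(np.stack([z0, z05, z1], axis=1)), axis=1)
        R = np.zeros((n, 3, 3))
        R[:, 0, 0] = R[:, 1, 1] = R[:, 2, 2] = 1.0
        R[:, 0, 1] = R[:, 1, 0] = stats["rho0_05"]
        R[:, 1, 2] = R[:, 2, 1] = stats["rho1_05"]
        R[:, 0, 2] = R[:, 2, 0] = stats["rho0_1"]
        R = nearest_corr(R)
        lo = -tmax[:, None] * np.ones(3)
        hi = tmax[:, None] * np.ones(3)
        inside = np.empty(n)
        for i0 in range(0, n, 2000):
            sl = slice(i0, min(i0 + 2000, n))
            inside[sl] = mvn3_rect(lo[sl], hi[sl], R[sl], nodes=32)
        pv["max3"] = np.clip(1.0 - inside, 0.0, 1.0)
    if "sgms" in tests:
        stat = _two_stage_statistic_batch(z05, stats["smrt"], z0, z1, c)
        pv["sgms"] = _two_stage_pvalue_batch(
            np.abs(stat), c, stats["rho0_05"], stats["rho0"], stats["rho1_05"], stats["rho1"]
        )
    if "sgme" in tests:
        d0 = 1.0 + stats["rho0_05"]
        d1 = 1.0 + stats["rho1_05"]
        a0 = (z0 + z05) / np.sqrt(2.0 * d0)
        a1 = (z1 + z05) / np.sqrt(2.0 * d1)
        stat = _two_stage_statistic_batch(z05, stats["smrt"], a0, a1, c)
        pv["sgme"] = _two_stage_pvalue_batch(
            np.abs(stat), c,
            np.sqrt(d0 / 2.0), stats["rho0"] / np.sqrt(2.0 * d0),
            np.sqrt(d1 / 2.0), stats["rho1"] / np.sqrt(2.0 * d1),
        )
    return pv


def _unmatched_batch_stats(scenario: SimulationScenario, rng: np.random.Generator) -> dict:
    pop = scenario.population
    n = scenario.n_reps
    rc = np.zeros((n, 3))
    sc = np.zeros((n, 3))
    for l in range(pop.L):
        case_p, ctrl_p = genotype_distributions(pop, l)
        rc += rng.multinomial(scenario.r[l], case_p, size=n)
        sc += rng.multinomial(scenario.s[l], ctrl_p, size=n)
    r = rc.sum(axis=1)
    s = sc.sum(axis=1)
    ntot = r + s
    out: dict = {}
    a_by = {"0": np.array([0.0, 0.0, 1.0]), "05": np.array([0.0, 0.5, 1.0]), "1": np.array([0.0, 1.0, 1.0])}
    pooled = (rc + sc) / ntot[:, None]
    for key, a in a_by.items():
        u = ((a * (s[:, None] * rc - r[:, None] * sc)).sum(axis=1)) / ntot
        var = (r * s / ntot) * ((a**2 * pooled).sum(axis=1) - (a * pooled).sum(axis=1) ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            out["t" + key] = np.where(var > 0, u / np.sqrt(var), np.nan)
    # HWDTT
    cf = rc / r[:, None]
    gf = sc / s[:, None]
    dp = cf[:, 2] - (cf[:, 2] + 0.5 * cf[:, 1]) ** 2
    dq = gf[:, 2] - (gf[:, 2] + 0.5 * gf[:, 1]) ** 2
    phat = (2.0 * (rc[:, 2] + sc[:, 2]) + rc[:, 1] + sc[:, 1]) / (2.0 * ntot)
    v0 = (1.0 / r + 1.0 / s) * phat**2 * (1.0 - phat) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        out["hwdtt"] = np.where(v0 > 0, (dp - dq) / np.sqrt(v0), np.nan)
    # plug-in correlations (general delta-method forms at pooled frequencies,
    # mirroring unmatched.unmatched_correlations)
    p1, p2 = pooled[:, 1], pooled[:, 2]
    pbar = p2 + 0.5 * p1
    e_g = -p1 * pbar + p2 * (1.0 - 2.0 * pbar)
    v_g = p1 * pbar**2 + p2 * (1.0 - 2.0 * pbar) ** 2 - e_g**2
    v0o = p2 - p2**2
    v05o = 0.25 * p1 + p2 - (0.5 * p1 + p2) ** 2
    v1o = (p1 + p2) - (p1 + p2) ** 2
    cov_g0 = p2 * (1.0 - 2.0 * pbar) - e_g * p2
    cov_g1 = -p1 * pbar + p2 * (1.0 - 2.0 * pbar) - e_g * (p1 + p2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rho0"] = cov_g0 / np.sqrt(v_g * v0o)
        out["rho1"] = cov_g1 / np.sqrt(v_g * v1o)
        out["rho0_05"] = (p2 - 0.5 * p1 * p2 - p2**2) / np.sqrt(v0o * v05o)
        out["rho1_05"] = (0.5 * p1 + p2 - 0.5 * p1**2 - 1.5 * p1 * p2 - p2**2) / np.sqrt(v1o * v05o)
        out["rho0_1"] = (p2 * (1.0 - p1 - p2)) / np.sqrt(v0o * v1o)
    return out


def unmatched_pvalues_batch(stats: Mapping[str, np.ndarray], c: float, tests: Iterable[str]) -> dict:
    pv: dict[str, np.ndarray] = {}
    t0, t05, t1 = stats["t0"], stats["t05"], stats["t1"]
    for name, z in (("catt0", t0), ("catt05", t05), ("catt1", t1)):
        if name in tests:
            pv[name] = 2.0 * norm.sf(np.abs(z))
    if "gms" in tests:
        stat = _two_stage_statistic_batch(t05, stats["hwdtt"], t0, t1, c)
        pv["gms"] = _two_stage_pvalue_batch(
            np.abs(stat), c, stats["rho0_05"], stats["rho0"], stats["rho1_05"], stats["rho1"]
        )
    if "gme" in tests:
        d0 = 1.0 + stats["rho0_05"]
        d1 = 1.0 + stats["rho1_05"]
        a0 = (t0 + t05) / np.sqrt(2.0 * d0)
        a1 = (t1 + t05) / np.sqrt(2.0 * d1)
        stat = _two_stage_statistic_batch(t05, stats["hwdtt"], a0, a1, c)
        pv["gme"] = _two_stage_pvalue_batch(
            np.abs(stat), c,
            np.sqrt(d0 / 2.0), stats["rho0"] / np.sqrt(2.0 * d0),
            np.sqrt(d1 / 2.0), stats["rho1"] / np.sqrt(2.0 * d1),
        )
    return pv


def _rate_result(pv: Mapping[str, np.ndarray], scenario: SimulationScenario, meta: dict) -> ExperimentResult:
    rates, se, errors = {}, {}, {}
    for name, p in pv.items():
        bad = ~np.isfinite(p)
        errors[name] = int(bad.sum())
        ok = p[~bad]
        rate = float(np.mean(ok < scenario.alpha)) if ok.size else float("nan")
        rates[name] = rate
        se[name] = float(np.sqrt(rate * (1.0 - rate) / max(ok.size, 1)))
    return ExperimentResult(rates, se, scenario.n_reps, scenario.seed, errors, meta)


def rejection_rate(scenario: SimulationScenario, tests: Sequence[str] | None = None) -> ExperimentResult:
    """Empirical rejection fraction at ``scenario.alpha`` per test.

    Matched tests (mtt0/mtt05/mtt1/sgms/sgme/max3/chi2df2) or, when
    ``scenario.s`` is set, unmatched tests (catt*/gms/gme) on the pooled
    table.  Replicates with degenerate statistics are counted in ``errors``
    and excluded from the rate, never silently dropped.
    """
    rng = np.random.default_rng(scenario.seed)
    if scenario.s is None:
        tests = tuple(tests) if tests else MATCHED_TESTS
        unknown = set(tests) - set(MATCHED_TESTS)
        if unknown:
            raise ValueError(f"unknown matched tests: {sorted(unknown)}")
        counts = _matched_batch_counts(scenario.population, scenario.r, scenario.m, scenario.n_reps, rng)
        stats = _matched_batch_stats(counts, scenario.m)
        pv = matched_pvalues_batch(stats, scenario.c, tests)
        meta = {"design": "matched", "tests": tests}
    else:
        tests = tuple(tests) if tests else UNMATCHED_TESTS
        unknown = set(tests) - set(UNMATCHED_TESTS)
        if unknown:
            raise ValueError(f"unknown unmatched tests: {sorted(unknown)}")
        stats = _unmatched_batch_stats(scenario, rng)
        pv = unmatched_pvalues_batch(stats, scenario.c, tests)
        meta = {"design": "unmatched-pooled", "tests": tests}
    meta.update(alpha=scenario.alpha, c=scenario.c)
    return _rate_result(pv, scenario, meta)


def selection_exclusion_probs(scenario: SimulationScenario, model: str | None = None) -> ExperimentResult:
    """P(correct model selection) and P(correct exclusion of the most unlikely model).

    Selection is correct when the SMRT classification matches the true model's
    branch; exclusion is correct when the true model's opposite extreme is
    ruled out (Z_SMRT does not cross the wrong threshold).  Under ADD the two
    coincide.
    """
    model = (model or scenario.population.model_label() or "").upper()
    if model not in _MODEL_X:
        raise ValueError("a true model (REC, ADD or DOM) must be stated")
    rng = np.random.default_rng(scenario.seed)
    pop = scenario.population
    n = scenario.n_reps
    m = scenario.m
    # SMRT needs only the genotype-count marginals
    r_il = np.zeros((n, pop.L, 3))
    s_il = np.zeros((n, pop.L, 3))
    for l in range(pop.L):
        case_p, ctrl_p = genotype_distributions(pop, l)
        r_il[:, l, :] = rng.multinomial(scenario.r[l], case_p, size=n)
        s_il[:, l, :] = rng.multinomial(m * scenario.r[l], ctrl_p, size=n)
    rl = np.asarray(scenario.r, float)
    case_f = r_il / rl[None, :, None]
    ctrl_f = s_il / (m * rl[None, :, None])
    d_case = case_f[..., 2] - (case_f[..., 2] + 0.5 * case_f[..., 1]) ** 2
    d_ctrl = ctrl_f[..., 2] - (ctrl_f[..., 2] + 0.5 * ctrl_f[..., 1]) ** 2
    phat = (2.0 * (r_il[..., 2] + s_il[..., 2]) + r_il[..., 1] + s_il[..., 1]) / (2.0 * (m + 1) * rl)
    lam = (m + 1) * (1.0 - phat) ** 2 * phat**2 / (rl * m)
    z = (d_case - d_ctrl).sum(axis=1) / np.sqrt(lam.sum(axis=1))
    c = scenario.c
    if model == "REC":
        sel = z > c
        exc = z >= -c          # DOM ruled out
    elif model == "DOM":
        sel = z < -c
        exc = z <= c           # REC ruled out
    else:
        sel = np.abs(z) <= c
        exc = sel
    rates = {
        "selection": float(np.mean(sel)),
        "exclusion": float(np.mean(exc)),
        "p_rec_branch": float(np.mean(z > c)),
        "p_add_branch": float(np.mean(np.abs(z) <= c)),
        "p_dom_branch": float(np.mean(z < -c)),
    }
    se = {k: float(np.sqrt(v * (1.0 - v) / n)) for k, v in rates.items()}
    return ExperimentResult(rates, se, n, scenario.seed, meta={"model": model, "c": c})


def calibrate_grr(
    scenario: SimulationScenario,
    target_test: str,
    target_power: float,
    bracket: tuple[float, float] = (1.0, 4.0),
    tol: float = 0.01,
    max_iter: int = 30,
) -> tuple[float, float, list[tuple[float, float]]]:
    """Bisect the common GRR lambda2 until ``target_test`` has the target power.

    The population must carry a model index ``x_model``; lambda2 is common
    across strata and lambda1 follows the model family.  Uses common random
    numbers (same seed per evaluation), which makes the simulated power
    monotone in lambda2 along the calibration trace.  Returns
    (lambda2, achieved power, trace of (lambda2, power) pairs).
    """
    pop = scenario.population
    if pop.x_model is None:
        raise ValueError("calibrate_grr needs a population built from a model family (x_model)")

    def power_at(lam2: float) -> float:
        newpop = PopulationModel.from_grr(pop.p, pop.k, lam2, pop.x_model)
        sc = replace(scenario, population=newpop)
        res = rejection_rate(sc, tests=(target_test,))
        return res.rates[target_test]

    lo, hi = bracket
    trace: list[tuple[float, float]] = []
    p_lo = power_at(lo)
    trace.append((lo, p_lo))
    if abs(p_lo - target_power) <= tol:
        return lo, p_lo, trace
    p_hi = power_at(hi)
    trace.append((hi, p_hi))
    if not (p_lo < target_power < p_hi):
        raise ValueError(
            f"bracket {bracket} does not straddle target power {target_power} "
            f"(power {p_lo:.3f} .. {p_hi:.3f})"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p_mid = power_at(mid)
        trace.append((mid, p_mid))
        if abs(p_mid - target_power) <= tol:
            return mid, p_mid, trace
        if p_mid < target_power:
            lo = mid
        else:
            hi = mid
    return mid, p_mid, trace
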