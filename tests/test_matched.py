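"""Matched-data component tests against numeric-likelihood and MC oracles."""

import numpy as np
import pytest
from scipy.stats import norm

import matchtrend as mt
from matchtrend.matched import DegenerateStatisticError, mtt_components
from matchtrend.simulate import _matched_batch_counts, _matched_batch_stats
from .conftest import make_random_study

# ---------------------------------------------------------------------------
# independent oracles: numeric differentiation of the conditional likelihoods


def _scores(g, x):
    return np.array([0.0, x, 1.0])[np.asarray(g)]


def _cond_loglik_trend(study, beta, x):
    """Log conditional likelihood with a single linear genotype-score effect."""
    tot = 0.0
    for _, cases, ctrls in study.stratum_arrays():
        cs = beta * _scores(cases, x)
        ks = beta * _scores(ctrls, x)
        for j in range(len(cs)):
            tot += cs[j] - np.logaddexp(cs[j], np.logaddexp.reduce(ks[j]))
    return tot


def _numeric_score_test_trend(study, x, h=3e-4):
    f = lambda b: _cond_loglik_trend(study, b, x)  # noqa: E731
    score = (f(h) - f(-h)) / (2 * h)
    info = -(f(h) - 2 * f(0.0) + f(-h)) / h**2
    return score / np.sqrt(info)


_W = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0]])


def _cond_loglik_2df(study, beta):
    tot = 0.0
    for _, cases, ctrls in study.stratum_arrays():
        cs = _W[cases] @ beta
        ks = _W[ctrls] @ beta
        for j in range(len(cs)):
            tot += cs[j] - np.logaddexp(cs[j], np.logaddexp.reduce(ks[j]))
    return tot


def _numeric_score_test_2df(study, h=3e-4):
    def grad(b):
        g = np.zeros(2)
        for i in range(2):
            e = np.zeros(2)
            e[i] = h
            g[i] = (_cond_loglik_2df(study, b + e) - _cond_loglik_2df(study, b - e)) / (2 * h)
        return g

    score = grad(np.zeros(2))
    H = np.zeros((2, 2))
    for i in range(2):
        e = np.zeros(2)
        e[i] = h
        H[:, i] = -(grad(e) - grad(-e)) / (2 * h)
    return float(score @ np.linalg.pinv(H) @ score)


# ---------------------------------------------------------------------------


class TestMtt:
    def test_single_set_arithmetic(self):
        # case DD vs control dd with dominant scores: U = 1, V = 2*1 - 1 = 1
        study = mt.MatchedStudy((mt.MatchedSet("A", 2, (0,)),))
        u, v = mtt_components(study, 1.0)
        assert (u, v) == (1.0, 1.0)
        assert mt.mtt(study, 1.0).z == 1.0

    @pytest.mark.parametrize("x", [0.0, 0.5, 1.0])
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_numeric_conditional_score(self, x, seed):
        study = make_random_study(np.random.default_rng(seed), n_sets=30, m=2)
        assert mt.mtt(study, x).z == pytest.approx(_numeric_score_test_trend(study, x), abs=1e-6)

    def test_degenerate_raises(self):
        study = mt.MatchedStudy((mt.MatchedSet("A", 1, (1,)),) * 4)
        with pytest.raises(DegenerateStatisticError):
            mt.mtt(study, 0.5)

    def test_pvalue_identities(self):
        assert mt.mtt_pvalue(0.0) == 1.0
        assert mt.mtt_pvalue(1.959964) == pytest.approx(0.05, abs=1e-6)

    def test_allele_flip_antisymmetry(self, random_study):
        flip = random_study.flipped()
        assert mt.mtt(flip, 0.0).z == pytest.approx(-mt.mtt(random_study, 1.0).z, abs=1e-12)
        assert mt.mtt(flip, 0.5).z == pytest.approx(-mt.mtt(random_study, 0.5).z, abs=1e-12)
        assert mt.mtt(flip, 1.0).z == pytest.approx(-mt.mtt(random_study, 0.0).z, abs=1e-12)


class TestChi2:
    @pytest.mark.parametrize("seed", [4, 5])
    def test_matches_numeric_score_test(self, seed):
        study = make_random_study(np.random.default_rng(seed), n_sets=30, m=2)
        assert mt.chi2_2df(study).statistic == pytest.approx(_numeric_score_test_2df(study), abs=1e-5)

    def test_no_within_set_contrast(self):
        sets = tuple(mt.MatchedSet("A", g, (g,)) for g in (0, 1, 2, 1))
        res = mt.chi2_2df(mt.MatchedStudy(sets))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_flip_invariance(self, random_study):
        a = mt.chi2_2df(random_study)
        b = mt.chi2_2df(random_study.flipped())
        assert a.p_value == pytest.approx(b.p_value, abs=1e-9)


class TestCorrelations:
    def test_structural_constraints(self, random_study):
        c = mt.estimate_correlations(random_study)
        assert c.rho05 == 0.0
        assert c.rho0 >= 0.0 and c.rho1 <= 0.0
        for v in (c.rho0, c.rho1, c.rho0_05, c.rho1_05, c.rho0_1):
            assert -1.0 <= v <= 1.0

    def test_matches_empirical_null_correlations(self):
        # three-stratum matched null; plug-ins vs 5,000-replicate empirical
        pop = mt.PopulationModel.null((0.1, 0.3, 0.5), (0.01, 0.05, 0.02))
        rng = np.random.default_rng(11)
        counts = _matched_batch_counts(pop, (150, 150, 200), 2, 5000, rng)
        stats = _matched_batch_stats(counts, 2)
        emp = {
            "rho0": np.corrcoef(stats["smrt"], stats["z0"])[0, 1],
            "rho1": np.corrcoef(stats["smrt"], stats["z1"])[0, 1],
            "rho05": np.corrcoef(stats["smrt"], stats["z05"])[0, 1],
            "rho0_05": np.corrcoef(stats["z0"], stats["z05"])[0, 1],
            "rho1_05": np.corrcoef(stats["z1"], stats["z05"])[0, 1],
            "rho0_1": np.corrcoef(stats["z0"], stats["z1"])[0, 1],
        }
        for key in emp:
            plug = np.mean(stats[key]) if key != "rho05" else 0.0
            assert emp[key] == pytest.approx(plug, abs=0.02), key

    def test_rho_star_model_map(self, access):
        c = mt.estimate_correlations(access)
        assert c.rho_star("REC") == min(c.rho0_05, c.rho0_1)
        assert c.rho_star("ADD") == min(c.rho0_05, c.rho1_05)
        assert c.rho_star("DOM") == min(c.rho1_05, c.rho0_1)


class TestMat:
    def test_definition(self, random_study):
        c = mt.estimate_correlations(random_study)
        z0 = mt.mtt(random_study, 0.0).z
        z05 = mt.mtt(random_study, 0.5).z
        expected = (z0 + z05) / np.sqrt(2 * (1 + c.rho0_05))
        assert mt.mat(random_study, 0) == pytest.approx(expected, abs=1e-12)

    def test_null_variance_near_one(self):
        pop = mt.PopulationModel.null((0.1, 0.3, 0.5), (0.01, 0.05, 0.02))
        rng = np.random.default_rng(13)
        counts = _matched_batch_counts(pop, (150, 150, 200), 2, 5000, rng)
        stats = _matched_batch_stats(counts, 2)
        zmat0 = (stats["z0"] + stats["z05"]) / np.sqrt(2 * (1 + stats["rho0_05"]))
        assert abs(np.mean(zmat0)) < 0.05
        assert np.var(zmat0) == pytest.approx(1.0, abs=0.05)


class TestMax3:
    def test_statistic_is_max_abs(self, random_study):
        res = mt.max3(random_study)
        zs = [abs(mt.mtt(random_study, x).z) for x in (0.0, 0.5, 1.0)]
        assert res.statistic == pytest.approx(max(zs), abs=1e-12)

    def test_pvalue_matches_monte_carlo(self, access):
        res = mt.max3(access)
        R = mt.estimate_correlations(access).mtt_corr_matrix()
        w, V = np.linalg.eigh(R)
        L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
        rng = np.random.default_rng(17)
        Z = rng.normal(size=(1_000_000, 3)) @ L.T
        mc = np.mean(np.max(np.abs(Z), axis=1) > res.statistic)
        assert res.p_value == pytest.approx(mc, abs=3 * np.sqrt(mc * (1 - mc) / 1e6))

    def test_flip_invariance(self, random_study):
        a = mt.max3(random_study)
        b = mt.max3(random_study.flipped())
        assert a.p_value == pytest.approx(b.p_value, abs=1e-8)
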