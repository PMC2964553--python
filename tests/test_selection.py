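"""Model classification, SMRT, and the two-stage SGMS/SGME tests."""

import numpy as np
import pytest
from scipy.stats import norm

import matchtrend as mt
from matchtrend.selection import DEFAULT_THRESHOLD, two_stage_pvalue


def _branch_correlations(corr: mt.CorrelationEstimates, averaged: bool):
    """Correlations of (Z05, S) with the branch statistics A0 and A1.

    For the exclusion variants the branch statistics are the averaged tests,
    whose correlations follow from the averaging transform.
    """
    if not averaged:
        return corr.rho0_05, corr.rho0, corr.rho1_05, corr.rho1
    d0 = 1.0 + corr.rho0_05
    d1 = 1.0 + corr.rho1_05
    return (
        np.sqrt(d0 / 2.0), corr.rho0 / np.sqrt(2.0 * d0),
        np.sqrt(d1 / 2.0), corr.rho1 / np.sqrt(2.0 * d1),
    )


def _mc_two_stage_pvalue(t, c, corr, averaged, n, seed):
    """MC frequency of the two-stage rejection event under the asymptotic law.

    Draws (Z05, S, A0, A1) from the joint normal with the same correlations
    the analytic p-value integrates over.  The rejection event involves only
    one of A0/A1 at a time, so corr(A0, A1) is immaterial; it is set to the
    value that makes A0 and A1 conditionally independent given (Z05, S),
    which keeps the four-variable law positive semi-definite whenever each
    branch triple is.
    """
    r05a0, rsa0, r05a1, rsa1 = _branch_correlations(corr, averaged)
    ra0a1 = r05a0 * r05a1 + rsa0 * rsa1
    R = np.array(
        [
            [1.0, 0.0, r05a0, r05a1],
            [0.0, 1.0, rsa0, rsa1],
            [r05a0, rsa0, 1.0, ra0a1],
            [r05a1, rsa1, ra0a1, 1.0],
        ]
    )
    w, V = np.linalg.eigh(R)
    L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    rng = np.random.default_rng(seed)
    z05, s, a0, a1 = (rng.normal(size=(n, 4)) @ L.T).T
    stat = np.where(
        s > c,
        np.where(z05 > 0, a0, -a1),
        np.where(s < -c, np.where(z05 > 0, a1, -a0), np.abs(z05)),
    )
    return np.mean(np.abs(stat) > t)


class TestHwdDelta:
    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5, 0.9])
    def test_hwe_gives_zero(self, p):
        q = 1 - p
        assert mt.hwd_delta((q**2, 2 * p * q, p**2)).delta == pytest.approx(0.0, abs=1e-12)

    def test_extremes(self):
        assert mt.hwd_delta((0.0, 0.0, 1.0)).delta == 0.0
        assert mt.hwd_delta((0.5, 0.0, 0.5)).delta == 0.25

    def test_allele_relabel_invariance(self):
        f = (0.2, 0.5, 0.3)
        assert mt.hwd_delta(f).delta == pytest.approx(mt.hwd_delta(f[::-1]).delta, abs=1e-12)

    def test_non_normalised_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            mt.hwd_delta((0.5, 0.5, 0.5))


class TestSmrt:
    def test_identical_frequencies_give_zero(self):
        # every set pairs a case and control of the same genotype mix
        sets = []
        for g in (0, 0, 1, 1, 2, 2):
            sets.append(mt.MatchedSet("A", g, (g,)))
        assert mt.smrt(mt.MatchedStudy(tuple(sets))) == pytest.approx(0.0, abs=1e-12)

    def test_allele_relabel_invariance(self, random_study):
        assert mt.smrt(random_study) == pytest.approx(mt.smrt(random_study.flipped()), abs=1e-12)

    def test_null_calibration(self):
        pop = mt.PopulationModel.null((0.1, 0.3, 0.5), (0.01, 0.05, 0.02))
        from matchtrend.simulate import _matched_batch_counts, _matched_batch_stats

        counts = _matched_batch_counts(pop, (150, 150, 200), 2, 10_000, np.random.default_rng(5))
        z = _matched_batch_stats(counts, 2)["smrt"]
        assert abs(np.mean(z)) < 0.05
        assert np.var(z) == pytest.approx(1.0, abs=0.05)

    def test_directional_mean_under_extreme_models(self):
        # REC inflates case HWD relative to controls; DOM deflates it
        from matchtrend.simulate import _matched_batch_counts, _matched_batch_stats

        for x, sign in ((0.0, 1), (1.0, -1)):
            pop = mt.PopulationModel.from_baseline_penetrance(
                (0.1, 0.3, 0.5), (0.01, 0.05, 0.02), 1.8, x
            )
            counts = _matched_batch_counts(pop, (90, 90, 120), 2, 2000, np.random.default_rng(6))
            z = _matched_batch_stats(counts, 2)["smrt"]
            assert sign * np.mean(z) > 0.5


class TestClassifyModel:
    def test_branches_and_boundary(self):
        c = DEFAULT_THRESHOLD
        assert mt.classify_model(0.124, c).label == "ADD"
        assert mt.classify_model(c, c).label == "ADD"  # boundary joins the middle
        d = mt.classify_model(-2.0, c)
        assert d.label == "DOM-side" and d.excluded == ("REC",)
        assert mt.classify_model(2.0, c).excluded == ("DOM",)
        assert mt.classify_model(0.0, c).excluded == ("REC", "DOM")


class TestBranchOrthant:
    def test_independent_octant_limit(self):
        p = mt.branch_orthant(0.0, 1e-9, np.eye(3), (+1, +1))
        assert p == pytest.approx(1.0 / 8.0, abs=1e-6)

    def test_monotone_in_t_and_c(self):
        R = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 0.4], [0.5, 0.4, 1.0]])
        ps = [mt.branch_orthant(t, 1.0, R, (+1, +1)) for t in (0.0, 0.5, 1.0, 2.0)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        pc = [mt.branch_orthant(1.0, c, R, (+1, +1)) for c in (0.5, 1.0, 2.0)]
        assert all(a >= b for a, b in zip(pc, pc[1:]))


class TestTwoStagePvalues:
    def test_middle_branch_limit(self, access):
        # with an effectively infinite threshold the test reduces to Z_MTT(0.5)
        z05 = mt.mtt(access, 0.5).z
        expected = 2 * norm.sf(abs(z05))
        assert mt.sgms(access, c=10.0).p_value == pytest.approx(expected, abs=1e-6)
        assert mt.sgme(access, c=10.0).p_value == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("seed", [8, 9])
    @pytest.mark.parametrize("averaged", [False, True], ids=["sgms", "sgme"])
    def test_two_stage_pvalues_match_mc_event_oracle(self, seed, averaged):
        # HWE-compatible data: the plug-in correlations then define a proper
        # joint law (the oracle's sampling model matches the integrand's)
        pop = mt.PopulationModel.null((0.2, 0.4), (0.02, 0.05))
        study = mt.simulate_matched(mt.SimulationScenario(pop, r=(150, 150), m=2, seed=seed))
        res = (mt.sgme if averaged else mt.sgms)(study)
        mc = _mc_two_stage_pvalue(
            abs(res.statistic), DEFAULT_THRESHOLD, res.correlations, averaged, 1_000_000, seed
        )
        assert res.p_value == pytest.approx(mc, abs=3 * np.sqrt(mc * (1 - mc) / 1e6))

    def test_flip_invariance(self, random_study):
        for fn in (mt.sgms, mt.sgme):
            a = fn(random_study)
            b = fn(random_study.flipped())
            assert a.p_value == pytest.approx(b.p_value, abs=1e-8)
            assert abs(a.statistic) == pytest.approx(abs(b.statistic), abs=1e-9)

    def test_pvalue_monotone_in_t(self):
        ps = [two_stage_pvalue(t, DEFAULT_THRESHOLD, 0.6, 0.64, 0.92, -0.33) for t in (0.5, 1.0, 2.0, 3.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
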