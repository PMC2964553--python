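"""Population model, samplers, and simulation experiments."""

import dataclasses

import numpy as np
import pytest

import matchtrend as mt
from matchtrend.simulate import genotype_distributions, penetrances


class TestPenetrances:
    def test_null_model(self):
        f = penetrances(0.05, 0.3, 1.0, 1.0)
        assert f == pytest.approx((0.05, 0.05, 0.05))

    @pytest.mark.parametrize("seed", range(5))
    def test_prevalence_identity(self, seed):
        rng = np.random.default_rng(seed)
        k, p = rng.uniform(0.01, 0.2), rng.uniform(0.05, 0.95)
        l2 = rng.uniform(1.0, 3.0)
        l1 = 1 + 0.5 * (l2 - 1)
        f0, f1, f2 = penetrances(k, p, l1, l2)
        q = 1 - p
        assert f0 * q**2 + f1 * 2 * p * q + f2 * p**2 == pytest.approx(k, abs=1e-12)

    def test_recessive_has_equal_low_penetrances(self):
        f0, f1, f2 = penetrances(0.05, 0.3, 1.0, 2.5)  # REC: lambda1 = 1
        assert f1 == f0

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            penetrances(0.5, 0.05, 1.0, 50.0)


class TestGenotypeDistributions:
    def test_null_equals_hwe(self):
        pop = mt.PopulationModel.null((0.5,), (0.1,))
        case, ctrl = genotype_distributions(pop, 0)
        assert case == pytest.approx([0.25, 0.5, 0.25])
        assert ctrl == pytest.approx([0.25, 0.5, 0.25])

    def test_matches_bayes_enumeration(self):
        # brute-force Bayes on the three-genotype sample space, DOM lambda2 = 2
        p, k, l2 = 0.3, 0.05, 2.0
        pop = mt.PopulationModel.from_grr((p,), (k,), l2, x_model=1.0)
        q = 1 - p
        g = np.array([q**2, 2 * p * q, p**2])
        f = np.array(penetrances(k, p, l2, l2))
        case_ref = f * g / (f * g).sum()
        ctrl_ref = (1 - f) * g / ((1 - f) * g).sum()
        case, ctrl = genotype_distributions(pop, 0)
        assert case == pytest.approx(case_ref, abs=1e-12)
        assert ctrl == pytest.approx(ctrl_ref, abs=1e-12)

    def test_under_recessive_and_over_dominant_supported(self):
        for x in (-0.25, 1.25):
            pop = mt.PopulationModel.from_grr((0.3,), (0.05,), 1.5, x_model=x)
            case, ctrl = genotype_distributions(pop, 0)
            assert case.sum() == pytest.approx(1.0)


class TestSamplers:
    def test_matched_sampler_shape_and_determinism(self):
        pop = mt.PopulationModel.null((0.1, 0.3, 0.5), (0.01, 0.05, 0.02))
        sc = mt.SimulationScenario(pop, r=(15, 15, 20), m=2, seed=3)
        a = mt.simulate_matched(sc)
        b = mt.simulate_matched(sc)
        assert a == b
        assert a.n_cases == 50 and a.m == 2 and len(a.strata) == 3
        sums = mt.stratum_summaries(a)
        assert [s.r_l for s in sums] == [15, 15, 20]

    def test_matched_sampler_frequencies(self):
        pop = mt.PopulationModel.from_grr((0.3,), (0.05,), 2.0, x_model=0.5)
        sc = mt.SimulationScenario(pop, r=(20_000,), m=1, seed=4)
        study = mt.simulate_matched(sc)
        (s,) = mt.stratum_summaries(study)
        case_p, ctrl_p = genotype_distributions(pop, 0)
        se = np.sqrt(case_p * (1 - case_p) / 20_000)
        assert np.all(np.abs(s.case_freqs - case_p) < 4 * se + 1e-9)
        assert np.all(np.abs(s.control_freqs - ctrl_p) < 4 * se + 1e-9)

    def test_unmatched_pooled_mixture(self):
        pop = mt.PopulationModel.null((0.2, 0.4), (0.03, 0.07))
        sc = mt.SimulationScenario(pop, r=(30_000, 10_000), s=(10_000, 30_000), seed=5)
        tab = mt.simulate_unmatched_pooled(sc)
        assert tab.r == 40_000 and tab.s == 40_000
        mix = 0.75 * np.array(genotype_distributions(pop, 0)[0]) + 0.25 * np.array(
            genotype_distributions(pop, 1)[0]
        )
        assert np.all(np.abs(tab.case_counts / tab.r - mix) < 0.01)


class TestRejectionRate:
    def test_alpha_near_one_rejects_almost_everything(self):
        # ties at p = 1 (U exactly 0) escape a strict p < alpha cut
        pop = mt.PopulationModel.null((0.3,), (0.05,))
        sc = mt.SimulationScenario(pop, r=(50,), m=1, n_reps=50, alpha=0.999999, seed=6)
        res = mt.rejection_rate(sc, tests=("mtt05",))
        assert res.rates["mtt05"] >= 0.9

    def test_seed_determinism(self):
        pop = mt.PopulationModel.null((0.3,), (0.05,))
        sc = mt.SimulationScenario(pop, r=(100,), m=1, n_reps=200, seed=7)
        a = mt.rejection_rate(sc, tests=("mtt05", "sgms"))
        b = mt.rejection_rate(sc, tests=("mtt05", "sgms"))
        assert a.rates == b.rates

    def test_nested_alpha_levels(self):
        pop = mt.PopulationModel.null((0.3, 0.2), (0.05, 0.03))
        base = mt.SimulationScenario(pop, r=(100, 100), m=1, n_reps=500, seed=8)
        r05 = mt.rejection_rate(base, tests=("mtt05", "max3"))
        r01 = mt.rejection_rate(dataclasses.replace(base, alpha=0.01), tests=("mtt05", "max3"))
        for name in ("mtt05", "max3"):
            assert r01.rates[name] <= r05.rates[name]


class TestSelectionExclusion:
    def test_null_branch_probabilities(self):
        pop = mt.PopulationModel.from_grr((0.1, 0.3, 0.5), (0.01, 0.05, 0.02), 1.0, x_model=0.5)
        sc = mt.SimulationScenario(pop, r=(90, 90, 120), m=2, n_reps=10_000, seed=9)
        res = mt.selection_exclusion_probs(sc, model="ADD")
        band = 3 * np.sqrt(0.05 * 0.95 / 10_000)
        assert res.rates["p_rec_branch"] == pytest.approx(0.05, abs=band)
        assert res.rates["p_dom_branch"] == pytest.approx(0.05, abs=band)
        assert res.rates["p_add_branch"] == pytest.approx(0.90, abs=3 * np.sqrt(0.9 * 0.1 / 10_000))

    def test_add_selection_equals_exclusion(self):
        pop = mt.PopulationModel.from_grr((0.1, 0.3, 0.5), (0.01, 0.05, 0.02), 1.5, x_model=0.5)
        sc = mt.SimulationScenario(pop, r=(90, 90, 120), m=2, n_reps=2000, seed=10)
        res = mt.selection_exclusion_probs(sc)
        assert res.rates["selection"] == res.rates["exclusion"]


class TestCalibrateGrr:
    def test_null_bracket_end_returns_one(self):
        pop = mt.PopulationModel.from_grr((0.3,), (0.05,), 1.0, x_model=0.5)
        sc = mt.SimulationScenario(pop, r=(100,), m=1, n_reps=1000, alpha=0.05, seed=11)
        lam2, power, trace = mt.calibrate_grr(sc, "mtt05", target_power=0.05, tol=0.02)
        assert lam2 == 1.0
        assert power == pytest.approx(0.05, abs=0.02)

    def test_power_monotone_on_trace(self):
        pop = mt.PopulationModel.from_grr((0.1, 0.3, 0.5), (0.01, 0.05, 0.02), 1.5, x_model=0.5)
        sc = mt.SimulationScenario(pop, r=(150, 150, 200), m=2, n_reps=1000, seed=12)
        lam2, power, trace = mt.calibrate_grr(sc, "mtt05", target_power=0.8, tol=0.02)
        assert abs(power - 0.8) <= 0.02
        trace_sorted = sorted(trace)
        powers = [p for _, p in trace_sorted]
        assert all(a <= b + 1e-12 for a, b in zip(powers, powers[1:]))
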