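import numpy as np
import pytest

from epibench.disease import (
    DiseaseScenario,
    enumerate_scenarios,
    epistasis_matrix,
    logit_to_penetrance,
    penetrance_to_logit,
    relative_risk_table,
    select_causal_pair,
    solve_penetrance,
    two_locus_genotype_freqs,
)
from epibench.panel import LocusInfo
from epibench.resample import SimulatedPopulation, ld_r2


class TestEpistasisMatrix:
    def test_null_model_all_ones(self):
        assert np.array_equal(epistasis_matrix("M0"), np.ones((3, 3)))

    def test_dominant_dominant(self):
        expected = np.array([[1, 1, 1], [1, 2, 2], [1, 2, 2]])
        assert np.array_equal(epistasis_matrix("M1", 2), expected)

    def test_recessive_recessive(self):
        assert epistasis_matrix("M2", 5)[2, 2] == 5
        assert epistasis_matrix("M2", 5).sum() == 8 + 5

    def test_multiplicative(self):
        expected = np.array([[1, 1, 1], [1, 3, 9], [1, 9, 81]])
        assert np.array_equal(epistasis_matrix("M3", 3), expected)

    def test_multiplicative_power_structure(self):
        rho = 2.5
        m = epistasis_matrix("M3", rho)
        i, j = np.meshgrid(range(3), range(3), indexing="ij")
        assert np.allclose(m, rho ** (i * j))

    def test_alternative_model(self):
        r = 4.0
        expected = np.array([[1, 1, 1], [1, 1, r], [r, r, r]])
        assert np.array_equal(epistasis_matrix("M4", r), expected)

    def test_dominant_models_symmetric(self):
        for model in ("M0", "M1", "M2", "M3"):
            m = epistasis_matrix(model, 3)
            assert np.array_equal(m, m.T)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            epistasis_matrix("M9", 2)


class TestRelativeRiskTable:
    def test_null_no_main_effect_all_ones(self):
        s = DiseaseScenario(model="M0", rr_a=1, rr_b=1)
        assert np.array_equal(relative_risk_table(s), np.ones((3, 3)))

    def test_dominant_main_effect_rows(self):
        s = DiseaseScenario(model="M0", rr_a=1.5, rr_b=1)
        expected = np.array([[1, 1, 1], [1.5, 1.5, 1.5], [1.5, 1.5, 1.5]])
        assert np.allclose(relative_risk_table(s), expected)

    def test_pure_interaction_equals_epistasis_matrix(self):
        s = DiseaseScenario(model="M1", rho=2, rr_a=1, rr_b=1)
        assert np.allclose(relative_risk_table(s), epistasis_matrix("M1", 2))


class TestTwoLocusFreqs:
    def test_independence_is_outer_product(self):
        fa, fb = 0.2, 0.4
        g = two_locus_genotype_freqs(fa, fb, 0.0)
        ha = np.array([(1 - fa) ** 2, 2 * fa * (1 - fa), fa**2])
        hb = np.array([(1 - fb) ** 2, 2 * fb * (1 - fb), fb**2])
        assert np.allclose(g, np.outer(ha, hb))

    def test_perfect_ld_half_frequency(self):
        g = two_locus_genotype_freqs(0.5, 0.5, 1.0)
        assert g[2, 2] == pytest.approx(0.25)
        assert g[0, 0] == pytest.approx(0.25)
        assert g[1, 1] == pytest.approx(0.5)

    def test_intermediate_ld_closed_form(self):
        g = two_locus_genotype_freqs(0.3, 0.3, 0.2)
        p_ab = 0.09 + np.sqrt(0.2) * 0.21
        assert g[2, 2] == pytest.approx(p_ab**2, rel=1e-12)

    def test_sums_to_one(self):
        g = two_locus_genotype_freqs(0.15, 0.3, 0.1)
        assert g.sum() == pytest.approx(1.0, abs=1e-12)

    def test_infeasible_r2_names_maximum(self):
        with pytest.raises(ValueError, match="maximum r2"):
            two_locus_genotype_freqs(0.05, 0.5, 0.9)


class TestSolvePenetrance:
    def test_null_scenario_constant_prevalence(self):
        s = DiseaseScenario(model="M0", prevalence=0.15)
        g = two_locus_genotype_freqs(0.3, 0.3, 0.0)
        pen = solve_penetrance(s, g)
        assert np.allclose(pen.p, 0.15)

    def test_closed_form_baseline(self):
        # M1 rho=2, f=0.3, r2=0: double-carrier mass (1-0.49)^2 = 0.2601,
        # E[R] = 1.2601, p00 = 0.15/1.2601
        s = DiseaseScenario(model="M1", rho=2, maf_a=0.3, maf_b=0.3)
        g = two_locus_genotype_freqs(0.3, 0.3, 0.0)
        pen = solve_penetrance(s, g)
        assert pen.p00 == pytest.approx(0.15 / 1.2601, rel=1e-10)

    def test_prevalence_recovered(self):
        s = DiseaseScenario(model="M2", rho=5, maf_a=0.3, maf_b=0.3, r2=0.2)
        g = two_locus_genotype_freqs(0.3, 0.3, 0.2)
        pen = solve_penetrance(s, g)
        assert (g * pen.p).sum() == pytest.approx(0.15, abs=1e-12)

    def test_infeasible_scenario_raises(self):
        s = DiseaseScenario(model="M1", rho=10, rr_a=1.5, rr_b=1.5,
                            maf_a=0.15, maf_b=0.15)
        g = two_locus_genotype_freqs(0.15, 0.15, 0.0)
        with pytest.raises(ValueError, match="infeasible"):
            solve_penetrance(s, g)

    def test_risk_ratio_structure_preserved(self):
        s = DiseaseScenario(model="M4", rho=3, rr_a=1.5, rr_b=1.0,
                            maf_a=0.3, maf_b=0.3)
        g = two_locus_genotype_freqs(0.3, 0.3, 0.0)
        pen = solve_penetrance(s, g)
        assert np.allclose(pen.p / pen.p00, relative_risk_table(s), atol=1e-10)


class TestLogitDecomposition:
    def test_constant_table_zero_betas(self):
        from epibench.disease import PenetranceTable

        lp = penetrance_to_logit(PenetranceTable(np.full((3, 3), 0.15)))
        assert lp.alpha == pytest.approx(np.log(0.15 / 0.85))
        assert np.allclose(lp.beta_a, 0) and np.allclose(lp.beta_b, 0)
        assert np.allclose(lp.beta_ab, 0)

    def test_round_trip_identity(self, rng):
        from epibench.disease import PenetranceTable

        p = rng.uniform(0.01, 0.99, size=(3, 3))
        t = PenetranceTable(p)
        back = logit_to_penetrance(penetrance_to_logit(t))
        assert np.allclose(back.p, p, atol=1e-10)

    def test_null_pure_prevalence_interaction_free(self):
        s = DiseaseScenario(model="M0", rr_a=1, rr_b=1)
        g = two_locus_genotype_freqs(0.3, 0.3, 0.0)
        lp = penetrance_to_logit(solve_penetrance(s, g))
        assert np.allclose(lp.beta_ab, 0, atol=1e-12)

    def test_additive_logit_table_has_zero_interaction(self, rng):
        from epibench.disease import LogitParams

        lp = LogitParams(-2.0, rng.normal(size=2), rng.normal(size=2),
                         np.zeros((2, 2)))
        rec = penetrance_to_logit(logit_to_penetrance(lp))
        assert np.allclose(rec.beta_ab, 0, atol=1e-10)

    def test_boundary_penetrance_rejected(self):
        from epibench.disease import PenetranceTable

        p = np.full((3, 3), 0.5)
        p[2, 2] = 1.0
        with pytest.raises(ValueError):
            penetrance_to_logit(PenetranceTable(p))


def _toy_population(rng, n_loci=20, m=100, n_chrom=2):
    g = rng.integers(0, 3, size=(m, n_loci)).astype(np.int8)
    per = n_loci // n_chrom
    loci = [
        LocusInfo(f"s{j}", 1 + j // per, 10_000 * (j % per + 1))
        for j in range(n_loci)
    ]
    return SimulatedPopulation(g, loci, seed=0)


class TestSelectCausalPair:
    def test_matches_brute_force(self, rng):
        pop = _toy_population(rng)
        s = DiseaseScenario(model="M1", rho=2, maf_a=0.3, maf_b=0.3, r2=0.0)
        a, b, fa, fb, r2 = select_causal_pair(pop, s)
        # brute force over all admissible ordered pairs
        maf = pop.maf()
        chrom = np.array([l.chromosome for l in pop.loci])
        best, best_obj = None, np.inf
        n = pop.n_loci
        for x in range(n):
            for y in range(n):
                if x == y or chrom[x] == chrom[y]:
                    continue
                r2_hat = ld_r2(pop.genotypes[:, x], pop.genotypes[:, y])
                obj = (maf[x] - 0.3) ** 2 + (maf[y] - 0.3) ** 2 + r2_hat**2
                if obj < best_obj:
                    best, best_obj = (x, y), obj
        assert {a, b} == set(best)

    def test_zero_ld_target_uses_cross_chromosome_pairs(self, rng):
        pop = _toy_population(rng)
        s = DiseaseScenario(model="M1", rho=2, r2=0.0)
        a, b, *_ = select_causal_pair(pop, s)
        assert pop.loci[a].chromosome != pop.loci[b].chromosome

    def test_positive_ld_target_stays_within_chromosome(self, rng):
        pop = _toy_population(rng)
        s = DiseaseScenario(model="M1", rho=2, r2=0.2)
        a, b, *_ = select_causal_pair(pop, s)
        assert pop.loci[a].chromosome == pop.loci[b].chromosome

    def test_exact_match_returned(self, rng):
        pop = _toy_population(rng, n_loci=10, m=200)
        # plant a cross-chromosome pair with exact MAF targets and r2 ~ 0
        target = np.array([0] * 140 + [1] * 40 + [2] * 20, dtype=np.int8)
        pop.genotypes[:, 0] = target
        pop.genotypes[:, 9] = np.roll(target, 97)
        fa = pop.maf()[0]
        s = DiseaseScenario(model="M1", rho=2, maf_a=fa, maf_b=fa, r2=0.0)
        a, b, *_ = select_causal_pair(pop, s)
        assert {a, b} == {0, 9}


class TestScenarioGrid:
    def test_total_and_per_model_counts(self):
        grid = enumerate_scenarios()
        assert len(grid) == 234
        per = {}
        for s in grid:
            per[s.model] = per.get(s.model, 0) + 1
        assert per == {"M0": 18, "M1": 54, "M2": 54, "M3": 54, "M4": 54}

    def test_m2_uses_extended_rho_grid(self):
        rhos = {s.rho for s in enumerate_scenarios() if s.model == "M2"}
        assert rhos == {2.0, 5.0, 10.0}

    def test_null_model_has_no_rho(self):
        assert all(s.rho is None for s in enumerate_scenarios() if s.model == "M0")
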