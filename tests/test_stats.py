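import numpy as np
import pytest

from epibench.cohort import CaseControlCohort, PairTable
from epibench.stats import (
    METHODS,
    chi2_log_sf,
    dss_score,
    fastepi_score,
    gboost_score,
    indor_score,
    pair_table,
    scan_all_pairs,
    score_pair_table,
    shesisepi_score,
)

from conftest import random_dense_table


def _cohort(genotypes, phenotype):
    return CaseControlCohort(
        np.asarray(genotypes, dtype=np.int8),
        np.asarray(phenotype, dtype=np.int8),
        causal_pair=(0, 1),
        seed=0,
    )


class TestPairTable:
    def test_hand_counted(self):
        cohort = _cohort(
            [[0, 2], [1, 1], [0, 2], [2, 0]],
            [0, 0, 1, 1],
        )
        t = pair_table(cohort, 0, 1)
        expect = np.zeros((2, 3, 3), dtype=int)
        expect[0, 0, 2] = 1
        expect[0, 1, 1] = 1
        expect[1, 0, 2] = 1
        expect[1, 2, 0] = 1
        assert np.array_equal(t.counts, expect)

    def test_swapped_loci_transposes(self, rng):
        g = rng.integers(0, 3, size=(60, 4)).astype(np.int8)
        cohort = _cohort(g, rng.integers(0, 2, size=60))
        t_ab = pair_table(cohort, 1, 3)
        t_ba = pair_table(cohort, 3, 1)
        assert np.array_equal(t_ab.counts, t_ba.counts.transpose(0, 2, 1))

    def test_same_locus_diagonal(self, rng):
        g = rng.integers(0, 3, size=(40, 2)).astype(np.int8)
        cohort = _cohort(g, rng.integers(0, 2, size=40))
        t = pair_table(cohort, 0, 0)
        off = t.counts * (1 - np.eye(3, dtype=int))
        assert off.sum() == 0


class TestChi2LogSf:
    def test_zero_statistic_p_one(self):
        assert chi2_log_sf(0.0, 1) == 0.0
        assert chi2_log_sf(0.0, 4) == 0.0

    def test_standard_quantile(self):
        assert chi2_log_sf(3.841459, 1) == pytest.approx(np.log10(0.05), abs=1e-4)

    def test_even_df_closed_form(self):
        # df=4: sf(x) = exp(-x/2) (1 + x/2)
        x = 20.0
        assert chi2_log_sf(x, 4) == pytest.approx(
            np.log10(np.exp(-x / 2) * (1 + x / 2)), rel=1e-9
        )

    def test_deep_tail_accuracy(self):
        x = 150.0
        exact = np.log10(np.exp(-x / 2) * (1 + x / 2))
        assert chi2_log_sf(x, 4) == pytest.approx(exact, rel=1e-6)

    def test_monotone_in_statistic(self):
        xs = np.linspace(0, 80, 50)
        for df in (1, 4):
            vals = [chi2_log_sf(x, df) for x in xs]
            assert all(b < a for a, b in zip(vals, vals[1:]))


def _proportional_table(rng):
    base = rng.integers(5, 40, size=(3, 3))
    return PairTable(np.stack([base * 2, base * 3]))


class TestFastepi:
    def test_proportional_tables_score_zero(self, rng):
        res = fastepi_score(_proportional_table(rng))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_arithmetic_oracle(self, rng):
        t = random_dense_table(rng)
        res = fastepi_score(t)
        # independent recomputation, scalar arithmetic
        stat_terms = []
        var = 0.0
        lnors = []
        for d in (1, 0):
            T = np.zeros((2, 2))
            for i in range(3):
                for j in range(3):
                    nij = t.counts[d, i, j]
                    for u, cu in ((0, 2 - i), (1, i)):
                        for v, cv in ((0, 2 - j), (1, j)):
                            T[u, v] += nij * cu * cv
            lnors.append(np.log(T[1, 1] * T[0, 0] / (T[1, 0] * T[0, 1])))
            var += (1.0 / T).sum()
        z = (lnors[0] - lnors[1]) / np.sqrt(var)
        assert res.statistic == pytest.approx(z * z, rel=1e-10)

    def test_monomorphic_group_degenerate(self):
        counts = np.zeros((2, 3, 3), dtype=int)
        counts[0, 0, 0] = 50  # controls all (0,0): empty allele cells
        counts[1] = 10
        res = fastepi_score(PairTable(counts))
        assert res.degenerate and res.statistic == 0.0 and res.log10_p == 0.0


class TestShesisepi:
    def test_proportional_tables_score_zero(self, rng):
        res = shesisepi_score(_proportional_table(rng))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_swap_symmetry_equal_arms(self, rng):
        t = random_dense_table(rng, n=1500)
        swapped = PairTable(t.counts[::-1].copy())
        assert shesisepi_score(t).statistic == pytest.approx(
            shesisepi_score(swapped).statistic, rel=1e-12
        )

    def test_matches_expanded_individual_correlation(self, rng):
        t = random_dense_table(rng, n=300)
        res = shesisepi_score(t)
        zs, ns = [], []
        for d in (0, 1):
            ga, gb = [], []
            for i in range(3):
                for j in range(3):
                    ga += [i] * t.counts[d, i, j]
                    gb += [j] * t.counts[d, i, j]
            r = np.corrcoef(ga, gb)[0, 1]
            zs.append(np.arctanh(r))
            ns.append(len(ga))
        stat = (zs[1] - zs[0]) ** 2 / (1 / (ns[1] - 3) + 1 / (ns[0] - 3))
        assert res.statistic == pytest.approx(stat, rel=1e-9)

    def test_monomorphic_group_degenerate(self):
        counts = np.ones((2, 3, 3), dtype=int) * 5
        counts[0] = 0
        counts[0, 1, :] = 10  # SNP a constant (=1) in controls
        res = shesisepi_score(PairTable(counts))
        assert res.degenerate


class TestGboost:
    def test_proportional_tables_score_zero(self, rng):
        res = gboost_score(_proportional_table(rng))
        assert res.statistic == pytest.approx(0.0, abs=1e-6)

    def test_nonnegative_and_df4(self, rng):
        for _ in range(10):
            res = gboost_score(random_dense_table(rng, n=500))
            assert res.statistic >= 0 and res.df == 4

    def test_empty_cells_finite(self, rng):
        counts = rng.integers(0, 4, size=(2, 3, 3))
        counts[0, 2, 2] = 0
        counts[1, 2, 2] = 0
        res = gboost_score(PairTable(counts))
        assert np.isfinite(res.statistic) and res.statistic >= 0

    def test_pure_main_effects_near_null_distribution(self, rng):
        # saturated == main-effects truth: LRT should look chi2_4, i.e.
        # moderate mean, not diverging
        from epibench.stats import _gboost_batch

        probs_a = np.array([0.5, 0.35, 0.15])
        probs_b = np.array([0.4, 0.45, 0.15])
        joint = np.outer(probs_a, probs_b).ravel()
        tables = np.stack(
            [
                np.stack(
                    [
                        rng.multinomial(3000, joint).reshape(3, 3),
                        rng.multinomial(3000, joint).reshape(3, 3),
                    ]
                )
                for _ in range(300)
            ]
        )
        stat, _ = _gboost_batch(tables)
        assert abs(stat.mean() - 4.0) < 1.0  # E[chi2_4] = 4


class TestIndor:
    def test_identical_distributions_zero(self):
        base = np.array([[40, 30, 10], [30, 25, 9], [12, 9, 5]])
        t = PairTable(np.stack([base, base * 2]))
        res = indor_score(t)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert not res.degenerate

    def test_zero_cell_degenerate(self):
        base = np.array([[40, 30, 10], [30, 25, 9], [12, 9, 0]])
        res = indor_score(PairTable(np.stack([base, base + 1])))
        assert res.degenerate and res.statistic == 0.0

    def test_positive_on_interaction_table(self, rng):
        t = random_dense_table(rng)
        res = indor_score(t)
        assert res.statistic >= 0 and res.df == 4


class TestDss:
    def test_constant_second_snp_no_gain(self):
        counts = np.zeros((2, 3, 3), dtype=int)
        counts[0, :, 0] = [50, 30, 20]
        counts[1, :, 0] = [20, 30, 50]  # SNP b constant at 0
        res = dss_score(PairTable(counts))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_proportional_tables_zero(self, rng):
        res = dss_score(_proportional_table(rng))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_case_only_cell_hand_computed(self):
        # one pure-case cell that singles cannot isolate
        n1 = n0 = 100
        counts = np.zeros((2, 3, 3), dtype=int)
        counts[0] = [[25, 25, 0], [25, 25, 0], [0, 0, 0]]
        counts[1] = [[20, 20, 0], [20, 20, 0], [0, 0, 20]]
        res = dss_score(PairTable(counts))
        # pair ROC first vertex: cell (2,2) -> TPR 0.2 at FPR 0; single-SNP
        # ROCs at FPR 0 give TPR 0.2 as well (marginal row/col 2 is pure-case)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        counts[1, 2, 2] = 0
        counts[1, 0, 2] = 10
        counts[1, 2, 0] = 10
        counts[1, 1, 1] += 0
        t2 = PairTable(counts)
        res2 = dss_score(t2)
        # now corners are case-only cells; singles' best pure-case margins
        # carry only part of that mass, so the pair gains discrimination
        assert res2.statistic > 0

    def test_score_is_minus_log10_p(self, rng):
        res = dss_score(random_dense_table(rng))
        assert res.log10_p <= 0


class TestCrossMethodProperties:
    @pytest.mark.parametrize("method", METHODS)
    def test_transpose_invariance(self, method, rng):
        for _ in range(5):
            t = random_dense_table(rng, n=800)
            r1 = score_pair_table(t, method)
            r2 = score_pair_table(t.transposed(), method)
            assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("method", METHODS)
    def test_pvalue_consistent_with_statistic(self, method, rng):
        t = random_dense_table(rng)
        res = score_pair_table(t, method)
        if not res.degenerate and method != "dss":
            assert res.log10_p == pytest.approx(
                chi2_log_sf(res.statistic, res.df), rel=1e-9
            )

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            score_pair_table(random_dense_table(rng), "epiblaster")


class TestScanAllPairs:
    def test_pair_count(self, rng):
        g = rng.integers(0, 3, size=(80, 10)).astype(np.int8)
        cohort = _cohort(g, rng.integers(0, 2, size=80))
        out = list(scan_all_pairs(cohort, ["gboost"]))
        assert len(out) == 45
        assert len({pair for pair, _ in out}) == 45

    def test_gboost_screen_filters(self, rng):
        g = rng.integers(0, 3, size=(200, 8)).astype(np.int8)
        cohort = _cohort(g, rng.integers(0, 2, size=200))
        screened = list(scan_all_pairs(cohort, ["gboost"], gboost_screen=1.0))
        full = list(scan_all_pairs(cohort, ["gboost"]))
        kept = [r.statistic for _, r in full if r.statistic > 1.0]
        assert sorted(r.statistic for _, r in screened) == sorted(kept)

    def test_guard_on_wide_cohorts(self, rng):
        g = rng.integers(0, 3, size=(4, 30)).astype(np.int8)
        cohort = _cohort(g, np.array([0, 0, 1, 1]))
        with pytest.raises(ValueError, match="guard"):
            next(scan_all_pairs(cohort, ["fastepi"], max_loci=20))
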