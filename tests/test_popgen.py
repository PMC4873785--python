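"""Population-genetic statistics: heterozygosity, rarefaction, HWE, LD,
F-statistics, null-allele EM, multiple-testing correction."""

import numpy as np
import pytest
from scipy.stats import kstest

from oracles import hwe_two_allele_exact, rarefaction_enumeration
from ssrforge.io import MISSING, GenotypeMatrix
from ssrforge.popgen import (
    allele_counts,
    allelic_richness,
    hwe_exact_test,
    ld_test,
    locus_summary,
    null_allele_em,
    sequential_bonferroni,
    wc_fstats,
)
from ssrforge.simulate import GenotypeSimParams, simulate_genotypes


def matrix_from_calls(calls_by_pop, locus_ids=None):
    """Build a GenotypeMatrix from {pop: [(a, b), ...]} per-locus nested lists."""
    pops, ids, rows = [], [], []
    for pop, individuals in calls_by_pop.items():
        for i, genotypes in enumerate(individuals):
            pops.append(pop)
            ids.append(f"{pop}_{i}")
            rows.append(genotypes)
    calls = np.array(rows, dtype=np.int64)
    n_loci = calls.shape[1]
    return GenotypeMatrix(
        individual_ids=ids,
        populations=pops,
        locus_ids=locus_ids or [f"L{j}" for j in range(n_loci)],
        calls=calls,
    )


class TestLocusSummary:
    def test_hand_computed_example(self):
        # genotypes 11, 12, 22, 12, 11 -> p = (0.6, 0.4), Ho = 0.4,
        # He = (10/9)(1 - 0.52) = 0.5333
        gm = matrix_from_calls(
            {"p1": [[(100, 100)], [(100, 104)], [(104, 104)], [(100, 104)], [(100, 100)]]}
        )
        st = locus_summary(gm, "L0")["p1"]
        assert st.n == 5 and st.na == 2
        assert st.ho == pytest.approx(0.4)
        assert st.he == pytest.approx((10 / 9) * (1 - 0.6**2 - 0.4**2))

    def test_monomorphic(self):
        gm = matrix_from_calls({"p1": [[(100, 100)]] * 6})
        st = locus_summary(gm, "L0")["p1"]
        assert (st.na, st.ho, st.he) == (1, 0.0, 0.0)

    def test_all_missing_population_flagged(self):
        gm = matrix_from_calls(
            {"p1": [[(100, 104)]] * 4, "p2": [[(MISSING, MISSING)]] * 4}
        )
        assert not locus_summary(gm, "L0")["p2"].defined

    def test_relabeling_invariance(self):
        gm1 = matrix_from_calls({"p1": [[(100, 104)], [(104, 108)], [(100, 100)]]})
        gm2 = matrix_from_calls({"p1": [[(204, 208)], [(208, 212)], [(204, 204)]]})
        s1, s2 = locus_summary(gm1, "L0")["p1"], locus_summary(gm2, "L0")["p1"]
        assert s1.he == pytest.approx(s2.he) and s1.ho == s2.ho


class TestAllelicRichness:
    def test_no_rarefaction_returns_na(self):
        counts = {1: 6, 2: 3, 3: 1}
        assert allelic_richness(counts, g=10) == pytest.approx(3.0)

    def test_two_allele_closed_form(self):
        # counts (6,4), g=2: (1 - C(4,2)/C(10,2)) + (1 - C(6,2)/C(10,2))
        assert allelic_richness([6, 4], 2) == pytest.approx((1 - 6 / 45) + (1 - 15 / 45))

    def test_single_gene_draw(self):
        assert allelic_richness([5, 3, 2], 1) == pytest.approx(1.0)

    @pytest.mark.parametrize("counts,g", [([3, 2, 1], 2), ([4, 4], 3), ([2, 2, 2], 4)])
    def test_matches_enumeration(self, counts, g):
        assert allelic_richness(counts, g) == pytest.approx(
            rarefaction_enumeration(counts, g)
        )

    def test_domain_error(self):
        with pytest.raises(ValueError):
            allelic_richness([2, 2], 5)


class TestHWEExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(np.array([[1, 1]] * 10)) == 1.0

    def test_two_allele_enumeration_matches_oracle(self):
        for n_aa, n_ab, n_bb in [(3, 4, 3), (5, 0, 5), (0, 10, 0), (2, 7, 1)]:
            g = np.array([[1, 1]] * n_aa + [[1, 2]] * n_ab + [[2, 2]] * n_bb)
            assert hwe_exact_test(g, method="enumeration") == pytest.approx(
                hwe_two_allele_exact(n_aa, n_ab, n_bb), rel=1e-9
            )

    def test_extreme_heterozygote_excess(self):
        assert hwe_exact_test(np.array([[1, 2]] * 50)) < 0.001

    def test_monte_carlo_agrees_with_enumeration(self):
        g = np.array([[1, 1]] * 3 + [[1, 2]] * 4 + [[2, 2]] * 3)
        p_enum = hwe_exact_test(g, method="enumeration")
        p_mc = hwe_exact_test(g, method="monte_carlo", reps=100_000, seed=11)
        assert p_mc == pytest.approx(p_enum, abs=0.01)

    def test_monte_carlo_deterministic_under_seed(self):
        g = np.array([[1, 2]] * 6 + [[1, 1]] * 4 + [[2, 3]] * 5 + [[3, 3]] * 2)
        p1 = hwe_exact_test(g, method="monte_carlo", reps=5_000, seed=3)
        p2 = hwe_exact_test(g, method="monte_carlo", reps=5_000, seed=3)
        assert p1 == p2

    def test_three_allele_enumeration_vs_mc(self):
        rng = np.random.default_rng(8)
        sizes = np.array([1, 2, 3])
        g = sizes[rng.choice(3, size=(15, 2), p=[0.5, 0.3, 0.2])]
        p_enum = hwe_exact_test(g, method="enumeration")
        p_mc = hwe_exact_test(g, method="monte_carlo", reps=100_000, seed=5)
        assert p_mc == pytest.approx(p_enum, abs=0.01)


class TestLD:
    def test_duplicated_locus_extreme(self):
        gm, _ = simulate_genotypes(GenotypeSimParams(n_per_pop=(40,), n_loci=2, seed=1))
        gm.calls[:, 1, :] = gm.calls[:, 0, :]
        p = ld_test(gm, "L001", "L002", reps=1_000, seed=2)
        assert p <= 0.01

    def test_deterministic_under_seed(self):
        gm, _ = simulate_genotypes(GenotypeSimParams(n_per_pop=(30,), n_loci=2, seed=3))
        p1 = ld_test(gm, "L001", "L002", reps=2_000, seed=9)
        p2 = ld_test(gm, "L001", "L002", reps=2_000, seed=9)
        assert p1 == p2

    def test_insufficient_data_flagged(self):
        gm = matrix_from_calls({"p1": [[(1, 1), (2, 2)]] * 4})
        assert np.isnan(ld_test(gm, "L0", "L1"))

    def test_null_calibration_uniform(self):
        """p-values for independent loci are ~uniform (KS at alpha 0.01)."""
        pvals = []
        for seed in range(150):
            gm, _ = simulate_genotypes(
                GenotypeSimParams(n_per_pop=(40,), n_loci=2, target_fst=0.0,
                                  min_alleles=2, max_alleles=4, seed=1000 + seed)
            )
            pvals.append(ld_test(gm, "L001", "L002", reps=1_000, seed=seed))
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestWCFStats:
    def test_identical_populations_theta_near_zero(self):
        genos = [[(100, 104)], [(100, 100)], [(104, 104)], [(100, 104)]] * 8
        gm = matrix_from_calls({"p1": genos, "p2": [list(g) for g in genos]})
        assert abs(wc_fstats(gm).fst) < 0.02

    def test_fixed_difference_theta_one(self):
        gm = matrix_from_calls(
            {"p1": [[(100, 100)]] * 20, "p2": [[(104, 104)]] * 20}
        )
        assert wc_fstats(gm).fst == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        gm, _ = simulate_genotypes(GenotypeSimParams(n_per_pop=(30, 30), seed=4))
        theta = wc_fstats(gm).fst
        gm.calls[gm.calls != MISSING] += 500
        assert wc_fstats(gm).fst == pytest.approx(theta)

    def test_single_population_undefined(self):
        gm = matrix_from_calls({"p1": [[(100, 104)]] * 5})
        with pytest.raises(ValueError):
            wc_fstats(gm)

    def test_balding_nichols_recovery(self):
        gm, _ = simulate_genotypes(
            GenotypeSimParams(n_per_pop=(50, 50), n_loci=20, target_fst=0.10, seed=7)
        )
        assert 0.06 <= wc_fstats(gm).fst <= 0.14


class TestNullAlleleEM:
    def test_no_signal_small_r(self):
        # genotypes at exact HW proportions for p = (0.5, 0.5), n = 100
        g = np.array([[1, 1]] * 25 + [[1, 2]] * 50 + [[2, 2]] * 25)
        res = null_allele_em(g, n_missing=0)
        assert res.null_freq < 0.01
        assert res.converged

    def test_recovery_from_simulation(self):
        gm, truth = simulate_genotypes(
            GenotypeSimParams(n_per_pop=(200,), n_loci=6, target_fst=0.0,
                              null_rate=0.2, seed=13)
        )
        rhats = []
        for locus in gm.locus_ids:
            j = gm.locus_index(locus)
            g = gm.genotypes(locus)
            n_missing = int(((gm.calls[:, j, :] == MISSING).all(axis=1)).sum())
            rhats.append(null_allele_em(g, n_missing=n_missing).null_freq)
        assert 0.12 <= np.mean(rhats) <= 0.28

    def test_saturated_degenerate_case(self):
        # every individual homozygous for its own allele: r driven upward
        g = np.array([[a, a] for a in range(1, 31)])
        res = null_allele_em(g)
        assert res.saturated and res.null_freq > 0.3

    def test_requires_two_visible_alleles(self):
        with pytest.raises(ValueError):
            null_allele_em(np.array([[1, 1]] * 5))


class TestSequentialBonferroni:
    def test_single_pvalue_raw_threshold(self):
        assert sequential_bonferroni([0.04]).tolist() == [True]
        assert sequential_bonferroni([0.06]).tolist() == [False]

    def test_holm_worked_examples(self):
        assert sequential_bonferroni([0.001, 0.02, 0.04]).tolist() == [True, True, True]
        assert sequential_bonferroni([0.001, 0.03, 0.04]).tolist() == [True, False, False]

    def test_stepdown_stops_at_first_failure(self):
        # the largest p would pass its own threshold (0.049 <= 0.05) but the
        # procedure already stopped at the second-ranked p (0.03 > 0.025)
        flags = sequential_bonferroni([0.002, 0.049, 0.03], alpha=0.05)
        assert flags.tolist() == [True, False, False]

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            sequential_bonferroni([0.5, 1.2])


def test_hwe_type_one_error_controlled():
    """Exact-test p-values are super-uniform under simulated HWE."""
    rng = np.random.default_rng(2024)
    rejections = 0
    n_loci = 400
    for _ in range(n_loci):
        na = int(rng.integers(2, 4))
        p = rng.dirichlet(np.ones(na))
        g = rng.choice(na, size=(25, 2), p=p) + 1
        if len(np.unique(g)) < 2:
            continue
        if hwe_exact_test(np.sort(g, axis=1)) <= 0.05:
            rejections += 1
    rate = rejections / n_loci
    assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_loci)
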