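"""SNI detection, panel construction, assignment, and panel comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import mann_whitney_enumeration
from ssrforge.io import GenotypeMatrix
from ssrforge.panels import (
    MarkerProfile,
    assign_individuals,
    build_panels,
    compare_panels,
    detect_sni,
    mann_whitney,
    pca_coordinates,
    profiles_from_table,
)
from ssrforge.simulate import GenotypeSimParams, simulate_genotypes


def two_pop_matrix(pop1_geno, pop2_geno, n_loci):
    ids, pops, rows = [], [], []
    for pop, genos in (("p1", pop1_geno), ("p2", pop2_geno)):
        for i, g in enumerate(genos):
            ids.append(f"{pop}_{i}")
            pops.append(pop)
            rows.append(g)
    return GenotypeMatrix(ids, pops, [f"L{j}" for j in range(n_loci)],
                          np.array(rows, dtype=np.int64))


class TestDetectSNI:
    @pytest.mark.parametrize(
        "sizes,k,expected",
        [
            ([240, 244, 248, 252], 4, False),
            ([240, 244, 249], 4, True),
            ([150, 153, 156], 3, False),
            ([150, 153, 157], 3, True),
        ],
    )
    def test_examples(self, sizes, k, expected):
        assert detect_sni(sizes, k) is expected

    @given(st.lists(st.integers(0, 40), min_size=2, max_size=8),
           st.integers(2, 6), st.integers(-50, 50))
    def test_shift_invariance(self, steps, k, shift):
        sizes = [150 + k * s for s in steps]
        off = [s + shift for s in sizes]
        assert detect_sni(sizes, k) == detect_sni(off, k)
        assert detect_sni(sizes, k) is False  # all on the ladder

    def test_mononucleotide_not_applicable(self):
        with pytest.raises(ValueError):
            detect_sni([100, 101], 1)

    def test_planted_off_ladder_allele_recovered(self):
        """A +1 bp allele at frequency 0.1 is flagged in essentially every
        cohort of 47 diploid individuals."""
        detected = 0
        reps = 50
        for seed in range(reps):
            gm, truth = simulate_genotypes(
                GenotypeSimParams(n_per_pop=(23, 24), n_loci=1, sni_loci={0: 0.1},
                                  seed=5000 + seed)
            )
            g = gm.genotypes("L001")
            sizes = sorted({int(x) for x in g.ravel()})
            if detect_sni(sizes, gm.motif_lengths["L001"]):
                detected += 1
        assert detected >= int(0.99 * reps)


class TestBuildPanels:
    def test_reproduces_reference_panel_labels(self, reference_markers):
        df = reference_markers
        panels = build_panels(profiles_from_table(df))
        ref = {
            name: sorted(df[df.panel.str.contains(name)].locus)
            for name in ("MP", "SNI", "SS")
        }
        assert sorted(panels.sni) == ref["SNI"] and len(panels.sni) == 8
        assert sorted(panels.mp) == ref["MP"] and len(panels.mp) == 8
        assert sorted(panels.ss) == ref["SS"] and len(panels.ss) == 8
        assert len(panels.all) == 30

    def test_reference_table_structure(self, reference_markers):
        df = reference_markers
        assert df.na.mean() == pytest.approx(9.43, abs=0.005)
        assert df.na.max() == 17
        full = df[df.n == 47]
        assert len(full) == 14
        assert len(full[~full.sni]) == 9

    def test_mp_tie_at_cut_included(self):
        profiles = [
            MarkerProfile(f"x{i}", 3, na, 10, 10)
            for i, na in enumerate([17, 16, 13, 12, 11, 11, 11, 11, 10, 9])
        ]
        panels = build_panels(profiles, k=8)
        assert len(panels.mp) == 8  # four-way tie at 11 fills ranks 5-8
        profiles.append(MarkerProfile("x10", 3, 11, 10, 10))
        assert len(build_panels(profiles, k=8).mp) == 9  # extra tied locus kept

    def test_ambiguous_peaks_excluded_from_ss(self, reference_markers):
        panels = build_panels(profiles_from_table(reference_markers))
        assert "wft3-S01" not in panels.ss
        assert "excluded" in panels.decisions["wft3-S01"]["SS"]
        assert "ambiguous" in panels.decisions["wft3-S01"]["SS"]

    def test_deterministic_and_idempotent(self, reference_markers):
        profiles = profiles_from_table(reference_markers)
        p1, p2 = build_panels(profiles), build_panels(profiles)
        assert p1.as_dict() == p2.as_dict()
        for locus, rules in p1.decisions.items():
            assert set(rules) == {"MP", "SNI", "SS", "ALL"}

    def test_sni_loci_never_in_mp(self, reference_markers):
        panels = build_panels(profiles_from_table(reference_markers))
        assert not set(panels.mp) & set(panels.sni)


class TestAssignment:
    def test_fixed_difference_perfect_assignment(self):
        gm = two_pop_matrix([[(100, 100)] * 3] * 8, [[(104, 104)] * 3] * 8, 3)
        res = assign_individuals(gm, gm.locus_ids)
        assert res["correct"].all()
        q = res[["q_p1", "q_p2"]].max(axis=1)
        assert (q > 0.99).all()

    def test_identical_populations_uninformative(self):
        gm = two_pop_matrix([[(100, 100)] * 3] * 8, [[(100, 100)] * 3] * 8, 3)
        res = assign_individuals(gm, gm.locus_ids, q_threshold=0.60)
        assert np.allclose(res["q_p1"], 0.5)
        assert not res["correct"].any()  # Q = 0.5 < 0.60

    def test_threshold_monotonicity(self):
        gm, _ = simulate_genotypes(
            GenotypeSimParams(n_per_pop=(24, 23), n_loci=8, target_fst=0.08, seed=6)
        )
        counts = []
        for thr in (0.0, 0.6, 0.8, 0.95):
            counts.append(assign_individuals(gm, gm.locus_ids, thr)["correct"].sum())
        assert counts == sorted(counts, reverse=True)
        # threshold 0 is pure maximum-likelihood assignment
        res0 = assign_individuals(gm, gm.locus_ids, 0.0)
        assert (res0["correct"] == (res0["assigned"] == res0["true_pop"])).all()

    def test_unassignable_individual_reported(self):
        gm = two_pop_matrix([[(100, 100)], [(0, 0)]], [[(104, 104)], [(104, 104)]], 1)
        res = assign_individuals(gm, gm.locus_ids)
        assert res["unassigned"].tolist() == [False, True, False, False]

    def test_clean_loci_beat_noisy_loci(self):
        """Assignment is better on clean markers than on the same markers
        with 20% genotyping noise (per-allele random replacement)."""
        clean_rates, noisy_rates = [], []
        for seed in range(100):
            gm, _ = simulate_genotypes(
                GenotypeSimParams(n_per_pop=(24, 23), n_loci=8, target_fst=0.10,
                                  seed=7000 + seed)
            )
            clean_rates.append(assign_individuals(gm, gm.locus_ids)["correct"].mean())
            rng = np.random.default_rng(seed)
            noisy = gm.calls.copy()
            for j, locus in enumerate(gm.locus_ids):
                sizes = np.unique(noisy[:, j, :])
                sizes = sizes[sizes != 0]
                mask = rng.random(noisy[:, j, :].shape) < 0.20
                noisy[:, j, :][mask] = rng.choice(sizes, size=int(mask.sum()))
            gm_noisy = GenotypeMatrix(gm.individual_ids, gm.populations,
                                      gm.locus_ids, noisy, gm.motif_lengths)
            noisy_rates.append(assign_individuals(gm_noisy, gm.locus_ids)["correct"].mean())
        assert np.mean(clean_rates) > np.mean(noisy_rates)


class TestMannWhitney:
    def test_extreme_separation_exact(self):
        w, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert w == 0.0 and p == pytest.approx(0.1)

    @pytest.mark.parametrize("m,n", [(1, 2), (2, 2), (3, 3), (3, 4), (4, 5), (5, 5), (2, 8)])
    def test_agrees_with_enumeration(self, m, n):
        rng = np.random.default_rng(m * 10 + n)
        for _ in range(5):
            vals = rng.permutation(np.arange(1, m + n + 1) * 10)
            x, y = vals[:m], vals[m:]
            w, p = mann_whitney(x, y)
            w_ref, p_ref = mann_whitney_enumeration(x, y)
            assert w == pytest.approx(w_ref)
            assert p == pytest.approx(p_ref, abs=1e-9)

    def test_self_comparison_symmetric(self):
        x = [1.0, 2.0, 3.0, 4.0]
        w, p = mann_whitney(x, x)
        assert w == pytest.approx(len(x) ** 2 / 2)  # U at its null expectation
        assert p == pytest.approx(1.0)


class TestComparePanels:
    def test_summary_and_tests_structure(self):
        gm, _ = simulate_genotypes(
            GenotypeSimParams(n_per_pop=(20, 20), n_loci=12, target_fst=0.08,
                              sni_loci={0: 0.15, 5: 0.15}, seed=3)
        )
        from ssrforge.panels import profiles_from_genotypes

        profiles = profiles_from_genotypes(gm, hwe_reps=2_000, seed=1)
        panels = build_panels(profiles, k=4)
        comp = compare_panels(gm, panels)
        assert set(comp.fst) <= {"MP", "SNI", "SS", "ALL"}
        assert {"panel", "population", "mean_ar", "mean_he", "fis"} <= set(comp.summary.columns)
        assert (comp.tests["P"] <= 1).all() and (comp.tests["P"] >= 0).all()
        for name, df in comp.assignment.items():
            assert len(df) == len(gm.individual_ids)
        for name, df in comp.pca.items():
            assert {"PC1", "PC2"} <= set(df.columns)

    def test_mp_selection_inflates_diversity(self):
        """Picking the top-Na loci from a pool biases mean He upward
        relative to random panels from the same pool."""
        gm, _ = simulate_genotypes(
            GenotypeSimParams(n_per_pop=(40,), n_loci=30, target_fst=0.0, seed=9)
        )
        from ssrforge.popgen import locus_summary

        he = {}
        na = {}
        for locus in gm.locus_ids:
            st = locus_summary(gm, locus)["pop1"]
            he[locus], na[locus] = st.he, st.na
        top = sorted(gm.locus_ids, key=lambda l: -na[l])[:8]
        mp_mean = np.mean([he[l] for l in top])
        rng = np.random.default_rng(0)
        random_means = [
            np.mean([he[l] for l in rng.choice(gm.locus_ids, 8, replace=False)])
            for _ in range(200)
        ]
        assert mp_mean > np.mean(random_means)


def test_pca_sign_convention_fixed():
    gm, _ = simulate_genotypes(GenotypeSimParams(n_per_pop=(15, 15), n_loci=6, seed=2))
    a = pca_coordinates(gm, gm.locus_ids)
    b = pca_coordinates(gm, gm.locus_ids)
    assert np.allclose(a[["PC1", "PC2"]].values, b[["PC1", "PC2"]].values)
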