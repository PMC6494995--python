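"""Diversity estimators, HWE permutation tests, differentiation, clones, B-Y."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from ssngen import (
    GenotypeMatrix,
    allele_frequencies,
    by_correction,
    differentiation,
    diversity_per_population,
    find_clones,
    hwe_tests,
    individual_hl,
    read_genotypes,
    write_genotypes,
)


def hwe_sample(rng, freqs, n, F=0.0):
    """Draw diploid genotypes from allele frequencies with inbreeding F."""
    K = len(freqs)
    out = np.zeros((n, 2), dtype=int)
    for i in range(n):
        if rng.random() < F:
            a = rng.choice(K, p=freqs)
            out[i] = (a + 1, a + 1)
        else:
            a, b = rng.choice(K, size=2, p=freqs)
            out[i] = sorted((a + 1, b + 1))
    return out


class TestIO:
    def test_long_roundtrip(self, toy_genotypes, tmp_path):
        path = tmp_path / "g.csv"
        write_genotypes(toy_genotypes, path, dialect="long")
        back = read_genotypes(path, dialect="long")
        assert back.individuals == toy_genotypes.individuals
        assert back.loci == toy_genotypes.loci
        assert (back.calls == toy_genotypes.calls).all()

    def test_genalex_roundtrip_and_missing(self, toy_genotypes, tmp_path):
        path = tmp_path / "g_wide.csv"
        write_genotypes(toy_genotypes, path, dialect="genalex")
        back = read_genotypes(path, dialect="genalex")
        assert (back.calls == toy_genotypes.calls).all()
        assert (back.calls[2, 1] == 0).all()  # the 0,0 cell stays missing

    def test_long_two_individuals_one_locus(self, tmp_path):
        path = tmp_path / "tiny.csv"
        pd.DataFrame(
            {
                "individual": ["a", "b"],
                "population": ["P", "P"],
                "locus": ["L1", "L1"],
                "allele1": [1, 1],
                "allele2": [2, 1],
            }
        ).to_csv(path, index=False)
        G = read_genotypes(path, dialect="long")
        assert G.calls.shape == (2, 1, 2)

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            read_genotypes(tmp_path / "x.csv", dialect="plink")

    def test_half_call_rejected(self):
        with pytest.raises(ValueError, match="half"):
            GenotypeMatrix(["i"], ["P"], ["L"], np.array([[[1, 0]]]))


class TestAlleleFrequencies:
    def test_forced_example(self):
        G = GenotypeMatrix(
            ["a", "b"], ["P", "P"], ["L1"], np.array([[[11, 11]], [[11, 12]]])
        )
        f = allele_frequencies(G)["P"]["L1"]
        assert f[11] == pytest.approx(0.75) and f[12] == pytest.approx(0.25)

    def test_all_missing_locus_empty(self):
        G = GenotypeMatrix(
            ["a", "b"], ["P", "P"], ["L1", "L2"],
            np.array([[[1, 2], [0, 0]], [[1, 1], [0, 0]]]),
        )
        assert allele_frequencies(G)["P"]["L2"].empty

    def test_pooled_equals_weighted_mean(self, toy_genotypes):
        """Pooled frequencies recount exactly from the raw calls."""
        f_all = allele_frequencies(toy_genotypes, by="all")["all"]
        for l, locus in enumerate(toy_genotypes.loci):
            alleles = toy_genotypes.calls[:, l, :].ravel()
            alleles = alleles[alleles != 0]
            for a, cnt in zip(*np.unique(alleles, return_counts=True)):
                assert f_all[locus][a] == pytest.approx(cnt / alleles.size)


class TestDiversity:
    def test_all_heterozygous_forced_values(self):
        # one locus, p = q = 0.5, 5 individuals all heterozygous
        G = GenotypeMatrix(
            [f"i{k}" for k in range(5)], ["P"] * 5, ["L1"],
            np.array([[[1, 2]]] * 5),
        )
        div = diversity_per_population(G).loc["P"]
        assert div["Ho"] == 1.0
        assert div["uHe"] == pytest.approx(10 / 9 * 0.5, rel=1e-12)
        assert div["Ae"] == pytest.approx(2.0)
        assert div["Fis"] == pytest.approx(1 - 1 / (10 / 9 * 0.5), rel=1e-9)  # -0.80

    def test_monomorphic_locus(self):
        G = GenotypeMatrix(
            ["a", "b"], ["P", "P"], ["L1"], np.array([[[3, 3]], [[3, 3]]])
        )
        div = diversity_per_population(G).loc["P"]
        assert div["Ho"] == 0.0 and div["uHe"] == 0.0
        assert div["Ae"] == 1.0 and div["AR"] == 1.0

    def test_hwe_large_sample_consistency(self):
        """At n = 10000 under HWE, Ho tracks He and Ae matches 1/Σp²."""
        rng = np.random.default_rng(42)
        freqs = np.array([0.5, 0.3, 0.15, 0.05])
        calls = hwe_sample(rng, freqs, 10_000)[:, None, :]
        G = GenotypeMatrix([f"i{k}" for k in range(10_000)], ["P"] * 10_000, ["L1"], calls)
        div = diversity_per_population(G).loc["P"]
        he = 1 - (freqs**2).sum()
        se = np.sqrt(he * (1 - he) / 10_000)
        assert abs(div["Ho"] - he) < 3 * se
        assert div["Ae"] == pytest.approx(1 / (freqs**2).sum(), rel=0.01)

    def test_private_alleles(self, toy_genotypes):
        div = diversity_per_population(toy_genotypes)
        # P1 private: allele 1 at L1, alleles 1 and 2 at L2 -> 3 over 2 loci
        assert div.loc["P1", "PA"] == pytest.approx(1.5)
        # P2 private: alleles 3 and 4 at L2 only
        assert div.loc["P2", "PA"] == pytest.approx(1.0)

    def test_uhe_at_least_he(self, toy_genotypes):
        div = diversity_per_population(toy_genotypes)
        assert (div["uHe"] >= div["He"] - 1e-12).all()
        assert (div["Ae"] <= div["AR"] + 1e-12).all()


class TestHL:
    def test_boundaries(self):
        G = GenotypeMatrix(
            ["hom", "het", "mix"], ["P"] * 3, ["L1", "L2"],
            np.array([[[1, 1], [3, 3]], [[1, 2], [3, 4]], [[1, 1], [3, 4]]]),
        )
        hl = individual_hl(G)
        assert hl["hom"] == 1.0
        assert hl["het"] == 0.0
        assert 0 < hl["mix"] < 1

    def test_weighted_formula(self):
        """Two loci with E = 0.5 and 0.25; homozygous only at the second."""
        # population engineered so He(L1) = 0.5 and He(L2) = 0.25
        calls = np.array(
            [
                [[1, 2], [3, 3]],   # focal: het at L1, hom at L2
                [[1, 2], [3, 4]],
                [[1, 2], [3, 3]],
                [[1, 2], [3, 3]],
            ]
        )
        G = GenotypeMatrix(["f", "b", "c", "d"], ["P"] * 4, ["L1", "L2"], calls)
        he = diversity_per_population(G).loc["P"]
        assert he["He"] == pytest.approx((0.5 + 0.21875) / 2)
        hl = individual_hl(G)
        assert hl["f"] == pytest.approx(0.21875 / (0.5 + 0.21875))

    def test_missing_only_individual_is_nan(self):
        G = GenotypeMatrix(
            ["a", "b"], ["P", "P"], ["L1"], np.array([[[0, 0]], [[1, 2]]])
        )
        assert np.isnan(individual_hl(G)["a"])

    def test_inbred_cohort_has_larger_mean_hl(self):
        rng = np.random.default_rng(7)
        freqs = np.array([0.4, 0.3, 0.2, 0.1])
        n, L = 1000, 6
        def cohort(F, tag):
            calls = np.stack([hwe_sample(rng, freqs, n, F=F) for _ in range(L)], axis=1)
            return GenotypeMatrix([f"{tag}{k}" for k in range(n)], [tag] * n,
                                  [f"L{j}" for j in range(L)], calls)
        hl0 = individual_hl(cohort(0.0, "out")).mean()
        hl3 = individual_hl(cohort(0.3, "inb")).mean()
        assert hl3 > hl0

    def test_flipping_hom_to_het_decreases_hl(self, toy_genotypes):
        hl_before = individual_hl(toy_genotypes)["i1"]
        flipped = toy_genotypes.calls.copy()
        flipped[0, 0] = (1, 2)  # i1's homozygous L1 call becomes heterozygous
        G2 = GenotypeMatrix(
            toy_genotypes.individuals, toy_genotypes.populations,
            toy_genotypes.loci, flipped,
        )
        assert individual_hl(G2)["i1"] < hl_before


class TestHWE:
    def test_all_homozygotes_extreme_deficit(self):
        rng = np.random.default_rng(3)
        alleles = rng.integers(1, 5, size=30)
        calls = np.stack([alleles, alleles], axis=1)[:, None, :]
        G = GenotypeMatrix([f"i{k}" for k in range(30)], ["P"] * 30, ["L1"], calls)
        res = hwe_tests(G, n_perm=999, seed=0).loc["P"]
        assert res["P2"] <= 0.02
        assert res["P1"] > 0.5

    def test_determinism(self, toy_genotypes):
        r1 = hwe_tests(toy_genotypes, n_perm=199, seed=11)
        r2 = hwe_tests(toy_genotypes, n_perm=199, seed=11)
        pd.testing.assert_frame_equal(r1, r2)

    def test_tiny_population_missing(self):
        G = GenotypeMatrix(["a"], ["P"], ["L1"], np.array([[[1, 2]]]))
        assert hwe_tests(G, n_perm=99, seed=0).loc["P"].isna().all()

    def test_nperm_minimum(self, toy_genotypes):
        with pytest.raises(ValueError):
            hwe_tests(toy_genotypes, n_perm=10)


class TestDifferentiation:
    def _two_pop(self, calls1, calls2, loci=("L1",)):
        n1, n2 = len(calls1), len(calls2)
        calls = np.concatenate([calls1, calls2])[:, None, :] if len(loci) == 1 else None
        return GenotypeMatrix(
            [f"i{k}" for k in range(n1 + n2)],
            ["A"] * n1 + ["B"] * n2,
            list(loci),
            calls,
        )

    def test_fixed_differences_maximal(self):
        G = self._two_pop(np.array([[1, 1]] * 8), np.array([[2, 2]] * 8))
        d = differentiation(G).loc["all"]
        assert d["Gst"] == pytest.approx(1.0)
        assert d["D_Jost"] == pytest.approx(1.0)
        assert d["Fst"] == pytest.approx(1.0)

    def test_identical_populations_zero(self):
        block = np.array([[1, 2]] * 5 + [[1, 1]] * 3 + [[2, 2]] * 2)
        G = self._two_pop(block, block)
        d = differentiation(G).loc["all"]
        assert d["Gst"] == pytest.approx(0.0, abs=1e-12)
        assert d["D_Jost"] == pytest.approx(0.0, abs=1e-12)
        assert abs(d["Fst"]) < 0.1  # θ unbiased near 0 for identical samples

    def test_theta_near_zero_on_null_simulation(self):
        rng = np.random.default_rng(21)
        freqs = np.array([0.4, 0.35, 0.25])
        thetas = []
        for _ in range(30):
            c1, c2 = hwe_sample(rng, freqs, 40), hwe_sample(rng, freqs, 40)
            G = self._two_pop(c1, c2)
            thetas.append(differentiation(G).loc["all", "Fst"])
        assert abs(np.mean(thetas)) < 3 * np.std(thetas) / np.sqrt(len(thetas))

    def test_hedrick_jost_forced_arithmetic(self):
        """Hs = 0.5, Ht = 0.75 -> Gst = 1/3, G'st = 1, D = 1."""
        c1 = np.array([[1, 2]] * 4)   # alleles {1,2} at 0.5 each
        c2 = np.array([[3, 4]] * 4)   # alleles {3,4} at 0.5 each
        G = self._two_pop(c1, c2)
        d = differentiation(G).loc["all"]
        assert d["Gst"] == pytest.approx(1 / 3, rel=1e-12)
        assert d["Gpst"] == pytest.approx(1.0, rel=1e-12)
        assert d["D_Jost"] == pytest.approx(1.0, rel=1e-12)

    def test_grouping_by_region(self, toy_genotypes):
        with pytest.raises(ValueError, match="two populations"):
            differentiation(toy_genotypes, {"P1": "r1", "P2": "r2"})


class TestBYCorrection:
    def test_single_pvalue_reduces_to_alpha(self):
        rej, thr = by_correction([0.03], alpha=0.05)
        assert rej.tolist() == [True] and thr == pytest.approx(0.05)
        rej, _ = by_correction([0.06], alpha=0.05)
        assert rej.tolist() == [False]

    def test_forced_enumeration(self):
        rej, thr = by_correction([0.001, 0.2, 0.9], alpha=0.05)
        assert rej.tolist() == [True, False, False]
        cm = 1 + 0.5 + 1 / 3
        assert thr == pytest.approx(1 * 0.05 / (3 * cm))

    def test_all_ones_no_rejections(self):
        rej, thr = by_correction([1.0] * 6)
        assert not rej.any() and thr == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_statsmodels_fdr_by(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(2, 40))
        p[: rng.integers(0, 4)] *= 1e-4
        rej, _ = by_correction(p, alpha=0.05)
        rej_sm = multipletests(p, alpha=0.05, method="fdr_by")[0]
        assert (rej == rej_sm).all()

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            by_correction([0.5, 1.2])


class TestClones:
    def test_unique_genotypes_no_groups(self, toy_genotypes):
        assert find_clones(toy_genotypes).empty

    def test_single_locus_pgen(self):
        calls = np.array([[[1, 2]], [[1, 2]], [[1, 1]], [[2, 2]]])
        G = GenotypeMatrix(["a", "b", "c", "d"], ["P"] * 4, ["L1"], calls)
        res = find_clones(G)
        assert len(res) == 1
        assert res.iloc[0]["p_gen"] == pytest.approx(0.5)  # 2 * 0.5 * 0.5
        assert res.iloc[0]["Psex"] == pytest.approx(1 - 0.5**3)

    def test_duplicate_matches_bruteforce_product(self):
        rng = np.random.default_rng(13)
        n, L = 30, 8
        freqs = np.array([0.4, 0.3, 0.2, 0.1])
        calls = np.stack([hwe_sample(rng, freqs, n) for _ in range(L)], axis=1)
        calls[5] = calls[2]  # clone
        G = GenotypeMatrix([f"i{k}" for k in range(n)], ["P"] * n,
                           [f"L{j}" for j in range(L)], calls)
        res = find_clones(G)
        assert len(res) == 1 and res.iloc[0]["size"] == 2
        freqs_all = allele_frequencies(G, by="all")["all"]
        expect = 1.0
        for j, locus in enumerate(G.loci):
            a1, a2 = sorted(calls[2, j])
            f = freqs_all[locus]
            expect *= f[a1] ** 2 if a1 == a2 else 2 * f[a1] * f[a2]
        assert res.iloc[0]["p_gen"] == pytest.approx(expect, rel=1e-12)

    def test_missing_pattern_must_match(self):
        calls = np.array([[[1, 2], [0, 0]], [[1, 2], [3, 3]]])
        G = GenotypeMatrix(["a", "b"], ["P", "P"], ["L1", "L2"], calls)
        assert find_clones(G).empty
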