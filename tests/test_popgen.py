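"""Population-genetic estimators and the permutation set-enrichment test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cavechrono.popgen import (
    GenotypeTable,
    allele_frequencies,
    dxy,
    fst_outliers,
    high_frequency_variants,
    nucleotide_diversity,
    permutation_set_enrichment,
    popgen_table,
    weir_cockerham_fst,
)
from cavechrono.simulate import simulate_genotypes


def _table(genotype_rows, pops, gene_length=100):
    n_sites = len(genotype_rows)
    sites = pd.DataFrame(
        {"contig": "c", "pos": np.arange(1, n_sites + 1), "ref": "A", "alt": "G",
         "gene": "g1"}
    )
    iv = pd.DataFrame({"gene": ["g1"], "contig": ["c"], "start": [0], "end": [gene_length]})
    samples = [f"s{i}" for i in range(len(pops))]
    return GenotypeTable(
        sites=sites,
        genotypes=np.asarray(genotype_rows, dtype=np.int8),
        samples=samples,
        pop_map=dict(zip(samples, pops)),
        gene_intervals=iv,
    )


class TestAlleleFrequencies:
    def test_direct_count(self):
        t = _table([[0, 1, 2]], ["A"] * 3)
        af = allele_frequencies(t, "A")
        assert af["freq"].iloc[0] == pytest.approx(0.5)
        assert af["n_called_alleles"].iloc[0] == 6

    def test_all_alt(self):
        t = _table([[2, 2, 2]], ["A"] * 3)
        assert allele_frequencies(t, "A")["freq"].iloc[0] == 1.0

    def test_missing_excluded(self):
        t = _table([[-1, 0, 0, 2]], ["A"] * 4)
        af = allele_frequencies(t, "A")
        assert af["freq"].iloc[0] == pytest.approx(2 / 6)

    def test_all_missing_flagged(self):
        t = _table([[-1, -1]], ["A"] * 2)
        af = allele_frequencies(t, "A")
        assert not af["defined"].iloc[0] and np.isnan(af["freq"].iloc[0])


class TestNucleotideDiversity:
    def test_monomorphic_zero(self):
        t = _table([[0, 0, 0]], ["A"] * 3)
        assert nucleotide_diversity(t, "A")["pi"].iloc[0] == 0.0

    def test_unbiased_site_formula(self):
        # p = 0.5, n = 4 alleles -> site pi = (4/3) * 2 * 0.25 = 2/3
        t = _table([[1, 1]], ["A"] * 2, gene_length=1)
        assert nucleotide_diversity(t, "A")["pi"].iloc[0] == pytest.approx(2 / 3)

    def test_length_normalization(self):
        t100 = _table([[1, 1]], ["A"] * 2, gene_length=100)
        t200 = _table([[1, 1]], ["A"] * 2, gene_length=200)
        assert nucleotide_diversity(t100, "A")["pi"].iloc[0] == pytest.approx(
            2 * nucleotide_diversity(t200, "A")["pi"].iloc[0]
        )


class TestWeirCockerham:
    def test_fixed_difference_exactly_one(self):
        t = _table([[2, 2, 2, 0, 0, 0]], ["A"] * 3 + ["B"] * 3)
        _, per_gene = weir_cockerham_fst(t, "A", "B")
        assert per_gene["fst"].iloc[0] == pytest.approx(1.0)

    def test_monomorphic_excluded(self):
        t = _table([[1, 1, 1, 1], [0, 0, 0, 0]], ["A", "A", "B", "B"])
        per_site, per_gene = weir_cockerham_fst(t, "A", "B")
        assert not per_site["used"].iloc[1]
        assert per_gene["n_sites_excluded"].iloc[0] == 1

    def test_identical_population_mean_near_zero(self):
        table, _ = simulate_genotypes(1000, {"A": 10, "B": 10}, target_fst=0.0, seed=8)
        per_site, _ = weir_cockerham_fst(table, "A", "B")
        used = per_site[per_site["used"]]
        est = used["a"].sum() / used[["a", "b", "c"]].sum().sum()
        assert abs(est) < 0.02

    def test_order_invariance(self):
        table, _ = simulate_genotypes(200, {"A": 5, "B": 5}, target_fst=0.1, seed=2)
        _, g1 = weir_cockerham_fst(table, "A", "B")
        perm = np.random.default_rng(0).permutation(len(table.sites))
        shuffled = GenotypeTable(
            sites=table.sites.iloc[perm].reset_index(drop=True),
            genotypes=table.genotypes[perm],
            samples=table.samples,
            pop_map=table.pop_map,
            gene_intervals=table.gene_intervals,
        )
        _, g2 = weir_cockerham_fst(shuffled, "A", "B")
        m1 = g1.set_index("gene")["fst"].sort_index()
        m2 = g2.set_index("gene")["fst"].sort_index()
        pd.testing.assert_series_equal(m1, m2, atol=1e-12, rtol=0)


class TestDxy:
    def test_identical_monomorphic_zero(self):
        t = _table([[0, 0, 0, 0]], ["A", "A", "B", "B"])
        assert dxy(t, "A", "B")["dxy"].iloc[0] == 0.0

    def test_one_fixed_difference_per_100bp(self):
        t = _table([[2, 2, 0, 0]], ["A", "A", "B", "B"], gene_length=100)
        assert dxy(t, "A", "B")["dxy"].iloc[0] == pytest.approx(0.01)

    def test_symmetry(self):
        table, _ = simulate_genotypes(300, {"A": 5, "B": 5}, target_fst=0.1, seed=3)
        d1 = dxy(table, "A", "B")["dxy"].to_numpy()
        d2 = dxy(table, "B", "A")["dxy"].to_numpy()
        np.testing.assert_allclose(d1, d2)

    def test_self_comparison_matches_expected_heterozygosity(self):
        # d_XY of a population against an identical copy equals 2p(1-p)/L
        t = _table([[1, 0, 1, 0]], ["A", "A", "B", "B"], gene_length=10)
        p = 0.25
        assert dxy(t, "A", "B")["dxy"].iloc[0] == pytest.approx(2 * p * (1 - p) / 10)


class TestOutliers:
    def test_top_five_of_hundred(self):
        v = np.arange(1, 101, dtype=float)
        flags = fst_outliers(v, 0.05)
        assert flags.sum() == 5 and set(v[flags]) == {96, 97, 98, 99, 100}

    def test_forty_genes(self):
        v = np.arange(1, 41, dtype=float)
        flags = fst_outliers(v, 0.05)
        assert set(v[flags]) == {39, 40}

    def test_all_equal_all_flagged(self):
        flags = fst_outliers(np.ones(30), 0.05)
        assert flags.all()

    def test_minimum_gene_count(self):
        with pytest.raises(ValueError):
            fst_outliers(np.arange(10), 0.05)


class TestHighFrequencyVariants:
    def _freqs(self, cave, surface):
        return pd.DataFrame({"cave1": cave, "surf": surface})

    @pytest.mark.parametrize(
        "cave,surface,kept",
        [
            ([0.9], [0.0], 1),   # high in cave, absent in surface
            ([0.9], [0.05], 0),  # present in surface
            ([0.7], [0.0], 0),   # below the 0.8 threshold in all caves
            ([0.8], [0.0], 1),   # inclusive boundary
        ],
    )
    def test_rules(self, cave, surface, kept):
        out = high_frequency_variants(self._freqs(cave, surface), ["cave1"], "surf")
        assert len(out) == kept

    def test_missingness_guard(self):
        f = self._freqs([0.9], [0.0])
        f["n_called_surf"] = [0]
        out = high_frequency_variants(f, ["cave1"], "surf")
        assert len(out) == 0  # zero frequency unsupported by any called allele


class TestPermutationEnrichment:
    def test_all_flagged_p_one(self):
        flags = pd.Series(True, index=[f"g{i}" for i in range(50)])
        p, _ = permutation_set_enrichment(flags, 18, 10, n_perm=200, seed=0)
        assert p == 1.0

    def test_add_one_bounds(self):
        flags = pd.Series([True] * 2 + [False] * 98)
        p, _ = permutation_set_enrichment(flags, 18, 2, n_perm=1000, seed=1)
        assert 1 / 1001 <= p <= 1.0

    def test_converges_to_hypergeometric_tail(self):
        flags = pd.Series([True] * 10 + [False] * 90)
        p, _ = permutation_set_enrichment(flags, 18, 5, n_perm=100_000, seed=2)
        oracle = stats.hypergeom.sf(4, 100, 10, 18)
        se = np.sqrt(oracle * (1 - oracle) / 100_000)
        assert abs(p - oracle) < 3 * se + 2 / 100_000


class TestPopgenTable:
    def test_summary_columns_and_flags(self):
        table, _ = simulate_genotypes(1500, {"S": 8, "C": 8}, target_fst=0.15, seed=6)
        out = popgen_table(table, pairs=[("S", "C")], outlier_quantile=0.05)
        assert {"pi_S", "pi_C", "fst_S_C", "dxy_S_C", "outlier_S_C", "outlier_any"} <= set(out.columns)
        n_def = out["fst_S_C"].notna().sum()
        assert out["outlier_any"].sum() >= max(1, int(0.05 * n_def))
        assert (out["pi_S"].dropna() >= 0).all() and (out["dxy_S_C"].dropna() >= 0).all()
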