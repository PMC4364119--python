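"""Per-locus statistics: frequencies, diversity, HWE, LD, nulls, Ar, FDR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import hwe_pairing_oracle, rarefaction_oracle
from ssrpipe import (
    GenotypeDataset,
    IslandModelSpec,
    allele_frequencies,
    allelic_richness,
    by_fdr,
    expected_heterozygosity,
    generate_genotypes,
    hwe_exact_test,
    ld_test,
    null_allele_estimates,
    observed_heterozygosity,
    pic,
)


class TestFrequenciesAndHeterozygosity:
    def test_frequency_table(self):
        freqs, n = allele_frequencies([(1, 1), (1, 2)])
        assert freqs == {1: 0.75, 2: 0.25}
        assert n == 2

    def test_missing_excluded(self):
        freqs, n = allele_frequencies([(1, 1), (0, 0)])
        assert freqs == {1: 1.0} and n == 1

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            allele_frequencies([(0, 0)])
        with pytest.raises(ValueError):
            observed_heterozygosity([(0, 0)])

    def test_ho(self):
        assert observed_heterozygosity([(1, 2), (1, 1)]) == 0.5
        assert observed_heterozygosity([(1, 1), (2, 2)]) == 0.0

    def test_hs_monomorphic_zero(self):
        assert expected_heterozygosity({1: 1.0}, 10) == 0.0

    def test_hs_unbiased_small_sample(self):
        assert expected_heterozygosity({1: 0.5, 2: 0.5}, 10) == pytest.approx(
            (20 / 19) * 0.5
        )

    def test_hs_large_sample_limit(self):
        assert expected_heterozygosity({1: 0.5, 2: 0.5}, 10**6) == pytest.approx(
            0.5, abs=1e-5
        )

    def test_hs_requires_two_individuals(self):
        with pytest.raises(ValueError):
            expected_heterozygosity({1: 1.0}, 1)


class TestPic:
    @pytest.mark.parametrize(
        "freqs,expected",
        [({1: 1.0}, 0.0), ({1: 0.5, 2: 0.5}, 0.375), ({1: 0.5, 2: 0.3, 3: 0.2}, 0.5478)],
    )
    def test_closed_forms(self, freqs, expected):
        assert pic(freqs) == pytest.approx(expected, abs=1e-4)

    @given(
        st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=1, max_size=8)
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_gene_diversity(self, raw):
        p = np.array(raw) / sum(raw)
        value = pic(p)
        assert -1e-12 <= value <= 1 - np.sum(p**2) + 1e-12


class TestHweExactTest:
    def test_monomorphic_p_one(self):
        assert hwe_exact_test([(1, 1)] * 8) == 1.0

    @pytest.mark.parametrize(
        "genotypes",
        [
            [(1, 1)] * 2 + [(1, 2)] * 2 + [(2, 2)],
            [(1, 2)] * 5,
            [(1, 1), (2, 2), (3, 3)],
            [(1, 2), (1, 3), (2, 3), (1, 1)],
            [(1, 1), (1, 2), (2, 2), (2, 3), (3, 3), (1, 3)],
        ],
    )
    def test_enumeration_equals_pairing_oracle(self, genotypes):
        expected = hwe_pairing_oracle(genotypes)
        assert hwe_exact_test(genotypes, method="enumerate") == pytest.approx(expected)

    def test_mc_close_to_enumeration(self):
        genotypes = [(1, 1)] * 6 + [(1, 2)] * 8 + [(2, 2)] * 2 + [(2, 3)] * 4
        exact = hwe_exact_test(genotypes, method="enumerate")
        mc = hwe_exact_test(genotypes, method="mc", mc_reps=20_000, seed=1)
        se = math.sqrt(exact * (1 - exact) / 20_000)
        assert abs(mc - exact) < 3 * se + 1e-4

    def test_mc_seed_deterministic(self):
        genotypes = [(1, 2)] * 10 + [(1, 1)] * 5
        a = hwe_exact_test(genotypes, method="mc", mc_reps=2000, seed=9)
        b = hwe_exact_test(genotypes, method="mc", mc_reps=2000, seed=9)
        assert a == b

    def test_type_i_error_rate(self):
        """Rejection rate at alpha=0.05 on panmictic data sits in its
        binomial 95% interval (exact tests are conservative, so the rate
        may fall below the interval but must not exceed it)."""
        rng = np.random.default_rng(2024)
        n, reps = 50, 400
        rejections = 0
        for _ in range(reps):
            genos = [tuple(sorted(rng.integers(1, 3, size=2))) for _ in range(n)]
            if hwe_exact_test(genos) < 0.05:
                rejections += 1
        rate = rejections / reps
        upper = 0.05 + 1.96 * math.sqrt(0.05 * 0.95 / reps)
        assert rate <= upper


class TestLdTest:
    def _dataset(self, genos_a, genos_b):
        return GenotypeDataset(
            locus_names=["A", "B"],
            pop_names=["p1"],
            individual_names=[[f"i{k}" for k in range(len(genos_a))]],
            genotypes=[[[a, b] for a, b in zip(genos_a, genos_b)]],
        )

    def test_duplicated_locus_maximal_dependence(self):
        rng = np.random.default_rng(1)
        genos = [tuple(sorted(rng.integers(1, 4, size=2))) for _ in range(30)]
        ds = self._dataset(genos, genos)
        p = ld_test(ds, "A", "B", permutations=500, seed=3)
        assert p <= 3 / 501

    def test_monomorphic_locus_p_one(self):
        genos_a = [(1, 2)] * 10
        genos_b = [(5, 5)] * 10
        assert ld_test(self._dataset(genos_a, genos_b), "A", "B", seed=1) == 1.0

    def test_independent_loci_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        rejected = 0
        reps = 120
        for _ in range(reps):
            a = [tuple(sorted(rng.integers(1, 4, size=2))) for _ in range(24)]
            b = [tuple(sorted(rng.integers(1, 4, size=2))) for _ in range(24)]
            p = ld_test(self._dataset(a, b), "A", "B", permutations=200, seed=11)
            rejected += p < 0.05
        assert rejected / reps < 0.15


class TestNullAlleles:
    def test_no_deficit_no_evidence(self):
        est = null_allele_estimates(0.5, 0.5)
        assert (est.chakraborty, est.brookfield1, est.evidence) == (0.0, 0.0, False)

    def test_closed_form_values(self):
        est = null_allele_estimates(0.20, 0.66)
        assert est.chakraborty == pytest.approx(0.5349, abs=1e-4)
        assert est.brookfield1 == pytest.approx(0.2771, abs=1e-4)
        assert est.evidence

    def test_excess_heterozygosity_clamped(self):
        est = null_allele_estimates(0.8, 0.5)
        assert est.chakraborty == 0.0 and est.brookfield1 == 0.0 and not est.evidence

    def test_brookfield_recovery_from_simulation(self):
        """Null-allele frequency 0.2 recovered within +-0.07 (500 diploids)."""
        ds, _ = generate_genotypes(
            IslandModelSpec(
                n_pops=1, n_per_pop=500, n_loci=20, n_alleles=8,
                null_rate=0.2, seed=31,
            )
        )
        estimates = []
        for l in range(20):
            genos = [ind[l] for ind in ds.genotypes[0]]
            freqs, n = allele_frequencies(genos)
            ho = observed_heterozygosity(genos)
            hs = expected_heterozygosity(freqs, n)
            estimates.append(null_allele_estimates(ho, hs).brookfield1)
        assert np.mean(estimates) == pytest.approx(0.2, abs=0.07)


class TestAllelicRichness:
    def test_full_sample_equals_allele_count(self):
        counts = {1: 3, 2: 2, 3: 1}
        assert allelic_richness(counts, 6) == pytest.approx(3.0)

    def test_single_gene_equals_one(self):
        assert allelic_richness({1: 3, 2: 2, 3: 1}, 1) == pytest.approx(1.0)

    def test_matches_exhaustive_subsampling_oracle(self):
        counts = [3, 2, 1]
        for g in range(1, 7):
            assert allelic_richness(counts, g) == pytest.approx(
                rarefaction_oracle(counts, g)
            )

    def test_monotone_in_g(self):
        counts = [5, 4, 2, 1]
        values = [allelic_richness(counts, g) for g in range(1, 13)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))

    def test_invalid_g_rejected(self):
        with pytest.raises(ValueError):
            allelic_richness([2, 2], 0)
        with pytest.raises(ValueError):
            allelic_richness([2, 2], 5)


class TestByFdr:
    def test_single_p_unchanged(self):
        assert by_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_computed_example(self):
        adj = by_fdr([0.01, 0.02, 0.04])
        assert adj == pytest.approx([0.055, 0.055, 0.0733], abs=1e-4)

    def test_all_ones(self):
        assert by_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_empty(self):
        assert len(by_fdr([])) == 0

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_permutation_invariant(self, ps):
        adj = by_fdr(ps)
        order = np.argsort(ps)
        assert all(np.diff(adj[order]) >= -1e-12)
        perm = np.random.default_rng(0).permutation(len(ps))
        adj_perm = by_fdr([ps[i] for i in perm])
        np.testing.assert_allclose(adj_perm, adj[perm], atol=1e-12)
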