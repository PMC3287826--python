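import numpy as np
import pandas as pd
import pytest

from zipburden.collapse import collapse_gene
from zipburden.simulate import (SimulationDesign, carrier_moments, child_seed,
                                designed_power, effect_for_power,
                                simulate_genotypes, simulate_phenotypes,
                                simulate_zip_counts)
from zipburden.zip_model import ZipDesign, fit_zip


class TestGenotypes:
    def test_hardy_weinberg_frequencies(self):
        design = SimulationDesign(pop_sizes=(10_000,), n_replicates=1, seed=1,
                                  fixed_pop_freq=np.array([[0.5]]),
                                  fixed_snps_per_gene=[1])
        geno, _, _ = simulate_genotypes(design)
        freqs = np.bincount(geno.calls[:, 0], minlength=3) / 10_000
        se = 3 * np.sqrt(np.array([0.25, 0.5, 0.25]) *
                         (1 - np.array([0.25, 0.5, 0.25])) / 10_000)
        np.testing.assert_array_less(np.abs(freqs - [0.25, 0.5, 0.25]), se)

    def test_zero_maf_limit_gives_all_reference(self):
        design = SimulationDesign(pop_sizes=(500,), n_replicates=1, seed=2,
                                  fixed_pop_freq=np.array([[0.0, 0.0]]),
                                  fixed_snps_per_gene=[2])
        geno, _, _ = simulate_genotypes(design)
        assert not geno.calls.any()

    def test_divergent_pops_flip_minor_allele(self):
        design = SimulationDesign(
            pop_sizes=(300, 300), n_replicates=1, seed=3,
            fixed_pop_freq=np.array([[0.98], [0.02]]),
            fixed_snps_per_gene=[1])
        geno, _, _ = simulate_genotypes(design)
        from zipburden.io import compute_minor_allele_freq
        pooled = compute_minor_allele_freq(geno, geno.snps[0])
        in_a = compute_minor_allele_freq(geno, geno.snps[0],
                                         geno.subjects[:300])
        in_b = compute_minor_allele_freq(geno, geno.snps[0],
                                         geno.subjects[300:])
        assert in_a.minor_allele != in_b.minor_allele
        assert in_a.maf < 0.1 and in_b.maf < 0.1
        assert 0.3 < pooled.maf <= 0.5

    def test_genotypes_fixed_for_fixed_seed(self):
        design = SimulationDesign(pop_sizes=(40,), n_genes=4, seed=4)
        a, _, _ = simulate_genotypes(design)
        b, _, _ = simulate_genotypes(design)
        np.testing.assert_array_equal(a.calls, b.calls)

    def test_mafs_in_range_and_ids_styled(self):
        design = SimulationDesign(pop_sizes=(50,), n_genes=6, seed=5)
        geno, gmap, truth = simulate_genotypes(design)
        assert all(s.startswith("C") and "S" in s for s in geno.snps)
        assert set(gmap.entries[s][1] for s in geno.snps) <= \
            {"synonymous", "nonsynonymous"}
        assert np.all(truth["base_freq"] > 0)
        assert np.all(truth["base_freq"] <= 0.5)

    def test_collapsed_count_mean_matches_hwe_carrier_probability(self):
        mafs = np.array([0.05, 0.1, 0.02, 0.08])
        design = SimulationDesign(pop_sizes=(4000,), n_replicates=1, seed=6,
                                  fixed_pop_freq=mafs[None, :],
                                  fixed_snps_per_gene=[4])
        geno, gmap, _ = simulate_genotypes(design)
        cc = collapse_gene(geno, "GENE0000", gmap)
        mean, var = carrier_moments(mafs)
        assert cc.counts.mean() == pytest.approx(
            mean, abs=3 * np.sqrt(var / 4000))


@pytest.fixture(scope="module")
def study():
    design = SimulationDesign(pop_sizes=(150, 150), n_genes=10,
                              n_replicates=3, seed=7,
                              causal_genes={"Q1": {0: 0.5}})
    geno, gmap, truth = simulate_genotypes(design)
    return design, geno, gmap


class TestPhenotypes:
    def test_deterministic_per_replicate(self, study):
        design, geno, gmap = study
        a = simulate_phenotypes(geno, gmap, design, 1)
        b = simulate_phenotypes(geno, gmap, design, 1)
        pd.testing.assert_frame_equal(a, b)

    def test_replicates_differ_but_covariates_shared(self, study):
        design, geno, gmap = study
        a = simulate_phenotypes(geno, gmap, design, 0)
        b = simulate_phenotypes(geno, gmap, design, 1)
        assert not np.array_equal(a["Q1"], b["Q1"])
        np.testing.assert_array_equal(a["age"], b["age"])
        np.testing.assert_array_equal(a["sex"], b["sex"])

    def test_prevalence_hit_exactly(self, study):
        design, geno, gmap = study
        phen = simulate_phenotypes(geno, gmap, design, 0)
        assert phen["affected"].sum() == round(0.30 * 300)

    def test_causal_gene_correlates_with_trait(self, study):
        design, geno, gmap = study
        phen = simulate_phenotypes(geno, gmap, design, 2)
        counts = collapse_gene(geno, "GENE0000", gmap).counts
        r = np.corrcoef(counts, phen["Q1"])[0, 1]
        assert r > 0.1

    def test_null_trait_independent_of_genotype(self):
        design = SimulationDesign(pop_sizes=(400,), n_genes=5,
                                  n_replicates=1, seed=8)
        geno, gmap, _ = simulate_genotypes(design)
        phen = simulate_phenotypes(geno, gmap, design, 0)
        for g in range(5):
            counts = collapse_gene(geno, f"GENE000{g}", gmap).counts
            r = np.corrcoef(counts, phen["Q1"])[0, 1]
            assert abs(r) < 4 / np.sqrt(400)

    def test_out_of_range_replicate_rejected(self, study):
        design, geno, gmap = study
        with pytest.raises(ValueError, match="replicate"):
            simulate_phenotypes(geno, gmap, design, 99)

    def test_unreachable_prevalence_rejected(self):
        design = SimulationDesign(pop_sizes=(2,), n_genes=2, seed=9,
                                  prevalence=0.05)
        geno, gmap, _ = simulate_genotypes(design)
        with pytest.raises(ValueError, match="prevalence"):
            simulate_phenotypes(geno, gmap, design, 0)


class TestZipCounts:
    def test_certain_inflation_gives_all_zeros(self):
        X = np.ones((500, 1))
        T = simulate_zip_counts(X, X, [500.0], [1.0], seed=0)
        assert not T.any()

    def test_no_inflation_matches_poisson_moments(self):
        X = np.ones((50_000, 1))
        mu = 2.0
        T = simulate_zip_counts(X, X, [-500.0], [np.log(mu)], seed=1)
        se = 3 * np.sqrt(mu / 50_000)
        assert T.mean() == pytest.approx(mu, abs=se)
        assert T.var() == pytest.approx(mu, rel=0.05)

    def test_zero_fraction_closed_form(self):
        X = np.ones((50_000, 1))
        p, mu = 0.3, 2.0
        gamma0 = np.log(p / (1 - p))
        T = simulate_zip_counts(X, X, [gamma0], [np.log(mu)], seed=2)
        expected = p + (1 - p) * np.exp(-mu)
        se = 3 * np.sqrt(expected * (1 - expected) / 50_000)
        assert np.mean(T == 0) == pytest.approx(expected, abs=se)

    def test_end_to_end_parameter_recovery(self):
        rng = np.random.default_rng(10)
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        gamma, beta = np.array([-0.8, 0.4]), np.array([0.3, 0.3])
        T = simulate_zip_counts(X, X, gamma, beta, seed=3)
        fit = fit_zip(ZipDesign(T, X, X))
        est = np.concatenate([fit.gamma, fit.beta])
        se = np.sqrt(np.diag(fit.cov))
        assert np.all(np.abs(est - np.concatenate([gamma, beta])) < 3 * se)


class TestSeedsAndPower:
    def test_child_seeds_stable_and_bounded(self):
        a = child_seed(5, "phenotype", 3)
        assert a == child_seed(5, "phenotype", 3)
        assert a != child_seed(5, "phenotype", 4)
        assert 0 <= a < 2**31

    def test_designed_power_inverts_effect_for_power(self):
        b = effect_for_power(0.8, 700, count_mean=0.5, count_var=0.45)
        assert designed_power(b, 700, 0.5, 0.45, 1.0) == pytest.approx(0.8,
                                                                       abs=1e-6)

    def test_power_monotone_in_effect_and_n(self):
        p1 = designed_power(0.3, 700, 0.5, 0.45, 1.0)
        p2 = designed_power(0.6, 700, 0.5, 0.45, 1.0)
        p3 = designed_power(0.3, 2800, 0.5, 0.45, 1.0)
        assert p1 < p2 and p1 < p3
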