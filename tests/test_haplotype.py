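import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import imprintgen as ig
from imprintgen.haplotype import (
    HAPLOTYPES,
    SNP1_GENOTYPES,
    SNP2_GENOTYPES,
    composite_blocks,
    diplotype_candidates,
    double_het_phase_weight,
    em_haplotype_frequencies,
    fit_composite_diplotype_effects,
    gamete_distribution,
    genotype_strings,
    offspring_genotype_distribution,
    select_risk_haplotype,
    transmission_matrix,
)


class TestGametes:
    def test_free_recombination_uniform(self):
        dist = gamete_distribution("AB|ab", 0.5)
        assert all(v == pytest.approx(0.25) for v in dist.values())

    def test_complete_linkage_parental_only(self):
        dist = gamete_distribution("AB|ab", 0.0)
        assert dist == pytest.approx({"AB": 0.5, "ab": 0.5, "Ab": 0.0, "aB": 0.0})

    def test_homozygote_independent_of_r(self):
        for r in (0.0, 0.2, 0.5):
            dist = gamete_distribution("AB|AB", r)
            assert dist["AB"] == pytest.approx(1.0)

    def test_single_heterozygote_independent_of_r(self):
        for r in (0.0, 0.3, 0.5):
            dist = gamete_distribution(("AB", "Ab"), r)
            assert dist["AB"] == pytest.approx(0.5)
            assert dist["Ab"] == pytest.approx(0.5)

    def test_repulsion_phase(self):
        dist = gamete_distribution("Ab|aB", 0.1)
        assert dist["Ab"] == dist["aB"] == pytest.approx(0.45)
        assert dist["AB"] == dist["ab"] == pytest.approx(0.05)

    @given(r=st.floats(0.0, 0.5))
    def test_rows_normalize(self, r):
        T = transmission_matrix(r)
        assert np.allclose(T.sum(axis=1), 1.0)

    def test_r_out_of_range(self):
        with pytest.raises(ValueError):
            gamete_distribution("AB|ab", 0.7)


class TestPhaseWeight:
    def test_symmetric(self):
        assert double_het_phase_weight([0.25] * 4) == pytest.approx(0.5)

    def test_boundary(self):
        assert double_het_phase_weight([0.5, 0.0, 0.0, 0.5]) == pytest.approx(1.0)

    def test_derived_value(self):
        assert double_het_phase_weight([0.4, 0.1, 0.1, 0.4]) == pytest.approx(
            0.16 / 0.17, abs=1e-9
        )

    def test_undefined(self):
        with pytest.raises(ValueError):
            double_het_phase_weight([0.5, 0.0, 0.5, 0.0])


class TestDiplotypeEnumeration:
    def test_double_heterozygote_has_four_ordered_phases(self):
        cands = diplotype_candidates("Aa", "Bb")
        assert len(cands) == 4
        phases = {frozenset((HAPLOTYPES[hm], HAPLOTYPES[hp])) for hm, hp in cands}
        assert phases == {frozenset(("AB", "ab")), frozenset(("Ab", "aB"))}

    @pytest.mark.parametrize(
        "g1, g2", list(itertools.product(SNP1_GENOTYPES, SNP2_GENOTYPES))
    )
    def test_candidates_reproduce_genotype(self, g1, g2):
        for cand in diplotype_candidates(g1, g2):
            assert genotype_strings(cand) == (g1, g2)


class TestOffspringDistributions:
    @pytest.mark.parametrize("r", [0.0, 0.05, 0.5])
    def test_all_81_combinations_normalize(self, r):
        freqs = [0.4, 0.1, 0.1, 0.4]
        genos = list(itertools.product(SNP1_GENOTYPES, SNP2_GENOTYPES))
        for mg, fg in itertools.product(genos, genos):
            dist = offspring_genotype_distribution(mg, fg, freqs, r)
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_homozygous_parents_single_offspring_genotype(self):
        dist = offspring_genotype_distribution(
            ("AA", "BB"), ("aa", "bb"), [0.25] * 4, 0.1
        )
        assert dist == {("Aa", "Bb"): pytest.approx(1.0)}

    def test_r_only_matters_for_double_heterozygotes(self):
        freqs = [0.4, 0.1, 0.1, 0.4]
        a = offspring_genotype_distribution(("Aa", "BB"), ("AA", "Bb"), freqs, 0.0)
        b = offspring_genotype_distribution(("Aa", "BB"), ("AA", "Bb"), freqs, 0.4)
        for k in a:
            assert a[k] == pytest.approx(b[k])
        c = offspring_genotype_distribution(("Aa", "Bb"), ("AA", "BB"), freqs, 0.0)
        d = offspring_genotype_distribution(("Aa", "Bb"), ("AA", "BB"), freqs, 0.4)
        assert max(abs(c[k] - d.get(k, 0.0)) for k in c) > 0.01


class TestHaplotypeEM:
    def test_monotone_and_convergent(self, two_snp_data):
        fit = em_haplotype_frequencies(two_snp_data)
        assert fit.converged
        assert np.all(np.diff(fit.loglik_trace) >= -1e-6)
        assert fit.frequencies.sum() == pytest.approx(1.0)
        assert np.all(fit.frequencies >= 0)
        assert 0.0 <= fit.r <= 0.5

    def test_recovery_of_frequencies_and_r(self, two_snp_data):
        fit = em_haplotype_frequencies(two_snp_data)
        # one replicate of n = 800: estimates close to (0.4,0.1,0.1,0.4), r=0.05
        assert np.allclose(fit.frequencies, [0.4, 0.1, 0.1, 0.4], atol=0.05)
        assert fit.r == pytest.approx(0.05, abs=0.05)

    def test_complete_data_counting_in_one_iteration(self):
        # no double heterozygotes: frequencies are closed-form counts
        hs = ig.HaplotypeSystem(frequencies=(0.6, 0.0, 0.0, 0.4), r=0.0,
                                risk_haplotype="AB")
        design = ig.DesignSpec(n_gen1_families=40, sons_per_family=1,
                               children_per_couple=1)
        data = ig.simulate_two_snp(design, hs, seed=6)
        # AaBb subjects here are unambiguous (only AB/ab possible)
        fit = em_haplotype_frequencies(data, tol=1e-9)
        assert fit.frequencies[1] == pytest.approx(0.0, abs=1e-6)
        assert fit.frequencies[2] == pytest.approx(0.0, abs=1e-6)
        founders = data.founders()
        n_ab = sum(d.count("ab") for d in founders["diplotype_true"])
        assert fit.frequencies[3] == pytest.approx(n_ab / (2 * len(founders)), abs=1e-6)

    def test_r_truth_zero_estimated_near_boundary(self):
        hs = ig.HaplotypeSystem(frequencies=(0.4, 0.1, 0.1, 0.4), r=0.0,
                                risk_haplotype="AB")
        design = ig.DesignSpec(n_gen1_families=150, sons_per_family=1,
                               children_per_couple=2)
        data = ig.simulate_two_snp(design, hs, seed=8)
        fit = em_haplotype_frequencies(data)
        assert fit.r <= 0.03


class TestCompositeEffects:
    def test_priors_are_distributions(self, two_snp_data):
        fit = em_haplotype_frequencies(two_snp_data)
        blocks = composite_blocks(two_snp_data, fit.frequencies, fit.r, "AB")
        for y, P in blocks.values():
            assert np.allclose(P.sum(axis=1), 1.0)
            assert np.all(P >= 0)

    def test_effect_recovery(self, two_snp_data):
        fit = em_haplotype_frequencies(two_snp_data)
        eff = fit_composite_diplotype_effects(
            two_snp_data, fit.frequencies, fit.r, "AB"
        )
        par = eff.params_by_generation["parental"]
        off = eff.params_by_generation["offspring"]
        # generating values: parental (1.0, 0.5, 0.5), offspring (0.5, 0.5, 0.0)
        assert par.a == pytest.approx(1.0, abs=0.35)
        assert par.i == pytest.approx(0.5, abs=0.35)
        assert off.a == pytest.approx(0.5, abs=0.25)
        assert abs(off.i) < 0.25

    def test_constant_phenotypes_zero_effects(self, two_snp_data):
        from imprintgen.pedigree import ThreeGenDataset

        df = two_snp_data.subjects.copy()
        df.loc[df["phenotype"].notna(), "phenotype"] = 1.0
        const = ThreeGenDataset(df, n_snps=2)
        fit0 = em_haplotype_frequencies(const)
        eff = fit_composite_diplotype_effects(const, fit0.frequencies, fit0.r, "AB")
        for p in eff.params_by_generation.values():
            assert (p.a, p.d, p.i) == pytest.approx((0.0, 0.0, 0.0), abs=1e-6)

    def test_risk_selection_contract(self, two_snp_data):
        sel = select_risk_haplotype(two_snp_data)
        assert set(sel.logliks) == set(HAPLOTYPES)
        assert all(f.converged for f in sel.fits.values())
        assert sel.risk_haplotype == "AB"  # the simulated risk haplotype

    def test_degenerate_two_snp_equals_single_snp_fit(self):
        # SNP2 monomorphic: only AB/aB haplotypes; composite diplotypes of
        # risk AB coincide with the SNP1 ordered configurations
        hs = ig.HaplotypeSystem(frequencies=(0.6, 0.0, 0.4, 0.0), r=0.5,
                                risk_haplotype="AB")
        design = ig.DesignSpec(n_gen1_families=100, sons_per_family=1,
                               children_per_couple=1)
        data2 = ig.simulate_two_snp(design, hs, seed=9)
        with pytest.warns(UserWarning, match="monomorphic"):
            f1 = em_haplotype_frequencies(data2)
        eff = fit_composite_diplotype_effects(data2, f1.frequencies, f1.r, "AB")

        data1 = ig.ThreeGenDataset(data2.subjects.copy(), n_snps=1)
        single = ig.full_fit(data1)
        for key in ("parental", "offspring"):
            a = eff.params_by_generation[key]
            b = single.params_by_generation[key]
            assert a.effects() == pytest.approx(b.effects(), abs=1e-5)
            assert a.sigma2 == pytest.approx(b.sigma2, abs=1e-5)
        assert eff.loglik == pytest.approx(single.loglik, abs=1e-4)
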