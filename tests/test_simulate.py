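"""Generators: pedigree shape, founder LD, gene dropping, DYD calibration."""

import numpy as np
import pandas as pd
import pytest

from ldacc.data import SizingError
from ldacc.evaluation import dyd_accuracy, ld_r2_profile
from ldacc.simulate import (
    DegenerateArchitectureError,
    TraitArchitecture,
    gene_drop,
    lognormal_daughter_counts,
    sample_architecture,
    simulate_founder_haplotypes,
    simulate_pedigree,
    simulate_phenotypes,
)


class TestSimulatePedigree:
    def test_single_generation_parents_are_founders(self):
        ped = simulate_pedigree(1, 6, 2, 3.0, seed=0)
        founders = set(ped.founders)
        non_founders = [i for i in ped.ids if i not in founders]
        assert non_founders
        for i in non_founders:
            assert ped.sire_of(i) in founders and ped.dam_of(i) in founders
        assert ped.half_sib_family_sizes().max() <= 6

    def test_family_sizes_match_target_and_are_right_skewed(self):
        # a configuration aiming at ~320 sires with mean family size 6
        ped = simulate_pedigree(5, 190, 64, 6.0, seed=1)
        fam = ped.half_sib_family_sizes()
        assert abs(fam.mean() - 6.0) / 6.0 < 0.2
        assert fam.max() > 4 * fam.mean()          # heavy right tail
        assert fam.median() < fam.mean()           # right-skew

    def test_full_sib_and_father_son_structure(self):
        ped = simulate_pedigree(4, 80, 25, 6.0, full_sib_rate=0.2, seed=3)
        t = ped.table
        kids = t[t["sire"] != "0"]
        full_sib_sizes = kids.groupby(["sire", "dam"]).size()
        assert (full_sib_sizes >= 2).any()
        # father/son chains across generations: some sire is itself non-founder
        sires = set(kids["sire"])
        assert any(ped.sire_of(s) != "0" for s in sires)

    def test_deterministic_under_seed(self):
        a = simulate_pedigree(3, 20, 6, 4.0, seed=9).table
        b = simulate_pedigree(3, 20, 6, 4.0, seed=9).table
        pd.testing.assert_frame_equal(a, b)
        c = simulate_pedigree(3, 20, 6, 4.0, seed=10).table
        assert not a.equals(c)

    def test_too_many_offspring_for_dams_raises(self):
        with pytest.raises(SizingError, match="dams"):
            simulate_pedigree(1, 3, 4, 20.0, max_offspring_per_dam=2, seed=0)


class TestFounderHaplotypes:
    @pytest.fixture(scope="class")
    def founders(self):
        return simulate_founder_haplotypes(
            200, 2, 400, 25_600_000, n_reserve_per_chrom=60, seed=3
        )

    def test_ld_decays_with_distance(self, founders):
        prof = ld_r2_profile(founders)
        assert prof.mean_r2_at(0.99) < prof.mean_r2_at(0.03)
        assert prof.mean_r2_at(0.5) < prof.mean_r2_at(0.05)

    def test_adjacent_pair_ld_near_calibration_target(self, founders):
        prof = ld_r2_profile(founders)
        assert 0.05 < prof.adjacent_mean_distance_mb < 0.08
        assert 0.17 <= prof.adjacent_mean_r2 <= 0.27

    def test_maf_spectrum_roughly_flat(self, founders):
        m = founders.markers_only().alleles.mean(axis=(0, 1))
        maf = np.minimum(m, 1 - m)
        assert maf.min() > 0.03
        assert 0.20 < maf.mean() < 0.33
        hist, _ = np.histogram(maf, bins=np.linspace(0.05, 0.5, 6))
        assert hist.min() > 0.25 * hist.max()      # no empty frequency band

    def test_independent_model_has_no_ld(self):
        le = simulate_founder_haplotypes(
            300, 1, 100, 10_000_000, model="independent", seed=5
        )
        prof = ld_r2_profile(le, bin_edges_mb=np.arange(0, 10.0, 0.5))
        finite = prof.bins["mean_r2"].dropna()
        assert (finite < 0.02).all()               # ~1/(2N) sampling level

    def test_deterministic_under_seed(self):
        a = simulate_founder_haplotypes(50, 1, 60, 4_000_000, seed=8)
        b = simulate_founder_haplotypes(50, 1, 60, 4_000_000, seed=8)
        assert np.array_equal(a.alleles, b.alleles)
        assert a.snp_map.equals(b.snp_map)

    def test_needs_two_snps(self):
        with pytest.raises(ValueError):
            simulate_founder_haplotypes(10, 1, 1, 1_000_000, seed=0)


class TestGeneDrop:
    def test_homozygous_parent_transmits_certainly(self, toy_pedigree):
        founders = simulate_founder_haplotypes(2, 1, 50, 5_000_000, seed=1)
        founders.alleles[0, :, :] = 0              # sire S homozygous 0 everywhere
        haps = gene_drop(toy_pedigree, founders, 1e-8, seed=2)
        x = haps.subset(ids=["X"]).alleles[0]
        assert (x[0] == 0).all()                   # paternal gamete from S

    def test_zero_recombination_transmits_intact_haplotypes(self, toy_pedigree):
        founders = simulate_founder_haplotypes(2, 1, 80, 5_000_000, seed=3)
        haps = gene_drop(toy_pedigree, founders, 0.0, seed=4)
        sire = haps.subset(ids=["S"]).alleles[0]
        child_pat = haps.subset(ids=["X"]).alleles[0][0]
        assert np.array_equal(child_pat, sire[0]) or np.array_equal(child_pat, sire[1])

    def test_parent_offspring_realized_relationship_half(self, small_population):
        from ldacc.relationships import genomic_relationship_matrix
        from ldacc.data import genotype_data_from_haplotypes

        ped = small_population["pedigree"]
        geno = genotype_data_from_haplotypes(small_population["haplotypes"])
        G = genomic_relationship_matrix(geno)
        pairs = [(i, ped.sire_of(i)) for i in ped.ids if ped.sire_of(i) != "0"]
        vals = np.array([G.between([a], [b])[0, 0] for a, b in pairs])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.5) < 4 * se + 0.02

    def test_missing_founder_haplotypes_raises(self, toy_pedigree):
        founders = simulate_founder_haplotypes(1, 1, 20, 1_000_000, seed=1)
        from ldacc.data import LineageError

        with pytest.raises(LineageError):
            gene_drop(toy_pedigree, founders, 1e-8, seed=0)

    def test_deterministic_under_seed(self, toy_pedigree):
        founders = simulate_founder_haplotypes(2, 1, 30, 2_000_000, seed=6)
        a = gene_drop(toy_pedigree, founders, 1e-8, seed=7)
        b = gene_drop(toy_pedigree, founders, 1e-8, seed=7)
        assert np.array_equal(a.alleles, b.alleles)


class TestPhenotypes:
    def test_dyd_accuracy_calibration_at_constant_daughter_count(self, small_population):
        haps, arch = small_population["haplotypes"], small_population["architecture"]
        bulls = small_population["bulls"]
        rs = []
        for seed in range(8):
            ph = simulate_phenotypes(
                haps, arch, bulls, daughters_per_bull=[50] * len(bulls), seed=seed
            ).for_trait(arch.trait)
            rs.append(np.corrcoef(ph["tbv"], ph["dyd"])[0, 1])
        expected = dyd_accuracy(50, arch.h2)
        assert abs(np.mean(rs) - expected) < 0.03
        assert np.allclose(ph["weight"], expected**2)

    def test_dyd_regression_slope_is_one(self, small_population):
        # DYDs are unshrunken: regression of y on g has slope ~1
        haps, arch = small_population["haplotypes"], small_population["architecture"]
        bulls = small_population["bulls"]
        slopes = []
        for seed in range(8):
            ph = simulate_phenotypes(haps, arch, bulls, seed=seed).for_trait(arch.trait)
            slopes.append(np.polyfit(ph["tbv"], ph["dyd"], 1)[0])
        assert abs(np.mean(slopes) - 1.0) < 0.05

    def test_huge_daughter_count_gives_nearly_true_breeding_value(self, small_population):
        haps, arch = small_population["haplotypes"], small_population["architecture"]
        bulls = small_population["bulls"][:30]
        ph = simulate_phenotypes(
            haps, arch, bulls, daughters_per_bull=[10_000_000] * 30, seed=1
        ).for_trait(arch.trait)
        assert np.allclose(ph["dyd"], ph["tbv"], atol=0.01)

    def test_zero_effects_flagged_degenerate(self, small_population):
        arch = small_population["architecture"]
        null = TraitArchitecture(
            "null", arch.qtl_ids, np.zeros(len(arch.qtl_ids)), 1.0, 0.5
        )
        with pytest.raises(DegenerateArchitectureError):
            simulate_phenotypes(
                small_population["haplotypes"], null, small_population["bulls"], seed=0
            )

    def test_daughter_count_distribution_spans_tens_to_thousands(self, rng):
        n = lognormal_daughter_counts(rng, 4000)
        assert n.min() >= 30 and n.max() > 1000
        assert 80 < np.median(n) < 200


class TestArchitecture:
    def test_variance_scaled_to_target(self, small_population):
        founders = small_population["founders"]
        arch = sample_architecture(founders, 15, 2.5, 0.4, seed=11)
        g = arch.breeding_values(founders)
        assert abs(np.var(g) - 2.5) / 2.5 < 0.1
        assert arch.sigma2_e == pytest.approx(2.5 * 0.6 / 0.4)

    def test_qtl_hidden_from_marker_panel(self, small_population):
        founders = small_population["founders"]
        arch = small_population["architecture"]
        marker_ids = set(founders.markers_only().snp_map["id"])
        assert not (set(arch.qtl_ids) & marker_ids)
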