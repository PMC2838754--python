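"""Accuracy estimator, LD decomposition regression and r² profile."""

import numpy as np
import pandas as pd
import pytest

from ldacc.data import HaplotypeSet
from ldacc.evaluation import (
    dyd_accuracy,
    estimate_accuracy,
    ld_accuracy_regression,
    ld_r2_profile,
)

try:
    from hypothesis import given
    from hypothesis import strategies as st

    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False


class TestDydAccuracy:
    def test_many_daughters_approach_perfect_accuracy(self):
        assert dyd_accuracy(10_000_000, 0.3) == pytest.approx(1.0, abs=1e-3)

    def test_single_daughter_value(self):
        # (1 * 0.53/4) / (1 + 0) = 0.1325 -> sqrt = 0.3640...
        assert dyd_accuracy(1, 0.53) == pytest.approx(np.sqrt(0.1325), abs=1e-9)

    def test_monotone_in_heritability_and_daughters(self):
        assert dyd_accuracy(100, 0.53) > dyd_accuracy(100, 0.23)
        n = np.array([1, 10, 100, 1000])
        r = dyd_accuracy(n, 0.51)
        assert (np.diff(r) > 0).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dyd_accuracy(0, 0.5)
        with pytest.raises(ValueError):
            dyd_accuracy(10, 1.5)


def ebv_frame(replicates, ids_per_rep, g):
    rows = []
    k = 0
    for rep in range(replicates):
        for _ in range(ids_per_rep):
            rows.append({"replicate": rep, "id": f"B{k}", "ebv": g[k]})
            k += 1
    return pd.DataFrame(rows)


def pheno_of(y, n):
    return pd.DataFrame(
        {"id": [f"B{i}" for i in range(len(y))], "dyd": y, "n_daughters": n}
    )


class TestEstimateAccuracy:
    def test_proportional_ebvs_give_inverse_mean_accuracy(self):
        # ghat exactly proportional to y and r_gy = 0.8 for every bull:
        # rho = 1/0.8 = 1.25, reported unclipped with a warning
        rng = np.random.default_rng(1)
        y = rng.normal(size=40)
        h2, n = 0.53, None
        # pick n so that r_gy = 0.8: solve for daughter count
        t = h2 / 4
        n = int(round(0.64 * (1 - t) / (t * (1 - 0.64))))
        r = dyd_accuracy(n, h2)
        ebvs = ebv_frame(4, 10, 2.0 * y)
        with pytest.warns(RuntimeWarning, match="exceeds 1"):
            est = estimate_accuracy(ebvs, pheno_of(y, n), h2)
        assert est.rho == pytest.approx(1.0 / r, abs=0.05)
        assert est.n_validation == 40

    def test_independent_ebvs_near_zero(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=400)
        ebvs = ebv_frame(8, 50, rng.normal(size=400))
        est = estimate_accuracy(ebvs, pheno_of(y, 200), 0.53)
        assert abs(est.rho) < 0.15

    def test_invariant_to_per_replicate_ebv_shifts(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=60)
        ebvs = ebv_frame(3, 20, y + rng.normal(scale=0.5, size=60))
        base = estimate_accuracy(ebvs, pheno_of(y, 150), 0.51)
        shifted = ebvs.copy()
        shifted["ebv"] += shifted["replicate"].map({0: 100.0, 1: -42.0, 2: 7.0})
        est = estimate_accuracy(shifted, pheno_of(y, 150), 0.51)
        assert est.rho == pytest.approx(base.rho, abs=1e-12)

    def test_too_few_bulls_rejected(self):
        ebvs = ebv_frame(1, 2, np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="fewer than 3"):
            estimate_accuracy(ebvs, pheno_of(np.array([1.0, 2.0]), 10), 0.5)

    if HAVE_HYPOTHESIS:

        @given(st.floats(-50, 50), st.floats(-50, 50))
        def test_centering_contract_property(self, c0, c1):
            rng = np.random.default_rng(9)
            y = rng.normal(size=30)
            ebvs = ebv_frame(2, 15, y + rng.normal(scale=0.3, size=30))
            base = estimate_accuracy(ebvs, pheno_of(y, 80), 0.5).rho
            shifted = ebvs.copy()
            shifted["ebv"] += shifted["replicate"].map({0: c0, 1: c1})
            assert estimate_accuracy(shifted, pheno_of(y, 80), 0.5).rho == pytest.approx(
                base, abs=1e-9
            )


class TestLdAccuracyRegression:
    def test_exact_recovery_on_noiseless_line(self):
        # rho = 0.30 + 0.35 x for x in {1, 0.9, 0.7, 0.5}
        x = {0.6: 1.0, 0.49: 0.9, 0.249: 0.7, 0.1249: 0.5}
        pblup = {a: 0.8 * xi for a, xi in x.items()}  # reference 0.6 -> x as given
        gebv = {a: 0.30 + 0.35 * xi for a, xi in x.items()}
        reg = ld_accuracy_regression(gebv, pblup, reference_amax=0.6)
        assert reg.rho_ld == pytest.approx(0.30, abs=1e-12)
        assert reg.d == pytest.approx(0.35, abs=1e-12)
        assert np.allclose(reg.residuals, 0.0, atol=1e-12)

    def test_pure_relationship_case_gives_zero_ld_accuracy(self):
        pblup = {0.6: 0.7, 0.49: 0.6, 0.249: 0.4, 0.1249: 0.25}
        gebv = {a: 1.1 * v / 0.7 * 0.7 for a, v in pblup.items()}  # proportional
        reg = ld_accuracy_regression({a: v * 1.0 for a, v in pblup.items()}, pblup)
        assert reg.rho_ld == pytest.approx(0.0, abs=1e-10)
        assert reg.d == pytest.approx(0.7, abs=1e-10)

    def test_residuals_orthogonal_to_predictor(self):
        rng = np.random.default_rng(4)
        pblup = {0.6: 0.72, 0.49: 0.61, 0.249: 0.45, 0.1249: 0.31}
        gebv = {a: 0.3 + 0.4 * v / 0.72 + rng.normal(scale=0.05) for a, v in pblup.items()}
        reg = ld_accuracy_regression(gebv, pblup)
        assert float(reg.x @ reg.residuals) == pytest.approx(0.0, abs=1e-10)
        assert float(reg.residuals.sum()) == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_predictor_rejected(self):
        flat = {0.6: 0.5, 0.49: 0.5, 0.249: 0.5}
        with pytest.raises(ValueError, match="unidentifiable"):
            ld_accuracy_regression({0.6: 0.6, 0.49: 0.6, 0.249: 0.6}, flat)

    def test_needs_three_scenarios(self):
        with pytest.raises(ValueError, match=">= 3"):
            ld_accuracy_regression({0.6: 0.6, 0.49: 0.5}, {0.6: 0.5, 0.49: 0.4})


def haps_from_columns(cols, positions, chrom=1):
    """Build a 1-individual-per-haplotype-pair set from explicit haplotype
    columns: cols is (n_haplotypes, n_sites)."""
    cols = np.asarray(cols, dtype=np.int8)
    n_hap, n_sites = cols.shape
    assert n_hap % 2 == 0
    alleles = cols.reshape(n_hap // 2, 2, n_sites)
    smap = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "id": [f"S{j}" for j in range(n_sites)]}
    )
    return HaplotypeSet([f"I{i}" for i in range(n_hap // 2)], alleles, smap)


class TestLdR2Profile:
    def test_hand_computed_two_locus_cases(self):
        # counts {00:4, 11:4} -> D = 0.25, r2 = 1; all four at 2 -> r2 = 0
        perfect = haps_from_columns([[0, 0]] * 4 + [[1, 1]] * 4, [1_000, 21_000])
        prof = ld_r2_profile(perfect)
        assert prof.adjacent_mean_r2 == pytest.approx(1.0)
        balanced = haps_from_columns(
            [[0, 0]] * 2 + [[0, 1]] * 2 + [[1, 0]] * 2 + [[1, 1]] * 2, [1_000, 21_000]
        )
        assert ld_r2_profile(balanced).adjacent_mean_r2 == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_locus_r2_one(self, rng):
        col = rng.integers(0, 2, size=40)
        haps = haps_from_columns(np.column_stack([col, col]), [5_000, 105_000])
        assert ld_r2_profile(haps).adjacent_mean_r2 == pytest.approx(1.0)

    def test_independent_loci_near_zero(self, rng):
        cols = rng.integers(0, 2, size=(2000, 6))
        haps = haps_from_columns(cols, np.arange(6) * 150_000 + 1)
        prof = ld_r2_profile(haps)
        assert prof.bins["mean_r2"].dropna().max() < 0.01

    def test_binning_and_cross_chromosome_sd(self, rng):
        cols = rng.integers(0, 2, size=(200, 40))
        smap_pos = np.tile(np.arange(20) * 50_000 + 1, 2)
        haps = HaplotypeSet(
            [f"I{i}" for i in range(100)],
            cols.reshape(100, 2, 40),
            pd.DataFrame(
                {"chrom": [1] * 20 + [2] * 20, "pos": smap_pos,
                 "id": [f"S{j}" for j in range(40)]}
            ),
        )
        prof = ld_r2_profile(haps)
        b = prof.bins
        assert (b["bin_lo"] < b["bin_hi"]).all()
        assert (b["bin_lo"].to_numpy()[1:] >= b["bin_hi"].to_numpy()[:-1] - 1e-12).all()
        filled = b.dropna(subset=["mean_r2"])
        assert ((filled["mean_r2"] >= 0) & (filled["mean_r2"] <= 1)).all()
        assert (filled["sd_r2"].dropna() >= 0).all()
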