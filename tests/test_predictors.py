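"""BayesB, G-BLUP/P-BLUP and RR-BLUP predictors."""

import numpy as np
import pandas as pd
import pytest

from ldacc.data import GenotypeData
from ldacc.predictors import (
    BayesBConfig,
    EBVResult,
    PanelMismatchError,
    VarianceComponents,
    fit_bayesb,
    fit_blup,
    fit_rrblup,
    predict_gebv,
)
from ldacc.relationships import RelationshipMatrix, genomic_relationship_matrix


VAR = VarianceComponents(1.0, 0.5)


def pheno_frame(ids, y, w=None):
    return pd.DataFrame(
        {
            "id": ids,
            "dyd": y,
            "weight": w if w is not None else np.ones(len(ids)),
            "n_daughters": 100,
        }
    )


def random_instance(seed, n=60, k=120):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, size=k)
    X = rng.binomial(2, p, size=(n, k)).astype(float)
    smap = pd.DataFrame({"chrom": 1, "pos": np.arange(k) * 1000 + 1, "id": [f"S{j}" for j in range(k)]})
    geno = GenotypeData([f"B{i}" for i in range(n)], X, smap)
    y = rng.normal(size=n)
    w = rng.uniform(0.3, 1.0, size=n)
    return geno, y, w


class TestBlupEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_gblup_equals_rrblup(self, seed):
        # the animal model on the centered cross-product G and the SNP-effect
        # ridge model are the same linear model in two parameterisations
        geno, y, w = random_instance(seed)
        train = pheno_frame(geno.ids[:40], y[:40], w[:40])
        targets = geno.ids[40:]
        G = genomic_relationship_matrix(geno)
        a = fit_blup(train, G, VAR, target_ids=targets)
        b = fit_rrblup(train, geno, VAR, target_ids=targets)
        assert np.abs(a.for_ids(targets) - b.for_ids(targets)).max() < 1e-6
        assert a.mu == pytest.approx(b.mu, abs=1e-6)

    def test_identity_kinship_shrinks_deviations(self):
        # scalar mixed-model algebra: with K = I and equal weights,
        # ghat_i = (sigma2_a / (sigma2_a + sigma2_e)) * (y_i - mean(y))
        rng = np.random.default_rng(5)
        ids = [f"B{i}" for i in range(25)]
        y = rng.normal(size=25)
        K = RelationshipMatrix(ids, np.eye(25), "numerator")
        fit = fit_blup(pheno_frame(ids, y), K, VAR, target_ids=ids)
        shrink = VAR.sigma2_a / (VAR.sigma2_a + VAR.sigma2_e)
        assert np.allclose(fit.for_ids(ids), shrink * (y - y.mean()), atol=1e-8)

    def test_unrelated_target_gets_zero_ebv(self):
        rng = np.random.default_rng(6)
        ids = [f"B{i}" for i in range(10)] + ["stranger"]
        vals = np.eye(11)
        K = RelationshipMatrix(ids, vals, "numerator")
        fit = fit_blup(pheno_frame(ids[:10], rng.normal(size=10)), K, VAR, target_ids=["stranger"])
        assert fit.for_ids(["stranger"])[0] == pytest.approx(0.0, abs=1e-10)

    def test_higher_weight_pulls_fitted_residual_to_zero(self):
        geno, y, _ = random_instance(7, n=30, k=40)
        G = genomic_relationship_matrix(geno)
        resid = []
        for w0 in (0.2, 0.5, 0.9):
            w = np.full(30, 0.5)
            w[0] = w0
            fit = fit_blup(pheno_frame(geno.ids, y, w), G, VAR, target_ids=geno.ids)
            resid.append(abs(y[0] - fit.mu - fit.for_ids([geno.ids[0]])[0]))
        assert resid[0] > resid[1] > resid[2]


class TestBayesB:
    def test_null_phenotypes_give_null_fit(self):
        geno, _, w = random_instance(8, n=40, k=60)
        train = pheno_frame(geno.ids, np.zeros(40), w)
        cfg = BayesBConfig(pi=0.05, n_iter=600, burn_in=200, seed=3)
        with pytest.warns(RuntimeWarning):  # short chain: low-ESS warning possible
            fit = fit_bayesb(train, geno, VAR, cfg)
        assert abs(fit.alpha) < 0.05
        assert np.abs(fit.beta).max() < 0.05
        assert ((fit.inclusion_freq >= 0) & (fit.inclusion_freq <= 1)).all()

    def test_pi_one_fixed_variance_matches_closed_form_ridge(self, small_population):
        from oracles import weighted_ridge_gebv

        ph = small_population["phenotypes"].for_trait("trait").iloc[:120]
        geno = small_population["genotypes"].subset_individuals(list(ph["id"]))
        p = geno.allele_frequencies()
        s2pq = 2 * np.sum(p * (1 - p))
        cfg = BayesBConfig(
            pi=1.0, n_iter=2500, burn_in=800, seed=9,
            fixed_effect_variance=VAR.sigma2_a / s2pq,
        )
        fit = fit_bayesb(ph, geno, VAR, cfg)
        gebv = predict_gebv(fit, geno).for_ids(geno.ids)
        oracle = weighted_ridge_gebv(
            geno.matrix, ph["dyd"].to_numpy(), ph["weight"].to_numpy(),
            p, VAR.sigma2_a, VAR.sigma2_e, geno.matrix,
        )
        # centered comparison: Eq-style GEBVs differ from the centered oracle
        # by a constant absorbed in the intercept
        r = np.corrcoef(gebv, oracle)[0, 1]
        assert r > 0.97

    def test_deterministic_under_seed(self):
        geno, y, w = random_instance(10, n=30, k=50)
        train = pheno_frame(geno.ids, y, w)
        cfg = BayesBConfig(pi=0.1, n_iter=400, burn_in=100, seed=11)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f1 = fit_bayesb(train, geno, VAR, cfg)
            f2 = fit_bayesb(train, geno, VAR, cfg)
        assert np.array_equal(f1.traces["sigma2_e"], f2.traces["sigma2_e"])
        assert np.array_equal(f1.beta, f2.beta)

    def test_residual_variance_recovered_on_null_qtl_data(self):
        # y is pure noise at the generating sigma2_e: the posterior mean of
        # sigma2_e must recover it within Monte-Carlo error
        rng = np.random.default_rng(12)
        geno, _, _ = random_instance(12, n=150, k=80)
        y = rng.normal(0.0, np.sqrt(VAR.sigma2_e), size=150)
        train = pheno_frame(geno.ids, y)
        cfg = BayesBConfig(pi=0.02, n_iter=2000, burn_in=500, seed=13)
        fit = fit_bayesb(train, geno, VAR, cfg)
        assert fit.sigma2_e == pytest.approx(VAR.sigma2_e, rel=0.2)

    def test_chain_must_exceed_burn_in(self):
        with pytest.raises(ValueError):
            BayesBConfig(n_iter=100, burn_in=100)


class TestPredictGebv:
    def make_fit(self, beta, snp_ids):
        from ldacc.predictors import BayesBFit

        return BayesBFit(
            alpha=0.3, beta=np.asarray(beta, float),
            inclusion_freq=np.zeros(len(snp_ids)), sigma2_e=1.0,
            snp_ids=list(snp_ids),
        )

    def test_null_effects_give_zero_gebvs(self):
        geno, _, _ = random_instance(14, n=5, k=4)
        fit = self.make_fit(np.zeros(4), geno.snp_ids)
        out = predict_gebv(fit, geno)
        assert np.allclose(out.ebvs.to_numpy(), 0.0)

    def test_single_snp_arithmetic(self):
        smap = pd.DataFrame({"chrom": [1], "pos": [100], "id": ["S0"]})
        geno = GenotypeData(["a", "b", "c"], np.array([[0.0], [1.0], [2.0]]), smap)
        fit = self.make_fit([2.0], ["S0"])
        out = predict_gebv(fit, geno)
        assert list(out.for_ids(["a", "b", "c"])) == [0.0, 2.0, 4.0]

    def test_panel_mismatch_lists_snps(self):
        geno, _, _ = random_instance(15, n=4, k=6)
        fit = self.make_fit(np.zeros(5), [f"S{j}" for j in range(5)])
        with pytest.raises(PanelMismatchError, match="S5"):
            predict_gebv(fit, geno)


class TestLinkageEquilibriumLimit:
    def test_le_gblup_approaches_pblup_with_marker_count(self):
        # with LE founders and related validation bulls, markers only carry
        # relationship information: G-BLUP accuracy converges to P-BLUP
        # accuracy as the marker count grows
        from ldacc.workflow import run_le_study

        le = run_le_study(
            seed=5, marker_counts=(100, 1500), n_generations=2,
            founders_per_sex=60, sires_per_generation=20, offspring_per_sire=5.0,
        )
        ks = sorted(le["gblup"])
        gap_small = abs(le["gblup"][ks[0]]["related"] - le["pblup_related"])
        gap_large = abs(le["gblup"][ks[-1]]["related"] - le["pblup_related"])
        assert gap_large < gap_small
        assert abs(le["gblup"][ks[-1]]["unrelated"]) < 0.2
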