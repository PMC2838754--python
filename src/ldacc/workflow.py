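"""End-to-end experiment: simulate → QC → relationship matrices → splits →
fits → accuracy and the LD decomposition.

:func:`run_experiment` executes the full relationship-constrained
cross-validation on one synthetic population and returns (and optionally
writes) the per-scenario accuracies, the accuracy-due-to-LD regressions,
the r² decay profile and a provenance manifest.  :func:`run_le_study` is
the companion linkage-equilibrium experiment: with LE markers, GEBVs of
unrelated bulls carry no information, while for related bulls G-BLUP
approaches P-BLUP as the marker count grows because the markers recover the
pedigree relationships.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import ExperimentConfig, derive_seed
from .data import (
    GenotypeData,
    HaplotypeSet,
    Pedigree,
    PhenotypeTable,
    genotype_data_from_haplotypes,
)
from .design import SplitConstraints, downsample_training, sample_splits
from .evaluation import (
    AccuracyEstimate,
    LDProfile,
    estimate_accuracy,
    ld_accuracy_regression,
    ld_r2_profile,
)
from .predictors import (
    BayesBConfig,
    VarianceComponents,
    fit_bayesb,
    fit_blup,
    predict_gebv,
)
from .qc import filter_snps, impute_missing, mask_x_heterozygotes
from .relationships import (
    RelationshipMatrix,
    genomic_relationship_matrix,
    numerator_relationship_matrix,
)
from .simulate import (
    gene_drop,
    sample_architecture,
    simulate_founder_haplotypes,
    simulate_pedigree,
    simulate_phenotypes,
)

logger = logging.getLogger(__name__)

__all__ = ["run_experiment", "run_le_study", "ExperimentReport", "StageFailure"]


class StageFailure(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ExperimentReport:
    accuracy: pd.DataFrame        # method, trait, a_max, train_size, rho, raw_corr, n_val
    regressions: pd.DataFrame     # method, trait, train_size, rho_ld, d, se_rho_ld, se_d
    ld_profile: LDProfile
    family_stats: dict
    manifest: dict
    splits: dict = field(default_factory=dict)          # a_max -> list[Split]
    estimates: dict = field(default_factory=dict)       # (method, trait, a_max, size) -> AccuracyEstimate
    ebv_frames: dict = field(default_factory=dict)      # (method, trait, a_max, size) -> DataFrame
    phenotypes: PhenotypeTable | None = None
    pedigree: Pedigree | None = None
    genotypes: GenotypeData | None = None
    relationship_A: RelationshipMatrix | None = None


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - reraise with stage context
                raise StageFailure(f"stage {name!r} failed: {err}") from err
            logger.info("stage %s done in %.1f s", name, time.time() - t0)
            return out
        return wrapped
    return deco


@_stage("simulate")
def _simulate_population(cfg: ExperimentConfig):
    ped = simulate_pedigree(
        cfg.pedigree.n_generations,
        cfg.pedigree.founders_per_sex,
        cfg.pedigree.sires_per_generation,
        cfg.pedigree.offspring_per_sire,
        full_sib_rate=cfg.pedigree.full_sib_rate,
        max_offspring_per_dam=cfg.pedigree.max_offspring_per_dam,
        family_size_skew=cfg.pedigree.family_size_skew,
        seed=cfg.stage_seed("pedigree"),
    )
    founders = simulate_founder_haplotypes(
        len(ped.founders),
        cfg.genome.n_chromosomes,
        cfg.genome.n_snps_per_chrom,
        cfg.genome.chrom_length_bp,
        effective_pop_size=cfg.genome.effective_pop_size,
        recombination_rate=cfg.genome.recombination_rate,
        n_reserve_per_chrom=cfg.genome.n_reserve_per_chrom,
        model=cfg.genome.founder_model,
        seed=cfg.stage_seed("founders"),
    )
    haps = gene_drop(ped, founders, cfg.genome.recombination_rate, seed=cfg.stage_seed("genedrop"))
    return ped, founders, haps


def _genotyped_bulls(ped: Pedigree, from_generation: int) -> list[str]:
    t = ped.table
    mask = (t["sex"] == "M") & (t["birth_year"] >= from_generation)
    return list(t.loc[mask, "id"].astype(str))


@_stage("phenotypes")
def _make_phenotypes(cfg, founders, haps, bulls) -> tuple[PhenotypeTable, dict]:
    tables, archs = [], {}
    for trait in cfg.traits:
        arch = sample_architecture(
            founders,
            trait.n_qtl,
            trait.sigma2_a,
            trait.h2,
            trait=trait.name,
            effect_distribution=trait.effect_distribution,
            gamma_shape=trait.gamma_shape,
            seed=cfg.stage_seed(f"architecture:{trait.name}"),
        )
        archs[trait.name] = arch
        tables.append(
            simulate_phenotypes(
                haps, arch, bulls, seed=cfg.stage_seed(f"dyd:{trait.name}")
            ).table
        )
    return PhenotypeTable(pd.concat(tables, ignore_index=True)), archs


@_stage("qc")
def _qc(cfg, haps: HaplotypeSet, bulls, sex) -> GenotypeData:
    geno = genotype_data_from_haplotypes(haps, sex=sex, ids=bulls)
    geno = mask_x_heterozygotes(geno)
    geno, log = filter_snps(geno, cfg.qc.max_missing_rate, cfg.qc.min_maf)
    logger.info("QC removed %d SNPs", len(log))
    if not geno.is_complete():
        geno = impute_missing(geno, cfg.qc.imputation, seed=cfg.stage_seed("impute"))
    return geno


def _fit_scenario(
    cfg: ExperimentConfig,
    method: str,
    trait_name: str,
    h2: float,
    splits,
    phenotypes: PhenotypeTable,
    geno: GenotypeData,
    A: RelationshipMatrix,
    G: RelationshipMatrix,
    variances: VarianceComponents,
    a_max: float,
    train_size: int,
) -> pd.DataFrame:
    rows = []
    for split in splits:
        pheno_train = phenotypes.subset(split.train, trait_name)
        if method == "BayesB":
            bb = BayesBConfig(
                pi=cfg.bayesb.pi,
                nu_e=cfg.bayesb.nu_e,
                nu_beta=cfg.bayesb.nu_beta,
                n_iter=cfg.bayesb.n_iter,
                burn_in=cfg.bayesb.burn_in,
                thin=cfg.bayesb.thin,
                seed=derive_seed(
                    cfg.seed, f"bayesb:{trait_name}:{a_max}:{train_size}:{split.replicate}"
                ),
            )
            fit = fit_bayesb(
                pheno_train, geno.subset_individuals(split.train), variances, bb
            )
            ebv = predict_gebv(fit, geno.subset_individuals(split.val))
        elif method == "G-BLUP":
            ebv = fit_blup(pheno_train, G, variances, target_ids=split.val)
        elif method == "P-BLUP":
            ebv = fit_blup(pheno_train, A, variances, target_ids=split.val)
        else:  # pragma: no cover - config validation rejects earlier
            raise ValueError(method)
        rows.append(
            pd.DataFrame(
                {"replicate": split.replicate, "id": split.val, "ebv": ebv.for_ids(split.val)}
            )
        )
    return pd.concat(rows, ignore_index=True)


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> ExperimentReport:
    """Run the full cross-validation experiment defined by ``config``.

    Deterministic given the config (the master seed fans out to stages by
    label); MCMC stages are trace-identical under the same config.
    """
    cfg = config
    ped, founders, haps = _simulate_population(cfg)
    bulls = _genotyped_bulls(ped, cfg.pedigree.genotype_from_generation)
    sex = dict(zip(ped.table["id"].astype(str), ped.table["sex"]))
    phenotypes, archs = _make_phenotypes(cfg, founders, haps, bulls)
    geno = _qc(cfg, haps, bulls, sex)

    try:
        A = numerator_relationship_matrix(ped)
        G = genomic_relationship_matrix(geno)
    except Exception as err:
        raise StageFailure(f"stage 'relationships' failed: {err}") from err

    # splits: sampled once per a_max at the largest training size; smaller
    # sizes reuse the same validation sets with protected down-sampling
    sizes = cfg.train_sizes_desc()
    splits_by_amax: dict[float, list] = {}
    try:
        for a_max in cfg.scenarios.a_max_grid:
            constraints = SplitConstraints(
                a_max=a_max,
                train_size=sizes[0],
                val_size=cfg.scenarios.val_size[a_max],
                min_val_size=cfg.scenarios.min_val_size[a_max],
                n_replicates=cfg.scenarios.n_replicates,
                n_tries=cfg.scenarios.n_tries,
                protect_threshold=cfg.scenarios.protect_threshold,
            )
            splits_by_amax[a_max] = sample_splits(
                A, ped, bulls, constraints, seed=cfg.stage_seed(f"splits:{a_max}")
            )
    except Exception as err:
        raise StageFailure(f"stage 'splits' failed: {err}") from err

    splits_by_size: dict[tuple, list] = {}
    for a_max, splits in splits_by_amax.items():
        splits_by_size[(a_max, sizes[0])] = splits
        for size in sizes[1:]:
            splits_by_size[(a_max, size)] = [
                downsample_training(
                    s,
                    size,
                    A,
                    protect_threshold=cfg.scenarios.protect_threshold,
                    seed=derive_seed(cfg.seed, f"halve:{a_max}:{size}:{s.replicate}"),
                )
                for s in splits
            ]

    acc_rows, reg_rows = [], []
    estimates: dict = {}
    ebv_frames: dict = {}
    for trait in cfg.traits:
        mean_w = float(phenotypes.for_trait(trait.name)["weight"].mean())
        variances = VarianceComponents(
            sigma2_a=trait.sigma2_a,
            sigma2_e=max(trait.sigma2_a * (1.0 - mean_w), 1e-3),
        )
        for size in sizes:
            per_method: dict[str, dict[float, float]] = {m: {} for m in cfg.methods}
            for a_max in cfg.scenarios.a_max_grid:
                for method in cfg.methods:
                    t0 = time.time()
                    ebvs = _fit_scenario(
                        cfg, method, trait.name, trait.h2,
                        splits_by_size[(a_max, size)],
                        phenotypes, geno, A, G, variances, a_max, size,
                    )
                    est = estimate_accuracy(ebvs, phenotypes.for_trait(trait.name), trait.h2)
                    key = (method, trait.name, a_max, size)
                    estimates[key] = est
                    ebv_frames[key] = ebvs
                    per_method[method][a_max] = est.rho
                    acc_rows.append(
                        {
                            "method": method,
                            "trait": trait.name,
                            "a_max": a_max,
                            "train_size": size,
                            "rho": est.rho,
                            "raw_corr": est.raw_correlation,
                            "mean_r_gy": est.mean_r_gy,
                            "n_val": est.n_validation,
                        }
                    )
                    logger.info(
                        "%s %s a_max=%s n=%d: rho=%.3f (%.1f s)",
                        method, trait.name, a_max, size, est.rho, time.time() - t0,
                    )
            if "P-BLUP" in per_method and len(cfg.scenarios.a_max_grid) >= 3:
                for method in cfg.methods:
                    if method == "P-BLUP":
                        continue
                    reg = ld_accuracy_regression(
                        per_method[method],
                        per_method["P-BLUP"],
                        reference_amax=cfg.scenarios.reference_amax,
                    )
                    reg_rows.append(
                        {
                            "method": method,
                            "trait": trait.name,
                            "train_size": size,
                            "rho_ld": reg.rho_ld,
                            "d": reg.d,
                            "se_rho_ld": reg.se_rho_ld,
                            "se_d": reg.se_d,
                        }
                    )

    try:
        profile = ld_r2_profile(haps.subset(ids=bulls).markers_only())
    except Exception as err:
        raise StageFailure(f"stage 'ld_profile' failed: {err}") from err

    fam = ped.half_sib_family_sizes()
    family_stats = {
        "n_half_sib_families": int(len(fam)),
        "mean_half_sib_family_size": float(fam.mean()),
        "max_half_sib_family_size": int(fam.max()),
        "n_genotyped_bulls": len(bulls),
    }
    config_blob = json.dumps(cfg.to_dict(), sort_keys=True, default=float)
    manifest = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "master_seed": cfg.seed,
        "stage_seeds": {
            lbl: cfg.stage_seed(lbl)
            for lbl in ("pedigree", "founders", "genedrop", "impute")
        },
        "n_snps_post_qc": geno.n_snps,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }

    report = ExperimentReport(
        accuracy=pd.DataFrame(acc_rows),
        regressions=pd.DataFrame(reg_rows),
        ld_profile=profile,
        family_stats=family_stats,
        manifest=manifest,
        splits=splits_by_size,
        estimates=estimates,
        ebv_frames=ebv_frames,
        phenotypes=phenotypes,
        pedigree=ped,
        genotypes=geno,
        relationship_A=A,
    )
    if out_dir is not None:
        _write_report(report, cfg, Path(out_dir))
    return report


def _write_report(report: ExperimentReport, cfg: ExperimentConfig, out: Path) -> None:
    from .io import write_phenotypes_tsv, write_splits_tsv

    out.mkdir(parents=True, exist_ok=True)
    report.accuracy.to_csv(out / "accuracy.tsv", sep="\t", index=False)
    report.regressions.to_csv(out / "ld_regressions.tsv", sep="\t", index=False)
    report.ld_profile.bins.to_csv(out / "ld_profile.tsv", sep="\t", index=False)
    for (a_max, size), splits in report.splits.items():
        write_splits_tsv(splits, out / f"splits_amax{a_max}_n{size}.tsv")
    if report.phenotypes is not None:
        write_phenotypes_tsv(report.phenotypes, out / "phenotypes.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# linkage-equilibrium companion study
# ---------------------------------------------------------------------------

def _relabel(ped: Pedigree, prefix: str) -> Pedigree:
    t = ped.table.copy()
    for col in ("id", "sire", "dam"):
        t[col] = t[col].astype(str).map(lambda x: x if x == "0" else f"{prefix}{x}")
    return Pedigree(t)


def run_le_study(
    seed: int = 1,
    marker_counts: tuple = (250, 2000),
    n_generations: int = 3,
    founders_per_sex: int = 100,
    sires_per_generation: int = 33,
    offspring_per_sire: float = 6.0,
    n_qtl: int = 60,
    h2: float = 0.53,
) -> dict:
    """Linkage-equilibrium experiment on two unrelated sub-populations.

    Founder alleles are drawn independently (no LD); QTL sit on sites
    disjoint from the markers, so markers carry no LD information about the
    QTL and can help only by capturing additive-genetic relationships.
    Training bulls come from population 1; validation bulls are (a) the
    youngest population-1 males (related) and (b) population-2 males
    (unrelated, relationship 0 with training).  Accuracies are correlations
    with the simulated true breeding values.

    Returns a dict with G-BLUP accuracies per marker count for both
    validation sets and the P-BLUP accuracy of the related set.
    """
    k_max = max(marker_counts)
    peds = []
    for group in (1, 2):
        ped = simulate_pedigree(
            n_generations,
            founders_per_sex,
            sires_per_generation,
            offspring_per_sire,
            seed=derive_seed(seed, f"le:pedigree{group}"),
        )
        peds.append(_relabel(ped, f"P{group}:"))
    n_founders = sum(len(p.founders) for p in peds)
    # one very long chromosome: ~30 Morgans, so sites are effectively
    # unlinked and cosegregation contributes little beyond relationships
    founders = simulate_founder_haplotypes(
        n_founders,
        1,
        k_max,
        3_000_000_000,
        n_reserve_per_chrom=int(n_qtl * 1.5),
        model="independent",
        seed=derive_seed(seed, "le:founders"),
    )
    split_at = len(peds[0].founders)
    hap_parts = [
        gene_drop(
            peds[0],
            founders.subset(ids=founders.ids[:split_at]),
            seed=derive_seed(seed, "le:drop1"),
        ),
        gene_drop(
            peds[1],
            founders.subset(ids=founders.ids[split_at:]),
            seed=derive_seed(seed, "le:drop2"),
        ),
    ]
    haps = HaplotypeSet(
        hap_parts[0].ids + hap_parts[1].ids,
        np.concatenate([hap_parts[0].alleles, hap_parts[1].alleles], axis=0),
        founders.snp_map.copy(),
    )
    arch = sample_architecture(
        founders, n_qtl, 1.0, h2, effect_distribution="normal",
        seed=derive_seed(seed, "le:arch"),
    )

    def males_of(ped, years):
        t = ped.table
        return list(t.loc[(t["sex"] == "M") & t["birth_year"].isin(years), "id"].astype(str))

    train = males_of(peds[0], range(1, n_generations))
    related_val = males_of(peds[0], [n_generations])
    unrelated_val = males_of(peds[1], [n_generations])
    pheno = simulate_phenotypes(haps, arch, train, seed=derive_seed(seed, "le:dyd"))
    pheno_df = pheno.for_trait(arch.trait)
    variances = VarianceComponents(1.0, max(1.0 - float(pheno_df["weight"].mean()), 1e-3))

    all_ids = train + related_val + unrelated_val
    g_true = pd.Series(
        arch.breeding_values(haps.subset(ids=all_ids)), index=pd.Index(all_ids, name="id")
    )

    def acc(ebv, ids):
        return float(np.corrcoef(ebv.for_ids(ids), g_true.loc[ids])[0, 1])

    A1 = numerator_relationship_matrix(peds[0])
    n1, n2 = len(peds[0]), len(peds[1])
    A2 = numerator_relationship_matrix(peds[1])
    joint = np.zeros((n1 + n2, n1 + n2))
    joint[:n1, :n1] = A1.values
    joint[n1:, n1:] = A2.values
    A = RelationshipMatrix(A1.ids + A2.ids, joint, "numerator")

    pblup = fit_blup(pheno_df, A, variances, target_ids=related_val + unrelated_val)
    out = {
        "pblup_related": acc(pblup, related_val),
        "pblup_unrelated": acc(pblup, unrelated_val),
        "gblup": {},
    }
    geno_all = genotype_data_from_haplotypes(haps, ids=all_ids)
    rng = np.random.default_rng(derive_seed(seed, "le:panels"))
    for k in marker_counts:
        cols = np.sort(rng.choice(geno_all.n_snps, size=k, replace=False))
        sub = GenotypeData(
            geno_all.ids, geno_all.matrix[:, cols],
            geno_all.snp_map.iloc[cols].reset_index(drop=True),
        )
        G = genomic_relationship_matrix(sub)
        gblup = fit_blup(pheno_df, G, variances, target_ids=related_val + unrelated_val)
        out["gblup"][k] = {
            "related": acc(gblup, related_val),
            "unrelated": acc(gblup, unrelated_val),
        }
    out["n_train"] = len(train)
    out["n_related_val"] = len(related_val)
    out["n_unrelated_val"] = len(unrelated_val)
    return out
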