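"""Synthetic Holstein-like populations for genomic-prediction experiments.

The generators in this module produce every input the analysis needs:

* :func:`simulate_pedigree` — a multi-generation pedigree with right-skewed
  paternal half-sib families (a handful of heavily used sires), repeated
  matings that yield full sibs, and genotyped father/son chains, mimicking
  the family structure of a progeny-testing dairy population.
* :func:`simulate_founder_haplotypes` — founder haplotypes whose pairwise
  r² decays with map distance, generated from a neutral coalescent with
  recombination (msprime) and thinned with a MAF-weighted ascertainment
  step that flattens the minor-allele-frequency spectrum the way SNP-chip
  panels do.  A linkage-equilibrium variant draws alleles independently.
* :func:`gene_drop` — Mendelian gene dropping with crossovers through the
  pedigree, so realized genomic relationships have the pedigree expectation.
* :func:`simulate_phenotypes` — daughter yield deviations (DYDs): the
  bull's true breeding value plus noise calibrated so that the correlation
  between truth and DYD equals the selection-index progeny-test accuracy
  for the bull's daughter count.

Only males receive phenotypes (they are the "bulls"); females exist in the
pedigree as links.  Mating is random — no selection is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import msprime
import numpy as np
import pandas as pd

from .data import (
    HaplotypeSet,
    LineageError,
    Pedigree,
    PhenotypeTable,
    SizingError,
    UNKNOWN_PARENT,
)
from .evaluation import dyd_accuracy

__all__ = [
    "simulate_pedigree",
    "simulate_founder_haplotypes",
    "gene_drop",
    "TraitArchitecture",
    "sample_architecture",
    "simulate_phenotypes",
    "lognormal_daughter_counts",
]


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(
    n_generations: int,
    founders_per_sex: int,
    sires_per_generation: int,
    offspring_per_sire: float,
    *,
    full_sib_rate: float = 0.08,
    max_offspring_per_dam: int = 4,
    family_size_skew: float = 0.35,
    seed: int = 0,
) -> Pedigree:
    """Simulate a pedigree with large paternal half-sib families.

    Each generation, ``sires_per_generation`` males are drawn from the two
    preceding cohorts and allotted ``sires_per_generation *
    offspring_per_sire`` offspring multinomially with Gamma-distributed
    usage weights (``family_size_skew`` is the Gamma shape; small values
    give a few very large families).  Dams come from the previous female
    cohort, each carrying at most ``max_offspring_per_dam`` offspring; with
    probability ``full_sib_rate`` a mating repeats an existing sire-dam
    pair, creating full sibs.

    Raises
    ------
    SizingError
        if a generation demands more offspring than the available dams can
        carry.
    """
    if min(n_generations, founders_per_sex, sires_per_generation) < 1:
        raise SizingError("all counts must be >= 1")
    if offspring_per_sire < 1:
        raise SizingError("offspring_per_sire must be >= 1")
    rng = np.random.default_rng(seed)

    records: list[tuple[str, str, str, str, int]] = []
    males: dict[int, list[str]] = {0: []}
    females: dict[int, list[str]] = {0: []}
    for i in range(founders_per_sex):
        mid, fid = f"G0M{i:04d}", f"G0F{i:04d}"
        records.append((mid, UNKNOWN_PARENT, UNKNOWN_PARENT, "M", 0))
        records.append((fid, UNKNOWN_PARENT, UNKNOWN_PARENT, "F", 0))
        males[0].append(mid)
        females[0].append(fid)

    n_offspring = int(round(sires_per_generation * offspring_per_sire))
    used_sires: set[str] = set()
    for gen in range(1, n_generations + 1):
        # fresh sires each generation: a paternal family then collects one
        # cohort of sons, keeping the mean family size near the target
        sire_pool = [
            m
            for m in males.get(gen - 1, []) + males.get(gen - 2, [])
            if m not in used_sires
        ]
        dam_pool = list(females.get(gen - 1, []))
        if len(dam_pool) * max_offspring_per_dam < n_offspring:
            raise SizingError(
                f"generation {gen}: {n_offspring} offspring demanded but only "
                f"{len(dam_pool)} dams x {max_offspring_per_dam} capacity available"
            )
        n_sires = min(sires_per_generation, len(sire_pool))
        sires = list(rng.choice(sire_pool, size=n_sires, replace=False))
        used_sires.update(sires)
        weights = rng.gamma(family_size_skew, 1.0, size=n_sires)
        weights /= weights.sum()
        # every selected sire gets at least one offspring, so the mean
        # half-sib family size stays at offspring_per_sire while the Gamma
        # weights produce the right-skewed tail (few very large families)
        counts = 1 + rng.multinomial(max(n_offspring - n_sires, 0), weights)

        dam_load = {d: 0 for d in dam_pool}
        pairings: dict[str, list[str]] = {s: [] for s in sires}
        males[gen], females[gen] = [], []
        k = 0
        for sire, cnt in zip(sires, counts):
            for _ in range(cnt):
                dam = None
                if pairings[sire] and rng.random() < full_sib_rate:
                    reuse = [d for d in pairings[sire] if dam_load[d] < max_offspring_per_dam]
                    if reuse:
                        dam = reuse[int(rng.integers(len(reuse)))]
                if dam is None:
                    open_dams = [d for d in dam_pool if dam_load[d] < max_offspring_per_dam]
                    dam = open_dams[int(rng.integers(len(open_dams)))]
                    pairings[sire].append(dam)
                dam_load[dam] += 1
                sex = "M" if rng.random() < 0.5 else "F"
                cid = f"G{gen}{sex}{k:04d}"
                k += 1
                records.append((cid, sire, dam, sex, gen))
                (males if sex == "M" else females)[gen].append(cid)

    table = pd.DataFrame(records, columns=["id", "sire", "dam", "sex", "birth_year"])
    return Pedigree(table)


# ---------------------------------------------------------------------------
# founder haplotypes
# ---------------------------------------------------------------------------

def _ascertain_panel(
    genotype_counts: np.ndarray,
    positions: np.ndarray,
    chrom_length_bp: int,
    n_markers: int,
    n_reserve: int,
    min_maf: float,
    rng: np.random.Generator,
    maf_flatten: bool,
    maf_weight_power: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick marker sites (one per evenly spaced window, MAF-weighted) and a
    reserve pool of additional sites for hidden QTL.  Returns (marker_idx,
    reserve_idx), both sorted by position."""
    freqs = genotype_counts
    maf = np.minimum(freqs, 1.0 - freqs)
    eligible = np.flatnonzero(maf > min_maf)
    if eligible.size < n_markers:
        raise SizingError(
            f"only {eligible.size} segregating sites above MAF {min_maf}; "
            f"cannot ascertain {n_markers} markers (increase mutation rate)"
        )
    edges = np.linspace(0, chrom_length_bp, n_markers + 1)
    window = np.clip(np.searchsorted(edges, positions[eligible], side="right") - 1, 0, n_markers - 1)
    chosen: list[int] = []
    taken = set()
    for w in range(n_markers):
        cand = eligible[window == w]
        cand = np.array([c for c in cand if c not in taken], dtype=np.intp)
        if cand.size == 0:
            continue
        p = maf[cand] ** maf_weight_power if maf_flatten else np.ones(cand.size)
        idx = int(rng.choice(cand, p=p / p.sum()))
        chosen.append(idx)
        taken.add(idx)
    # top up from leftover eligible sites if some windows were empty
    if len(chosen) < n_markers:
        leftovers = np.array([c for c in eligible if c not in taken], dtype=np.intp)
        extra = rng.choice(leftovers, size=n_markers - len(chosen), replace=False)
        chosen.extend(int(e) for e in extra)
        taken.update(int(e) for e in extra)
    marker_idx = np.sort(np.asarray(chosen, dtype=np.intp))
    leftovers = np.array([c for c in eligible if c not in taken], dtype=np.intp)
    n_res = min(n_reserve, leftovers.size)
    reserve_idx = (
        np.sort(rng.choice(leftovers, size=n_res, replace=False))
        if n_res > 0
        else np.empty(0, dtype=np.intp)
    )
    return marker_idx, reserve_idx


def simulate_founder_haplotypes(
    n_founders: int,
    n_chromosomes: int,
    n_snps_per_chrom: int,
    chrom_length_bp: int,
    *,
    effective_pop_size: float = 800.0,
    recombination_rate: float = 1e-8,
    mutation_rate: float | None = None,
    n_reserve_per_chrom: int = 0,
    min_maf: float = 0.03,
    maf_flatten: bool = True,
    maf_weight_power: float = 2.0,
    model: str = "coalescent",
    seed: int = 0,
) -> HaplotypeSet:
    """Simulate phased founder haplotypes with distance-decaying LD.

    The default backend is a neutral coalescent with recombination
    (msprime) under a constant effective population size; the genetic map
    is uniform at 1 cM per Mb (``recombination_rate`` = 1e-8 per bp).  The
    default ``effective_pop_size`` is calibrated so that a panel at the
    reference ~0.064 Mb marker spacing shows adjacent-pair mean r² near
    0.22 in founders.  Marker ascertainment keeps one site per window,
    sampled with probability proportional to MAF, which flattens the MAF
    spectrum (mean MAF ≈ 0.27 after the >3% filter), emulating SNP-chip
    site selection.

    ``model="independent"`` instead draws every allele independently
    (linkage equilibrium), with allele frequencies uniform on
    [min_maf, 1 − min_maf]; positions remain evenly spaced.

    ``n_reserve_per_chrom`` extra segregating sites are carried along with
    ``is_marker=False``; they are candidates for hidden QTL and never enter
    the genotyping panel.
    """
    if n_snps_per_chrom < 2:
        raise ValueError("need at least 2 SNPs per chromosome")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_founders
    ids = [f"FND{i:05d}" for i in range(n_founders)]

    alleles_parts: list[np.ndarray] = []
    map_parts: list[pd.DataFrame] = []
    for chrom in range(1, n_chromosomes + 1):
        if model == "independent":
            n_sites = n_snps_per_chrom + n_reserve_per_chrom
            freqs = rng.uniform(min_maf, 1.0 - min_maf, size=n_sites)
            hap = (rng.random((n_hap, n_sites)) < freqs).astype(np.int8)
            pos = np.linspace(1, chrom_length_bp, n_sites + 1)[:-1].astype(np.int64)
            pos = pos + np.arange(n_sites)  # strictly increasing
            is_marker = np.ones(n_sites, dtype=bool)
            if n_reserve_per_chrom:
                res = rng.choice(n_sites, size=n_reserve_per_chrom, replace=False)
                is_marker[res] = False
        elif model == "coalescent":
            mu = mutation_rate
            if mu is None:
                # aim for ~4x the requested number of sites before ascertainment
                a1 = np.sum(1.0 / np.arange(1, n_hap))
                target = 4.0 * (n_snps_per_chrom + n_reserve_per_chrom)
                mu = target / (4.0 * effective_pop_size * a1 * chrom_length_bp)
            anc_seed = int(rng.integers(1, 2**31 - 1))
            mut_seed = int(rng.integers(1, 2**31 - 1))
            ts = msprime.sim_ancestry(
                samples=n_founders,
                population_size=effective_pop_size,
                sequence_length=chrom_length_bp,
                recombination_rate=recombination_rate,
                random_seed=anc_seed,
            )
            ts = msprime.sim_mutations(
                ts, rate=mu, random_seed=mut_seed, model=msprime.BinaryMutationModel()
            )
            hap_all = ts.genotype_matrix().T.astype(np.int8)  # (n_hap, sites)
            hap_all = np.clip(hap_all, 0, 1)
            pos_all = ts.sites_position.astype(np.int64)
            # collapse duplicate integer positions (keep first)
            _, keep = np.unique(pos_all, return_index=True)
            hap_all, pos_all = hap_all[:, keep], pos_all[keep]
            marker_idx, reserve_idx = _ascertain_panel(
                hap_all.mean(axis=0),
                pos_all.astype(float),
                chrom_length_bp,
                n_snps_per_chrom,
                n_reserve_per_chrom,
                min_maf,
                rng,
                maf_flatten,
                maf_weight_power,
            )
            sel = np.sort(np.concatenate([marker_idx, reserve_idx]))
            hap = hap_all[:, sel]
            pos = pos_all[sel]
            is_marker = np.isin(sel, marker_idx)
        else:
            raise ValueError(f"unknown founder model {model!r}")

        alleles_parts.append(hap)
        map_parts.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "id": [f"SNP{chrom}_{p}" for p in pos],
                    "is_marker": is_marker,
                }
            )
        )

    hap_matrix = np.concatenate(alleles_parts, axis=1)
    alleles = hap_matrix.reshape(n_founders, 2, -1)
    snp_map = pd.concat(map_parts, ignore_index=True)
    return HaplotypeSet(ids, alleles, snp_map)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def _meiosis(
    parent: np.ndarray,
    chrom_starts: np.ndarray,
    chrom_ends: np.ndarray,
    positions: np.ndarray,
    recombination_rate: float,
    chrom_lengths: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from a (2, n_sites) parent: per chromosome, Poisson
    crossovers at uniform positions, alternating between the two parental
    haplotypes from a random starting phase."""
    gamete = np.empty(parent.shape[1], dtype=np.int8)
    for c in range(len(chrom_starts)):
        lo, hi = chrom_starts[c], chrom_ends[c]
        pos = positions[lo:hi]
        phase = int(rng.integers(2))
        n_x = rng.poisson(recombination_rate * chrom_lengths[c])
        if n_x == 0:
            gamete[lo:hi] = parent[phase, lo:hi]
            continue
        xovers = np.sort(rng.uniform(0, chrom_lengths[c], size=n_x))
        # phase at a site = start phase + number of crossovers before it
        flips = np.searchsorted(xovers, pos)
        site_phase = (phase + flips) % 2
        seg = parent[:, lo:hi]
        gamete[lo:hi] = np.where(site_phase == 0, seg[0], seg[1])
    return gamete


def gene_drop(
    pedigree: Pedigree,
    founder_haplotypes: HaplotypeSet,
    recombination_rate_per_bp: float = 1e-8,
    seed: int = 0,
) -> HaplotypeSet:
    """Drop founder haplotypes through the pedigree with crossovers.

    Founders are matched to ``founder_haplotypes`` rows in pedigree order.
    Every non-founder receives one recombined gamete from each parent.  An
    individual with exactly one known parent is not supported (the
    generators never produce one); a founder missing haplotypes raises
    :class:`LineageError`.
    """
    rng = np.random.default_rng(seed)
    founders = pedigree.founders
    if len(founders) > founder_haplotypes.n_individuals:
        raise LineageError(
            f"pedigree has {len(founders)} founders but only "
            f"{founder_haplotypes.n_individuals} founder haplotype pairs supplied"
        )
    snp_map = founder_haplotypes.snp_map
    chroms, starts = np.unique(snp_map["chrom"].to_numpy(), return_index=True)
    order = np.argsort(starts)
    chroms, starts = chroms[order], starts[order]
    ends = np.append(starts[1:], len(snp_map))
    positions = snp_map["pos"].to_numpy(float)
    chrom_lengths = np.array(
        [snp_map.loc[snp_map["chrom"] == c, "pos"].max() for c in chroms], dtype=float
    )

    n_sites = founder_haplotypes.n_sites
    ped_ids = pedigree.topological_order()
    alleles = np.zeros((len(ped_ids), 2, n_sites), dtype=np.int8)
    index = {i: k for k, i in enumerate(ped_ids)}

    founder_rows = founder_haplotypes.alleles
    for j, f in enumerate(founders):
        alleles[index[f]] = founder_rows[j]

    founder_set = set(founders)
    for ind in ped_ids:
        if ind in founder_set:
            continue
        sire, dam = pedigree.sire_of(ind), pedigree.dam_of(ind)
        if sire == UNKNOWN_PARENT or dam == UNKNOWN_PARENT:
            raise LineageError(f"individual {ind} has an unknown parent mid-pedigree")
        for h, parent in enumerate((sire, dam)):
            alleles[index[ind], h] = _meiosis(
                alleles[index[parent]],
                starts,
                ends,
                positions,
                recombination_rate_per_bp,
                chrom_lengths,
                rng,
            )
    return HaplotypeSet(ped_ids, alleles, snp_map.copy())


# ---------------------------------------------------------------------------
# trait architecture and phenotypes
# ---------------------------------------------------------------------------

class DegenerateArchitectureError(ValueError):
    """All QTL effects are zero (true breeding values have no variance)."""


@dataclass
class TraitArchitecture:
    """Additive QTL architecture for one trait.

    ``sigma2_a`` is the additive-genetic variance among founders after
    effect scaling; ``sigma2_e`` the residual variance of a single daughter
    record, implied by ``h2`` (heritability of a daughter record):
    ``sigma2_e = sigma2_a (1 - h2) / h2``.
    """

    trait: str
    qtl_ids: list[str]
    effects: np.ndarray
    sigma2_a: float
    h2: float

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("h2 must lie in (0, 1]")
        if self.sigma2_a <= 0:
            raise ValueError("sigma2_a must be positive")
        self.effects = np.asarray(self.effects, dtype=float)
        if len(self.effects) != len(self.qtl_ids):
            raise ValueError("one effect per QTL required")

    @property
    def sigma2_e(self) -> float:
        return self.sigma2_a * (1.0 - self.h2) / self.h2

    def breeding_values(self, haplotypes: HaplotypeSet) -> np.ndarray:
        lookup = {s: k for k, s in enumerate(haplotypes.snp_map["id"].astype(str))}
        try:
            cols = np.asarray([lookup[q] for q in self.qtl_ids], dtype=np.intp)
        except KeyError as err:
            raise KeyError(f"QTL {err} not on the haplotype map") from None
        dosage = haplotypes.alleles[:, :, cols].sum(axis=1)
        return dosage @ self.effects


def sample_architecture(
    founder_haplotypes: HaplotypeSet,
    n_qtl: int,
    sigma2_a: float,
    h2: float,
    *,
    trait: str = "trait",
    effect_distribution: str = "gamma",
    gamma_shape: float = 0.4,
    min_qtl_maf: float = 0.05,
    use_reserve_sites: bool = True,
    seed: int = 0,
) -> TraitArchitecture:
    """Draw QTL positions and additive effects, scaled so the realized
    founder breeding-value variance equals ``sigma2_a`` exactly.

    With ``use_reserve_sites`` (default) QTL are placed on reserve sites
    (hidden from the marker panel) so that prediction must work through
    marker-QTL LD; otherwise they sit on markers.  ``gamma`` effects
    (shape << 1, random sign) give the few-large-QTL architecture; use
    ``"normal"`` for a polygenic one.
    """
    rng = np.random.default_rng(seed)
    smap = founder_haplotypes.snp_map
    pool_mask = ~smap["is_marker"].to_numpy() if use_reserve_sites else smap["is_marker"].to_numpy()
    freqs = founder_haplotypes.alleles.mean(axis=(0, 1))
    maf = np.minimum(freqs, 1 - freqs)
    pool = np.flatnonzero(pool_mask & (maf >= min_qtl_maf))
    if pool.size < n_qtl:
        raise SizingError(
            f"only {pool.size} candidate QTL sites (need {n_qtl}); "
            "increase n_reserve_per_chrom or lower min_qtl_maf"
        )
    qtl_sites = np.sort(rng.choice(pool, size=n_qtl, replace=False))
    if effect_distribution == "gamma":
        effects = rng.gamma(gamma_shape, 1.0, size=n_qtl) * rng.choice((-1.0, 1.0), size=n_qtl)
    elif effect_distribution == "normal":
        effects = rng.normal(0.0, 1.0, size=n_qtl)
    else:
        raise ValueError(f"unknown effect distribution {effect_distribution!r}")
    qtl_ids = [str(s) for s in smap["id"].iloc[qtl_sites]]
    arch = TraitArchitecture(trait, qtl_ids, effects, sigma2_a, h2)
    g = arch.breeding_values(founder_haplotypes)
    var_g = float(np.var(g))
    if var_g <= 0:
        raise DegenerateArchitectureError("founder breeding values have zero variance")
    arch.effects = arch.effects * np.sqrt(sigma2_a / var_g)
    return arch


def lognormal_daughter_counts(
    rng: np.random.Generator,
    size: int,
    *,
    median: float = 120.0,
    sigma: float = 0.8,
    low: int = 30,
    high: int = 5000,
) -> np.ndarray:
    """Right-skewed daughter counts: log-normal, clipped to [low, high].

    Defaults span the tens-to-thousands range reported for progeny-tested
    bulls (recent cohorts near 100 daughters, old proven sires in the
    thousands), with the progeny-test entry floor of 30 daughters.
    """
    n = np.exp(rng.normal(np.log(median), sigma, size=size))
    return np.clip(np.round(n), low, high).astype(int)


def simulate_phenotypes(
    haplotypes: HaplotypeSet,
    architecture: TraitArchitecture,
    bull_ids: Sequence[str],
    daughters_per_bull: Callable[[np.random.Generator, int], np.ndarray] | Sequence[int] | None = None,
    seed: int = 0,
) -> PhenotypeTable:
    """Simulate DYDs for the given bulls.

    The DYD of bull *i* is ``y_i = g_i + eps_i`` with ``Var(eps_i) =
    sigma2_a (1 - r_i^2)/r_i^2`` where ``r_i = dyd_accuracy(n_i, h2)`` is
    the selection-index progeny-test accuracy for ``n_i`` daughters, so
    that corr(g, y) = r_i by construction and the regression of y on g has
    slope one (DYDs are unshrunken).  The reliability weight is ``w_i =
    r_i^2``.

    Raises
    ------
    DegenerateArchitectureError
        if the architecture gives the bulls zero genetic variance (corr(g, y)
        would be undefined).
    """
    rng = np.random.default_rng(seed)
    bull_ids = [str(b) for b in bull_ids]
    sub = haplotypes.subset(ids=bull_ids)
    g = architecture.breeding_values(sub)
    if np.var(g) <= 0 or not np.any(architecture.effects != 0):
        raise DegenerateArchitectureError(
            "breeding values are constant; DYD accuracy is undefined"
        )
    if daughters_per_bull is None:
        n_daughters = lognormal_daughter_counts(rng, len(bull_ids))
    elif callable(daughters_per_bull):
        n_daughters = np.asarray(daughters_per_bull(rng, len(bull_ids)), dtype=int)
    else:
        n_daughters = np.asarray(daughters_per_bull, dtype=int)
        if len(n_daughters) != len(bull_ids):
            raise ValueError("daughter counts must match the number of bulls")
    if (n_daughters < 1).any():
        raise ValueError("daughter counts must be >= 1")

    r = dyd_accuracy(n_daughters, architecture.h2)
    noise_sd = np.sqrt(architecture.sigma2_a * (1.0 - r**2) / r**2)
    y = g + rng.normal(0.0, 1.0, size=len(bull_ids)) * noise_sd
    table = pd.DataFrame(
        {
            "id": bull_ids,
            "trait": architecture.trait,
            "dyd": y,
            "n_daughters": n_daughters,
            "weight": r**2,
            "tbv": g,
        }
    )
    return PhenotypeTable(table)
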