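"""SNP quality control: X-heterozygote masking, missingness/MAF filtering,
and naive imputation of the surviving missing calls.

The filter pipeline mirrors routine SNP-chip editing in dairy cattle
evaluations: male heterozygote calls on the non-pseudo-autosomal X are set
to missing first (males are hemizygous there, so a heterozygous call is a
genotyping artefact), then SNPs are kept only when their missing rate is
strictly below 5% and their minor allele frequency strictly above 3%.
Allele frequencies are always computed over non-missing calls after the
X-masking step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import GenotypeData

__all__ = ["mask_x_heterozygotes", "filter_snps", "impute_missing", "EmptyPanelError"]


class EmptyPanelError(ValueError):
    """Filtering removed every SNP."""


def mask_x_heterozygotes(genotypes: GenotypeData) -> GenotypeData:
    """Set male heterozygote calls on the non-pseudo-autosomal X to missing.

    Requires ``genotypes.x_chromosome`` to name the X chromosome in the SNP
    map and an ``is_par`` column flagging pseudo-autosomal SNPs; if the data
    carry no X chromosome the input is returned unchanged (autosome-only
    panels are common in simulation).
    """
    out = genotypes.copy()
    if genotypes.x_chromosome is None:
        return out
    smap = out.snp_map
    is_par = smap["is_par"].to_numpy(bool) if "is_par" in smap.columns else np.zeros(len(smap), bool)
    x_cols = (smap["chrom"] == genotypes.x_chromosome).to_numpy() & ~is_par
    male_rows = np.asarray([out.sex.get(i) == "M" for i in out.ids])
    if not x_cols.any() or not male_rows.any():
        return out
    block = out.matrix[np.ix_(male_rows, x_cols)]
    block[block == 1.0] = np.nan
    out.matrix[np.ix_(male_rows, x_cols)] = block
    return out


def filter_snps(
    genotypes: GenotypeData,
    max_missing_rate: float = 0.05,
    min_maf: float = 0.03,
) -> tuple[GenotypeData, pd.DataFrame]:
    """Keep SNPs with missing rate < ``max_missing_rate`` and MAF > ``min_maf``.

    Both thresholds are strict inequalities.  Returns the filtered data and
    an exclusion log with one row per removed SNP (columns ``id, reason``;
    a SNP failing both tests is logged once, as ``missingness``, the first
    test applied).

    Raises
    ------
    EmptyPanelError
        if no SNP survives.
    """
    for name, t in (("max_missing_rate", max_missing_rate), ("min_maf", min_maf)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    miss = genotypes.missing_rates()
    all_missing = miss >= 1.0
    maf = genotypes.minor_allele_frequencies()
    fail_missing = miss >= max_missing_rate
    fail_maf = ~fail_missing & (all_missing | ~(maf > min_maf))
    keep = ~(fail_missing | fail_maf)
    if not keep.any():
        raise EmptyPanelError("no SNP passed the missingness/MAF filter")

    snp_ids = np.asarray(genotypes.snp_ids)
    log = pd.DataFrame(
        {
            "id": np.concatenate([snp_ids[fail_missing], snp_ids[fail_maf]]),
            "reason": ["missingness"] * int(fail_missing.sum()) + ["maf"] * int(fail_maf.sum()),
        }
    )
    filtered = GenotypeData(
        list(genotypes.ids),
        genotypes.matrix[:, keep],
        genotypes.snp_map.loc[keep].reset_index(drop=True),
        dict(genotypes.sex),
        genotypes.x_chromosome,
    )
    return filtered, log


def impute_missing(
    genotypes: GenotypeData,
    method: str = "mean_rounded",
    seed: int = 0,
) -> GenotypeData:
    """Fill missing calls in place of the out-of-scope phasing step.

    ``mean_rounded`` replaces a missing call with the SNP's mean non-missing
    dosage rounded to the nearest code in {0, 1, 2}; ``allele_frequency_draw``
    draws two alleles at the SNP's observed frequency.  Non-missing calls
    are never altered.

    Raises
    ------
    ValueError
        if a SNP has no non-missing call to impute from (the SNP is named).
    """
    if method not in ("mean_rounded", "allele_frequency_draw"):
        raise ValueError(f"unknown imputation method {method!r}")
    out = genotypes.copy()
    missing = np.isnan(out.matrix)
    if not missing.any():
        return out
    dead = missing.all(axis=0)
    if dead.any():
        names = [out.snp_ids[i] for i in np.flatnonzero(dead)[:5]]
        raise ValueError(f"cannot impute SNPs with all calls missing: {names}")
    rng = np.random.default_rng(seed)
    if method == "mean_rounded":
        col_mean = np.nanmean(out.matrix, axis=0)
        fill = np.clip(np.round(col_mean), 0, 2)
        out.matrix[missing] = np.broadcast_to(fill, out.matrix.shape)[missing]
    else:
        p = np.nanmean(out.matrix, axis=0) / 2.0
        draws = rng.binomial(2, np.broadcast_to(p, out.matrix.shape)).astype(float)
        out.matrix[missing] = draws[missing]
    return out
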