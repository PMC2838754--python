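"""Plain-text readers and writers for the pipeline's interchange formats.

Formats
-------
* pedigree CSV: ``id,sire,dam,sex,birth_year`` with ``0`` for an unknown
  parent;
* genotype TSV: rows = individuals, columns = SNP ids, cells in
  {0, 1, 2, NA};
* SNP map TSV: PLINK-style ``chrom  id  cM  bp`` (cM taken as bp / 1e6
  under the uniform 1 cM ≈ 1 Mb map);
* phenotype TSV: ``id  trait  dyd  n_daughters  weight  tbv``;
* VCF: written with phased ``|`` separators when haplotypes are known and
  ``/`` for unphased dosages; read through cyvcf2 when available.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .data import GenotypeData, HaplotypeSet, Pedigree, PhenotypeTable


# -- pedigree ---------------------------------------------------------------

def write_pedigree_csv(pedigree: Pedigree, path: str | os.PathLike) -> None:
    pedigree.table.to_csv(path, index=False)


def read_pedigree_csv(path: str | os.PathLike) -> Pedigree:
    table = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str, "sex": str})
    return Pedigree(table)


# -- genotype matrix / map --------------------------------------------------

def write_genotypes_tsv(genotypes: GenotypeData, path: str | os.PathLike) -> None:
    frame = pd.DataFrame(genotypes.matrix, index=genotypes.ids, columns=genotypes.snp_ids)
    frame = frame.astype("Int64")
    frame.to_csv(path, sep="\t", index_label="id", na_rep="NA")


def read_genotypes_tsv(
    path: str | os.PathLike,
    snp_map: pd.DataFrame,
    sex: Mapping[str, str] | None = None,
    x_chromosome=None,
) -> GenotypeData:
    frame = pd.read_csv(path, sep="\t", index_col="id", na_values="NA")
    frame = frame[[str(s) for s in snp_map["id"]]]
    return GenotypeData(
        [str(i) for i in frame.index],
        frame.to_numpy(float),
        snp_map,
        dict(sex) if sex else {},
        x_chromosome,
    )


def write_snp_map_tsv(snp_map: pd.DataFrame, path: str | os.PathLike) -> None:
    out = pd.DataFrame(
        {
            "chrom": snp_map["chrom"],
            "id": snp_map["id"],
            "cM": snp_map["pos"] / 1e6,
            "bp": snp_map["pos"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_snp_map_tsv(path: str | os.PathLike) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    return pd.DataFrame({"chrom": raw["chrom"], "pos": raw["bp"], "id": raw["id"].astype(str)})


# -- phenotypes -------------------------------------------------------------

def write_phenotypes_tsv(phenotypes: PhenotypeTable, path: str | os.PathLike) -> None:
    phenotypes.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes_tsv(path: str | os.PathLike) -> PhenotypeTable:
    table = pd.read_csv(path, sep="\t", dtype={"id": str, "trait": str}, na_values="NA")
    return PhenotypeTable(table)


# -- VCF --------------------------------------------------------------------

def write_vcf(
    data: HaplotypeSet | GenotypeData,
    path: str | os.PathLike,
) -> None:
    """Write genotypes as an uncompressed VCF (GT only).

    Haplotype input is written phased (``0|1``); dosage input unphased
    (``0/1``), with ``./.`` for missing calls.
    """
    phased = isinstance(data, HaplotypeSet)
    smap = data.snp_map
    ids = data.ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(smap["chrom"]):
            length = int(smap.loc[smap["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        if phased:
            alleles = data.alleles
            for j in range(len(smap)):
                calls = "\t".join(f"{alleles[i, 0, j]}|{alleles[i, 1, j]}" for i in range(len(ids)))
                row = smap.iloc[j]
                fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\tA\tB\t.\t.\t.\tGT\t{calls}\n")
        else:
            codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
            m = data.matrix
            for j in range(len(smap)):
                calls = "\t".join(
                    "./." if np.isnan(m[i, j]) else codes[m[i, j]] for i in range(len(ids))
                )
                row = smap.iloc[j]
                fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\tA\tB\t.\t.\t.\tGT\t{calls}\n")


def read_vcf(path: str | os.PathLike, sex: Mapping[str, str] | None = None, x_chromosome=None) -> GenotypeData:
    """Read a VCF into a dosage matrix (requires cyvcf2).

    The dosage counts ALT copies, so a VCF written by :func:`write_vcf`
    round-trips exactly.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, chroms, poss, snp_ids = [], [], [], []
    for var in vcf:
        arr = var.genotype.array()
        dose = arr[:, 0].astype(float) + arr[:, 1].astype(float)
        dose[(arr[:, 0] < 0) | (arr[:, 1] < 0)] = np.nan
        rows.append(dose)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"SNP{var.CHROM}_{var.POS}")
    smap = pd.DataFrame({"chrom": chroms, "pos": poss, "id": snp_ids})
    try:
        smap["chrom"] = smap["chrom"].astype(int)
    except ValueError:
        pass
    return GenotypeData(ids, np.column_stack(rows) if rows else np.empty((len(ids), 0)),
                        smap, dict(sex) if sex else {}, x_chromosome)


# -- splits and results -----------------------------------------------------

def write_splits_tsv(splits, path: str | os.PathLike) -> None:
    rows = []
    for s in splits:
        for role, members in (("train", s.train), ("val", s.val), ("excluded", s.excluded)):
            rows.extend({"replicate": s.replicate, "a_max": s.a_max, "role": role, "id": m} for m in members)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_relationship_tsv(matrix, path: str | os.PathLike) -> None:
    frame = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    frame.to_csv(path, sep="\t", index_label="id", float_format="%.6g")
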