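"""Core data containers shared across the pipeline.

The package moves four kinds of objects between stages: a :class:`Pedigree`
(the bull pedigree with sire/dam links), a :class:`HaplotypeSet` (phased
biallelic haplotypes on a physical SNP map), a :class:`GenotypeData`
(unphased 0/1/2 dosage matrix, possibly with missing calls), and a
:class:`PhenotypeTable` (daughter yield deviations with daughter counts and
reliability weights).  All containers are thin wrappers over pandas/numpy
objects so that downstream code can stay vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UNKNOWN_PARENT = "0"

PEDIGREE_COLUMNS = ["id", "sire", "dam", "sex", "birth_year"]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycles, missing parents, sex clash)."""


class SizingError(ValueError):
    """A simulation configuration that cannot be realised (e.g. too few dams)."""


class LineageError(ValueError):
    """A pedigree individual required by gene dropping has no haplotypes."""


@dataclass
class Pedigree:
    """A multi-generation pedigree.

    Parameters
    ----------
    table:
        DataFrame with columns ``id, sire, dam, sex, birth_year``.  Unknown
        parents are coded ``"0"``.  Sex is ``"M"`` or ``"F"``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        missing = [c for c in PEDIGREE_COLUMNS if c not in self.table.columns]
        if missing:
            raise PedigreeError(f"pedigree table lacks columns {missing}")
        self._index: dict[str, int] = {
            str(i): k for k, i in enumerate(self.table["id"].astype(str))
        }
        if len(self._index) != len(self.table):
            raise PedigreeError("duplicate individual ids in pedigree")
        self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return list(self.table["id"].astype(str))

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, item: str) -> bool:
        return str(item) in self._index

    def sire_of(self, ind: str) -> str:
        return str(self.table.at[self._index[str(ind)], "sire"])

    def dam_of(self, ind: str) -> str:
        return str(self.table.at[self._index[str(ind)], "dam"])

    def sex_of(self, ind: str) -> str:
        return str(self.table.at[self._index[str(ind)], "sex"])

    def birth_year_of(self, ind: str) -> int:
        return int(self.table.at[self._index[str(ind)], "birth_year"])

    @property
    def founders(self) -> list[str]:
        t = self.table
        mask = (t["sire"].astype(str) == UNKNOWN_PARENT) & (
            t["dam"].astype(str) == UNKNOWN_PARENT
        )
        return list(t.loc[mask, "id"].astype(str))

    @property
    def males(self) -> list[str]:
        return list(self.table.loc[self.table["sex"] == "M", "id"].astype(str))

    def offspring_of(self, ind: str) -> list[str]:
        ind = str(ind)
        t = self.table
        mask = (t["sire"].astype(str) == ind) | (t["dam"].astype(str) == ind)
        return list(t.loc[mask, "id"].astype(str))

    def paternal_family_of(self, ind: str) -> str:
        """Family key for the 'at most two validation bulls per paternal
        half-sib family' rule; unknown-sire individuals form singleton
        families keyed by their own id."""
        sire = self.sire_of(ind)
        return f"sire:{sire}" if sire != UNKNOWN_PARENT else f"solo:{ind}"

    def topological_order(self) -> list[str]:
        """Ids sorted parents-before-offspring (birth year is a witness)."""
        return list(
            self.table.sort_values(["birth_year", "id"], kind="stable")["id"].astype(str)
        )

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        t = self.table
        for role, expected_sex in (("sire", "M"), ("dam", "F")):
            parents = set(t[role].astype(str)) - {UNKNOWN_PARENT}
            unknown = parents - set(self._index)
            if unknown:
                raise PedigreeError(
                    f"{role}s {sorted(unknown)[:5]} not present as pedigree records"
                )
            for p in parents:
                if self.sex_of(p) != expected_sex:
                    raise PedigreeError(f"{role} {p} has sex {self.sex_of(p)}")
        ids = t["id"].astype(str).to_numpy()
        years = t["birth_year"].to_numpy()
        year_of = dict(zip(ids, years))
        for _, row in t.iterrows():
            for parent in (str(row["sire"]), str(row["dam"])):
                if parent != UNKNOWN_PARENT and year_of[parent] >= row["birth_year"]:
                    raise PedigreeError(
                        f"parent {parent} born {year_of[parent]} not before "
                        f"offspring {row['id']} born {row['birth_year']}"
                    )
        # birth-year ordering of parents before offspring implies acyclicity

    # -- summaries ---------------------------------------------------------
    def half_sib_family_sizes(self) -> pd.Series:
        """Paternal half-sib family sizes (offspring counted per known sire)."""
        sires = self.table["sire"].astype(str)
        sizes = sires[sires != UNKNOWN_PARENT].value_counts()
        sizes.name = "family_size"
        return sizes


@dataclass
class HaplotypeSet:
    """Phased haplotypes for a set of individuals.

    ``alleles`` has shape ``(n_individuals, 2, n_sites)`` with values in
    {0, 1}.  ``snp_map`` has columns ``chrom, pos, id`` plus an
    ``is_marker`` flag separating the genotyping panel from reserve sites
    (QTL candidates hidden from the marker panel).
    """

    ids: list[str]
    alleles: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 3 or self.alleles.shape[1] != 2:
            raise ValueError("alleles must have shape (n, 2, n_sites)")
        if self.alleles.shape[0] != len(self.ids):
            raise ValueError("ids and alleles disagree on individual count")
        if self.alleles.shape[2] != len(self.snp_map):
            raise ValueError("snp_map and alleles disagree on site count")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele values must be 0/1")
        if "is_marker" not in self.snp_map.columns:
            self.snp_map = self.snp_map.assign(is_marker=True)
        self.snp_map = self.snp_map.reset_index(drop=True)
        for _, sub in self.snp_map.groupby("chrom"):
            if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
                raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[2]

    def index_of(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {i: k for k, i in enumerate(self.ids)}
        return np.asarray([lookup[str(i)] for i in ids], dtype=np.intp)

    def genotypes(self) -> np.ndarray:
        """Unphased dosage matrix (n_individuals, n_sites)."""
        return self.alleles.sum(axis=1).astype(np.int8)

    def subset(self, ids: Sequence[str] | None = None, sites: np.ndarray | None = None) -> "HaplotypeSet":
        idx = self.index_of(ids) if ids is not None else np.arange(self.n_individuals)
        keep_ids = [self.ids[i] for i in idx]
        alleles = self.alleles[idx]
        snp_map = self.snp_map
        if sites is not None:
            alleles = alleles[:, :, sites]
            snp_map = snp_map.iloc[sites]
        return HaplotypeSet(keep_ids, alleles, snp_map.reset_index(drop=True))

    def markers_only(self) -> "HaplotypeSet":
        return self.subset(sites=np.flatnonzero(self.snp_map["is_marker"].to_numpy()))


@dataclass
class GenotypeData:
    """Unphased genotypes (0/1/2 dosage of the reference allele, NaN missing).

    ``snp_map`` columns: ``chrom, pos, id`` and optionally ``is_par`` (the
    pseudo-autosomal flag used by the X-heterozygote masking rule).  ``sex``
    maps individual ids to "M"/"F".
    """

    ids: list[str]
    matrix: np.ndarray
    snp_map: pd.DataFrame
    sex: Mapping[str, str] = field(default_factory=dict)
    x_chromosome: int | str | None = None

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.ids), len(self.snp_map)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.snp_map)} SNPs"
            )
        valid = np.isnan(self.matrix) | np.isin(self.matrix, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")
        self.snp_map = self.snp_map.reset_index(drop=True)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_map["id"].astype(str))

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Reference-allele frequency per SNP over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.matrix, axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def missing_rates(self) -> np.ndarray:
        return np.isnan(self.matrix).mean(axis=0)

    def is_complete(self) -> bool:
        return not np.isnan(self.matrix).any()

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeData":
        lookup = {i: k for k, i in enumerate(self.ids)}
        idx = [lookup[str(i)] for i in ids]
        return GenotypeData(
            [self.ids[i] for i in idx],
            self.matrix[idx],
            self.snp_map.copy(),
            dict(self.sex),
            self.x_chromosome,
        )

    def copy(self) -> "GenotypeData":
        return GenotypeData(
            list(self.ids), self.matrix.copy(), self.snp_map.copy(),
            dict(self.sex), self.x_chromosome,
        )


def genotype_data_from_haplotypes(
    haplotypes: HaplotypeSet,
    sex: Mapping[str, str] | None = None,
    ids: Sequence[str] | None = None,
) -> GenotypeData:
    """Collapse phased haplotypes (marker sites only) into a dosage matrix."""
    haps = haplotypes.markers_only()
    if ids is not None:
        haps = haps.subset(ids=ids)
    return GenotypeData(
        haps.ids,
        haps.genotypes().astype(float),
        haps.snp_map.drop(columns=["is_marker"]),
        dict(sex) if sex else {},
    )


PHENOTYPE_COLUMNS = ["id", "trait", "dyd", "n_daughters", "weight", "tbv"]


@dataclass
class PhenotypeTable:
    """Per-bull daughter yield deviations (DYDs).

    Columns: ``id, trait, dyd, n_daughters, weight, tbv``; ``tbv`` (the true
    breeding value) is only available in simulation and is NaN for file
    inputs.  The reliability ``weight`` is the squared selection-index
    accuracy of the bull's DYD.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns {missing}")
        self.table = self.table.reset_index(drop=True)
        t = self.table
        if (t["n_daughters"] < 1).any():
            raise ValueError("daughter counts must be >= 1")
        w = t["weight"].to_numpy(float)
        if ((w <= 0) | (w > 1)).any():
            raise ValueError("reliability weights must lie in (0, 1]")
        if t.duplicated(["id", "trait"]).any():
            raise ValueError("one row per bull per trait expected")

    @property
    def traits(self) -> list[str]:
        return list(pd.unique(self.table["trait"]))

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.table[self.table["trait"] == trait]
        if sub.empty:
            raise KeyError(f"no phenotypes for trait {trait!r}")
        return sub.reset_index(drop=True)

    def subset(self, ids: Sequence[str], trait: str | None = None) -> pd.DataFrame:
        t = self.for_trait(trait) if trait is not None else self.table
        sub = t.set_index("id").loc[[str(i) for i in ids]].reset_index()
        return sub
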