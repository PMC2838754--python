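"""Numerator (pedigree) and genomic relationship matrices.

``A`` is built by the tabular method: individuals are processed parents
first, each off-diagonal row is the parent-row average, and the diagonal is
1 plus half the parents' relationship (inbreeding).  ``G`` is the centered
cross-product form

    G = sum_k (x_k - 2 p_k 1)(x_k - 2 p_k 1)' / (2 sum_k p_k (1 - p_k)),

the standard realized-relationship matrix; with SNP effects given a common
normal prior this makes the animal model on G algebraically identical to
ridge-regression BLUP on the SNP dosages, an equivalence the test suite
asserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .data import GenotypeData, Pedigree, PedigreeError, UNKNOWN_PARENT

__all__ = [
    "RelationshipMatrix",
    "numerator_relationship_matrix",
    "genomic_relationship_matrix",
    "max_relationship",
]


class DesignError(ValueError):
    """Invalid set query (overlapping or empty train/validation sets)."""


class MonomorphicPanelError(ValueError):
    """All SNPs monomorphic: the genomic-relationship denominator is zero."""


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix over an ordered id list."""

    ids: list[str]
    values: np.ndarray
    kind: str  # "numerator" | "genomic"
    frequencies: np.ndarray | None = None
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        if self.kind not in ("numerator", "genomic"):
            raise ValueError("kind must be 'numerator' or 'genomic'")
        if self.kind == "numerator":
            if (np.diag(self.values) < 1.0 - 1e-12).any() or (self.values < -1e-12).any():
                raise ValueError("numerator matrix needs diagonal >= 1 and entries >= 0")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def indices(self, ids: Iterable[str]) -> np.ndarray:
        try:
            return np.asarray([self._index[str(i)] for i in ids], dtype=np.intp)
        except KeyError as err:
            raise KeyError(f"id {err} not covered by this relationship matrix") from None

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        idx = self.indices(ids)
        return RelationshipMatrix(
            [str(i) for i in ids], self.values[np.ix_(idx, idx)], self.kind, self.frequencies
        )

    def between(self, rows: Sequence[str], cols: Sequence[str]) -> np.ndarray:
        return self.values[np.ix_(self.indices(rows), self.indices(cols))]


def numerator_relationship_matrix(
    pedigree: Pedigree, subset_ids: Sequence[str] | None = None
) -> RelationshipMatrix:
    """Tabular-method numerator relationship matrix.

    Unknown parents are treated as unrelated, non-inbred founders.  The full
    recursion always runs over the whole pedigree; ``subset_ids`` selects the
    returned submatrix.
    """
    order = pedigree.topological_order()
    index = {i: k for k, i in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for ind in order:
        i = index[ind]
        s, d = pedigree.sire_of(ind), pedigree.dam_of(ind)
        si = index[s] if s != UNKNOWN_PARENT else None
        di = index[d] if d != UNKNOWN_PARENT else None
        if si is not None and si >= i or di is not None and di >= i:
            raise PedigreeError("pedigree is not sorted parents-before-offspring")
        row = np.zeros(i)
        if si is not None:
            row += 0.5 * A[si, :i]
        if di is not None:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    if subset_ids is None:
        return RelationshipMatrix(order, A, "numerator")
    idx = [index[str(i)] for i in subset_ids]
    return RelationshipMatrix([str(i) for i in subset_ids], A[np.ix_(idx, idx)], "numerator")


def genomic_relationship_matrix(
    genotypes: GenotypeData, frequencies: np.ndarray | None = None
) -> RelationshipMatrix:
    """Centered cross-product genomic relationship matrix.

    ``frequencies`` defaults to the allele frequencies observed in the
    supplied individuals (training and validation bulls pooled); supply
    external (e.g. base-population) frequencies to override.
    """
    if not genotypes.is_complete():
        raise ValueError("genotypes must be complete (run QC/imputation first)")
    if genotypes.n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    p = np.asarray(
        frequencies if frequencies is not None else genotypes.allele_frequencies(),
        dtype=float,
    )
    if p.shape != (genotypes.n_snps,):
        raise ValueError("one allele frequency per SNP required")
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0.0:
        raise MonomorphicPanelError("all SNPs monomorphic; G denominator is zero")
    Z = genotypes.matrix - 2.0 * p
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(list(genotypes.ids), G, "genomic", frequencies=p)


def max_relationship(
    matrix: RelationshipMatrix, set_train: Sequence[str], set_val: Sequence[str]
) -> float:
    """Maximum relationship between any training and any validation id."""
    train = [str(i) for i in set_train]
    val = [str(i) for i in set_val]
    if not train or not val:
        raise DesignError("both sets must be nonempty")
    if set(train) & set(val):
        raise DesignError("training and validation sets overlap")
    return float(matrix.between(train, val).max())
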