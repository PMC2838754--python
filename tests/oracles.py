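"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: the relationship
oracle estimates identity-by-descent by dropping founder allele labels
through the pedigree and counting label matches; the split oracle
enumerates every admissible validation set exhaustively; the ridge oracle
solves the weighted posterior mean directly from the joint normal
equations.
"""

from __future__ import annotations

import itertools

import numpy as np

from ldacc.data import Pedigree, UNKNOWN_PARENT


def allele_drop_relationships(
    pedigree: Pedigree, n_replicates: int = 1000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Monte-Carlo additive relationships by founder-label dropping.

    Each replicate assigns every founder two unique allele labels and drops
    them through the pedigree (one random allele per parent, no linkage).
    The additive relationship estimate between i and j is twice the
    coancestry: half the average number of label matches over the four
    allele pairings.  Returns (mean, standard error, id order).
    """
    rng = np.random.default_rng(seed)
    order = pedigree.topological_order()
    idx = {i: k for k, i in enumerate(order)}
    n = len(order)
    sums = np.zeros((n, n))
    sq = np.zeros((n, n))
    for _ in range(n_replicates):
        labels = np.zeros((n, 2), dtype=np.int64)
        next_label = 1
        for ind in order:
            k = idx[ind]
            s, d = pedigree.sire_of(ind), pedigree.dam_of(ind)
            for h, parent in enumerate((s, d)):
                if parent == UNKNOWN_PARENT:
                    labels[k, h] = next_label
                    next_label += 1
                else:
                    labels[k, h] = labels[idx[parent], int(rng.integers(2))]
        # a_ij = 2 * f_ij ; f_ij = (1/4) sum over allele pairs 1[label match]
        match = (
            (labels[:, None, :, None] == labels[None, :, None, :])
            .sum(axis=(2, 3))
            .astype(float)
        )
        a = match / 2.0
        # diagonal: a_ii = 1 + F_i with F_i = P(the two own alleles IBD)
        own = (labels[:, 0] == labels[:, 1]).astype(float)
        np.fill_diagonal(a, 1.0 + own)
        sums += a
        sq += a * a
    mean = sums / n_replicates
    var = sq / n_replicates - mean**2
    se = np.sqrt(np.maximum(var, 0.0) / n_replicates)
    return mean, se, order


def enumerate_min_exclusions(
    A: np.ndarray,
    ids: list[str],
    pedigree: Pedigree,
    a_max: float,
    val_size: int,
    max_per_family: int = 2,
    forbid_sires: bool = True,
) -> tuple[int, list[tuple]]:
    """Exhaustive search over validation sets of exactly ``val_size``.

    Returns the minimum number of a_max exclusions over all admissible
    validation sets and the list of optimal sets.  Only viable for toy
    candidate lists (combinatorial)."""
    pos = {c: k for k, c in enumerate(ids)}
    best = None
    optimal = []
    for combo in itertools.combinations(ids, val_size):
        fams = [pedigree.paternal_family_of(v) for v in combo]
        if any(fams.count(f) > max_per_family for f in set(fams)):
            continue
        if forbid_sires and a_max >= 0.5:
            if any(
                o in pos and o not in combo
                for v in combo
                for o in pedigree.offspring_of(v)
            ):
                continue
        vi = [pos[v] for v in combo]
        rest = [pos[c] for c in ids if c not in combo]
        n_excl = int((A[np.ix_(rest, vi)].max(axis=1) > a_max).sum())
        if best is None or n_excl < best:
            best, optimal = n_excl, [combo]
        elif n_excl == best:
            optimal.append(combo)
    if best is None:
        raise ValueError("no admissible validation set of that size")
    return best, optimal


def weighted_ridge_gebv(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    p: np.ndarray,
    sigma2_a: float,
    sigma2_e: float,
    X_target: np.ndarray,
) -> np.ndarray:
    """Closed-form weighted ridge GEBVs from the joint normal equations for
    (intercept, SNP effects) with common effect variance sigma2_a/sum 2pq."""
    Xc = X - 2 * p
    lam = sigma2_e / (sigma2_a / (2 * np.sum(p * (1 - p))))
    K = X.shape[1]
    C = np.zeros((K + 1, K + 1))
    C[0, 0] = w.sum()
    C[0, 1:] = w @ Xc
    C[1:, 0] = C[0, 1:]
    C[1:, 1:] = Xc.T @ (Xc * w[:, None]) + lam * np.eye(K)
    rhs = np.concatenate([[w @ y], Xc.T @ (w * y)])
    sol = np.linalg.solve(C, rhs)
    return (X_target - 2 * p) @ sol[1:]
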