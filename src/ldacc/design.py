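"""Relationship-constrained training/validation splits.

A split is valid when no training bull has a pedigree relationship above
``a_max`` with any validation bull, at most two validation bulls come from
one paternal half-sib family, no validation bull is the sire of a training
bull, and (across replicates) no bull is validated twice.  Bulls that would
violate the a_max cap against the chosen validation set are excluded from
the analysis entirely; the sampler is a randomized greedy that retries the
validation draw and keeps the assignment with the fewest exclusions.  A
brute-force enumeration oracle in the test suite bounds the greedy's
optimality gap on toy pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data import Pedigree
from .relationships import RelationshipMatrix, max_relationship

__all__ = ["SplitConstraints", "Split", "sample_splits", "downsample_training", "InfeasibleSplitError"]


class InfeasibleSplitError(ValueError):
    """Constraints cannot be satisfied; the message names the binding one."""


@dataclass
class SplitConstraints:
    """Constraint set for one a_max scenario.

    Defaults mirror the reference design: training size 2,096 (half:
    1,048), 15 replicate pairs, minimum validation size 30 (11 for the
    smallest a_max), at most two validation bulls per paternal half-sib
    family, sires of training bulls barred from validation, and validation
    bulls never reused across replicates.
    """

    a_max: float
    train_size: int = 2096
    val_size: int = 33
    min_val_size: int = 30
    max_per_half_sib_family: int = 2
    forbid_sires_of_training: bool = True
    unique_validation: bool = True
    n_replicates: int = 15
    n_tries: int = 30
    protect_threshold: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.a_max <= 2.0:
            raise ValueError("a_max must lie in (0, 2]")
        if min(self.train_size, self.val_size, self.min_val_size, self.n_replicates) < 1:
            raise ValueError("sizes and replicate count must be positive")


@dataclass
class Split:
    replicate: int
    a_max: float
    train: list[str]
    val: list[str]
    excluded: list[str] = field(default_factory=list)
    realized_max: float = float("nan")

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.val), set(self.excluded)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("train/val/excluded sets must be pairwise disjoint")


def _draw_validation(
    candidates: list[str],
    pedigree: Pedigree,
    constraints: SplitConstraints,
    candidate_set: set[str],
    rng: np.random.Generator,
) -> list[str]:
    """Scan a shuffled candidate list, accepting bulls that satisfy the
    family-count and fathers-of-training rules, until val_size is reached."""
    order = list(candidates)
    rng.shuffle(order)
    val: list[str] = []
    fam_count: dict[str, int] = {}
    for v in order:
        fam = pedigree.paternal_family_of(v)
        if fam_count.get(fam, 0) >= constraints.max_per_half_sib_family:
            continue
        if constraints.forbid_sires_of_training and constraints.a_max >= 0.5:
            # offspring (a = 0.5) stay in training below this cap, so a sire
            # in validation would violate the rule; for smaller a_max the
            # a_max exclusion removes the offspring from training anyway.
            if any(o in candidate_set for o in pedigree.offspring_of(v)):
                continue
        val.append(v)
        fam_count[fam] = fam_count.get(fam, 0) + 1
        if len(val) >= constraints.val_size:
            break
    return val


def sample_splits(
    A: RelationshipMatrix,
    pedigree: Pedigree,
    candidate_ids: Sequence[str],
    constraints: SplitConstraints,
    seed: int = 0,
) -> list[Split]:
    """Sample ``n_replicates`` training/validation pairs under ``constraints``.

    For each replicate the validation draw is retried ``n_tries`` times and
    the assignment excluding the fewest bulls is kept.  Training is trimmed
    to ``train_size`` by random removal that never touches bulls related to
    validation at or above ``protect_threshold`` (fathers, full and half
    sibs), so close relatives stay in training for the high-a_max scenarios.
    """
    rng = np.random.default_rng(seed)
    candidates = [str(i) for i in candidate_ids]
    idx = A.indices(candidates)
    Asub = A.values[np.ix_(idx, idx)]
    pos = {c: k for k, c in enumerate(candidates)}
    used_val: set[str] = set()
    splits: list[Split] = []

    for rep in range(constraints.n_replicates):
        avail = [c for c in candidates if c not in used_val] if constraints.unique_validation else list(candidates)
        best: tuple[tuple[int, int], list[str], list[str], list[str]] | None = None
        for _ in range(constraints.n_tries):
            val = _draw_validation(avail, pedigree, constraints, set(candidates), rng)
            if len(val) < constraints.min_val_size:
                continue
            vi = np.asarray([pos[v] for v in val], dtype=np.intp)
            rest = [c for c in candidates if c not in set(val)]
            ri = np.asarray([pos[c] for c in rest], dtype=np.intp)
            cross_max = Asub[np.ix_(ri, vi)].max(axis=1)
            over = cross_max > constraints.a_max
            excluded = [c for c, o in zip(rest, over) if o]
            train = [c for c, o in zip(rest, over) if not o]
            if len(train) < constraints.train_size:
                continue
            # primary objective: fewest exclusions; tie-break on fewest
            # protected close relatives so later down-sampling stays feasible
            n_protected = int(
                (cross_max[~over] >= constraints.protect_threshold).sum()
            )
            score = (len(excluded), n_protected)
            if best is None or score < best[0]:
                best = (score, val, train, excluded)
        if best is None:
            raise InfeasibleSplitError(
                f"replicate {rep}: could not reach min validation size "
                f"{constraints.min_val_size} and training size {constraints.train_size} "
                f"under a_max={constraints.a_max} "
                f"({len(avail)} candidates left; binding constraint is the "
                "validation/training size given the a_max exclusions)"
            )
        _, val, train, excluded = best
        split = Split(rep, constraints.a_max, train, val, excluded)
        if len(train) > constraints.train_size:
            split = downsample_training(
                split,
                constraints.train_size,
                A,
                protect_threshold=constraints.protect_threshold,
                seed=int(rng.integers(2**31 - 1)),
            )
        split.realized_max = max_relationship(A, split.train, split.val)
        assert split.realized_max <= constraints.a_max + 1e-12
        used_val.update(val)
        splits.append(split)
    return splits


def downsample_training(
    split: Split,
    target_size: int,
    A: RelationshipMatrix,
    protect_threshold: float = 0.25,
    seed: int = 0,
) -> Split:
    """Randomly remove training bulls down to ``target_size``, never removing
    a bull whose relationship with any validation bull is >= ``protect_threshold``
    (fathers and full/half sibs of validation bulls stay in training)."""
    if target_size > len(split.train):
        raise InfeasibleSplitError(
            f"target size {target_size} exceeds training size {len(split.train)}"
        )
    rng = np.random.default_rng(seed)
    cross = A.between(split.train, split.val).max(axis=1)
    protected = [t for t, c in zip(split.train, cross) if c >= protect_threshold]
    free = [t for t, c in zip(split.train, cross) if c < protect_threshold]
    if len(protected) > target_size:
        raise InfeasibleSplitError(
            f"{len(protected)} protected bulls exceed the target training size "
            f"{target_size}; the protect threshold {protect_threshold} is binding"
        )
    keep_free = list(rng.choice(free, size=target_size - len(protected), replace=False)) if free else []
    train = [t for t in split.train if t in set(protected) | set(keep_free)]
    new = replace(split, train=train)
    new.realized_max = max_relationship(A, new.train, new.val) if new.train else float("nan")
    return new
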