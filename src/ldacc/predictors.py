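"""Breeding-value prediction: BayesB, G-BLUP / P-BLUP and RR-BLUP.

All three models share the observation equation for a training bull's DYD,

    y_i = mu (or alpha) + g_i + e_i,      Var(e_i) = sigma2_e / w_i,

with the reliability w_i of the DYD weighting the residual.  They differ in
how the breeding value g_i is parameterised:

* BayesB: g_i = sum_k x_ik beta_k delta_k with Pr(delta_k = 1) = pi and a
  scaled-inverse-chi-square prior on each locus variance (a t-like effect
  prior), sampled by MCMC (see :mod:`ldacc._bayesb`).
* G-BLUP / P-BLUP: an animal model g ~ N(0, K sigma2_a) solved through the
  mixed-model equations, with K the genomic (G) or numerator (A)
  relationship matrix; validation bulls enter with missing phenotypes and
  receive EBVs through their relationship rows.
* RR-BLUP: the normal-prior SNP-effect model with common variance
  sigma2_a / sum_k 2 p_k q_k, solved in closed form; algebraically
  equivalent to G-BLUP when G uses the same centering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from ._bayesb import bayesb_chain
from .data import GenotypeData
from .relationships import RelationshipMatrix

__all__ = [
    "VarianceComponents",
    "BayesBConfig",
    "BayesBFit",
    "EBVResult",
    "fit_bayesb",
    "predict_gebv",
    "fit_blup",
    "fit_rrblup",
]

logger = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if self.sigma2_a <= 0 or self.sigma2_e <= 0:
            raise ValueError("variance components must be positive")


@dataclass
class BayesBConfig:
    """MCMC settings; defaults follow the reference analysis (pi = 0.01,
    nu = 4.2 on both variance priors, 50,000 iterations with 40,000
    burn-in).  Desk-scale runs shorten the chain explicitly."""

    pi: float = 0.01
    nu_e: float = 4.2
    nu_beta: float = 4.2
    n_iter: int = 50_000
    burn_in: int = 40_000
    thin: int = 10
    seed: int = 0
    fixed_effect_variance: float | None = None  # pin sig2b_k (oracle/testing)

    def __post_init__(self) -> None:
        if not 0.0 < self.pi <= 1.0:
            raise ValueError("pi must lie in (0, 1]")
        if self.n_iter <= self.burn_in:
            raise ValueError("chain length must exceed burn-in")


@dataclass
class BayesBFit:
    alpha: float
    beta: np.ndarray              # posterior mean of delta_k * beta_k
    inclusion_freq: np.ndarray
    sigma2_e: float
    snp_ids: list[str]
    traces: dict = field(default_factory=dict)
    acceptance_rate: float = float("nan")
    ess_sigma2_e: float = float("nan")


@dataclass
class EBVResult:
    """Estimated breeding values for exactly the requested individuals."""

    ebvs: pd.Series              # index: individual id
    method: str                  # "BayesB" | "G-BLUP" | "P-BLUP" | "RR-BLUP"
    mu: float = float("nan")

    def for_ids(self, ids: Sequence[str]) -> np.ndarray:
        return self.ebvs.loc[[str(i) for i in ids]].to_numpy()


def _effective_sample_size(x: np.ndarray) -> float:
    """Initial-positive-sequence ESS estimate from the autocorrelation."""
    x = np.asarray(x, float)
    m = len(x)
    if m < 10 or np.var(x) == 0:
        return float(m)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[m - 1 :] / (np.arange(m, 0, -1) * np.var(x))
    s = 0.0
    for lag in range(1, m):
        if acf[lag] <= 0:
            break
        s += acf[lag]
    return float(m / (1.0 + 2.0 * s))


def _training_arrays(
    phenotypes: pd.DataFrame, genotypes: GenotypeData
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ids = [str(i) for i in phenotypes["id"]]
    sub = genotypes.subset_individuals(ids)
    y = phenotypes["dyd"].to_numpy(float)
    w = phenotypes["weight"].to_numpy(float)
    if ((w <= 0) | (w > 1)).any():
        raise ValueError("reliability weights must lie in (0, 1]")
    return sub.matrix.astype(np.float64), y, w


def fit_bayesb(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeData,
    variances: VarianceComponents,
    config: BayesBConfig,
) -> BayesBFit:
    """Run the BayesB MCMC on training bulls.

    ``phenotypes`` is a single-trait frame with columns ``id, dyd, weight``.
    The locus-variance prior scale is derived from the additive variance by
    sigma2_beta = sigma2_a / (pi * sum_k 2 p_k q_k): the additive variance
    spread over the expected pi*K included loci.  Prior scales are set so
    the prior means equal the supplied components.  A low effective sample
    size of the residual-variance trace triggers a warning (never silent
    non-mixing).
    """
    if not genotypes.is_complete():
        raise ValueError("genotypes contain missing calls; run QC first")
    X, y, w = _training_arrays(phenotypes, genotypes)
    p = genotypes.allele_frequencies()
    sum2pq = float(2.0 * np.sum(p * (1.0 - p)))
    if sum2pq <= 0:
        raise ValueError("monomorphic panel")
    sigma2_beta = variances.sigma2_a / (config.pi * sum2pq)
    # scaled-inv-chi2 mean nu*S/(nu-2) = target
    s2_b = sigma2_beta * (config.nu_beta - 2.0) / config.nu_beta
    s2_e = variances.sigma2_e * (config.nu_e - 2.0) / config.nu_e
    fixed = -1.0 if config.fixed_effect_variance is None else float(config.fixed_effect_variance)

    alpha, beta, incl, sig2e, tr_a, tr_s, tr_n, acc = bayesb_chain(
        np.ascontiguousarray(X),
        y,
        w,
        config.pi,
        config.nu_e,
        s2_e,
        config.nu_beta,
        s2_b,
        fixed,
        config.n_iter,
        config.burn_in,
        config.thin,
        int(config.seed) % (2**31 - 1),
    )
    ess = _effective_sample_size(tr_s)
    if ess < 30.0:
        warnings.warn(
            f"BayesB residual-variance trace has low effective sample size "
            f"({ess:.1f}); consider a longer chain",
            RuntimeWarning,
            stacklevel=2,
        )
    return BayesBFit(
        alpha=float(alpha),
        beta=beta,
        inclusion_freq=incl,
        sigma2_e=float(sig2e),
        snp_ids=genotypes.snp_ids,
        traces={"alpha": tr_a, "sigma2_e": tr_s, "n_included": tr_n},
        acceptance_rate=float(acc),
        ess_sigma2_e=ess,
    )


class PanelMismatchError(ValueError):
    pass


def predict_gebv(fit: BayesBFit, genotypes_target: GenotypeData) -> EBVResult:
    """GEBV of each target bull: ghat_i = sum_k x_ik betahat_k (no intercept)."""
    if genotypes_target.snp_ids != fit.snp_ids:
        bad = sorted(set(genotypes_target.snp_ids) ^ set(fit.snp_ids))
        raise PanelMismatchError(
            f"target panel does not match training panel; {len(bad)} SNPs "
            f"differ, e.g. {bad[:5]}"
        )
    g = genotypes_target.matrix.astype(float) @ fit.beta
    return EBVResult(
        pd.Series(g, index=pd.Index(genotypes_target.ids, name="id")),
        method="BayesB",
        mu=fit.alpha,
    )


class SingularSystemError(np.linalg.LinAlgError):
    pass


def fit_blup(
    phenotypes: pd.DataFrame,
    relationship_matrix: RelationshipMatrix,
    variances: VarianceComponents,
    target_ids: Sequence[str] | None = None,
    ridge: float = 1e-8,
) -> EBVResult:
    """Animal-model BLUP via the mixed-model equations.

    Solves y = 1 mu + Z g + e with g ~ N(0, K sigma2_a) over the union of
    training and target ids.  Non-phenotyped targets obtain EBVs through
    their relationship rows (zero rows give a zero EBV).  A genomic K may be
    singular: a diagonal ridge (default 1e-8, escalated up to 1e-4 with a
    log message) is added until the factorisation succeeds.
    """
    train_ids = [str(i) for i in phenotypes["id"]]
    targets = [str(i) for i in (target_ids if target_ids is not None else [])]
    all_ids = train_ids + [t for t in targets if t not in set(train_ids)]
    K = relationship_matrix.submatrix(all_ids).values
    y = phenotypes["dyd"].to_numpy(float)
    w = phenotypes["weight"].to_numpy(float)
    if ((w <= 0) | (w > 1)).any():
        raise ValueError("reliability weights must lie in (0, 1]")
    q = w / variances.sigma2_e
    n, m = len(train_ids), len(all_ids)

    Kinv = None
    eps = ridge
    while Kinv is None:
        try:
            c, low = scipy.linalg.cho_factor(
                K + eps * np.eye(m), lower=True, check_finite=False
            )
            Kinv = scipy.linalg.cho_solve((c, low), np.eye(m), check_finite=False)
            if eps > ridge:
                logger.info("relationship matrix ridged with %.1e for solvability", eps)
        except np.linalg.LinAlgError:
            eps *= 10.0
            if eps > 1e-4:
                raise SingularSystemError(
                    "relationship matrix not factorisable even with ridge 1e-4; "
                    f"condition estimate {np.linalg.cond(K):.2e}"
                ) from None

    # MME: [[sum q, q'Z], [Z'q, Z'QZ + Kinv/sigma2_a]] [mu, g] = [q'y, Z'(qy)]
    C = np.zeros((1 + m, 1 + m))
    rhs = np.zeros(1 + m)
    C[0, 0] = q.sum()
    C[0, 1 : 1 + n] = q
    C[1 : 1 + n, 0] = q
    C[1:, 1:] = Kinv / variances.sigma2_a
    C[1 : 1 + n, 1 : 1 + n] += np.diag(q)
    rhs[0] = q @ y
    rhs[1 : 1 + n] = q * y
    try:
        sol = scipy.linalg.solve(C, rhs, assume_a="sym", check_finite=False)
    except np.linalg.LinAlgError:
        raise SingularSystemError(
            f"mixed-model coefficient matrix singular; condition {np.linalg.cond(C):.2e}"
        ) from None
    mu, g = float(sol[0]), sol[1:]
    method = "G-BLUP" if relationship_matrix.kind == "genomic" else "P-BLUP"
    out_ids = targets if target_ids is not None else all_ids
    series = pd.Series(g, index=pd.Index(all_ids, name="id")).loc[out_ids]
    return EBVResult(series, method=method, mu=mu)


def fit_rrblup(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeData,
    variances: VarianceComponents,
    target_ids: Sequence[str] | None = None,
    frequencies: np.ndarray | None = None,
) -> EBVResult:
    """Closed-form weighted ridge-regression BLUP on centered SNP dosages.

    All SNP effects share the variance sigma2_a / sum_k 2 p_k q_k; the
    intercept is estimated jointly.  GEBVs are computed from the centered
    dosages for training and target bulls alike.
    """
    if not genotypes.is_complete():
        raise ValueError("genotypes contain missing calls; run QC first")
    train_ids = [str(i) for i in phenotypes["id"]]
    p = np.asarray(
        frequencies if frequencies is not None else genotypes.allele_frequencies(), float
    )
    sum2pq = float(2.0 * np.sum(p * (1 - p)))
    if sum2pq <= 0:
        raise ValueError("monomorphic panel")
    lam = variances.sigma2_e / (variances.sigma2_a / sum2pq)

    Xc_all = genotypes.matrix.astype(float) - 2.0 * p
    lookup = {i: k for k, i in enumerate(genotypes.ids)}
    Xc = Xc_all[[lookup[i] for i in train_ids]]
    y = phenotypes["dyd"].to_numpy(float)
    w = phenotypes["weight"].to_numpy(float)
    K = genotypes.n_snps

    # normal equations for [mu, beta] with weighted residual precision
    C = np.zeros((1 + K, 1 + K))
    C[0, 0] = w.sum()
    C[0, 1:] = w @ Xc
    C[1:, 0] = C[0, 1:]
    C[1:, 1:] = Xc.T @ (Xc * w[:, None]) + lam * np.eye(K)
    rhs = np.concatenate([[w @ y], Xc.T @ (w * y)])
    sol = scipy.linalg.solve(C, rhs, assume_a="sym", check_finite=False)
    mu, beta = float(sol[0]), sol[1:]

    out_ids = [str(i) for i in target_ids] if target_ids is not None else list(genotypes.ids)
    g = Xc_all[[lookup[i] for i in out_ids]] @ beta
    return EBVResult(pd.Series(g, index=pd.Index(out_ids, name="id")), method="RR-BLUP", mu=mu)
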