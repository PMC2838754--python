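"""Accuracy estimation and the decomposition into relationship and LD parts.

The accuracy of GEBVs is estimated from validation DYDs: within each
replicate the EBVs are centered on the replicate's mean EBV, validation
bulls are pooled across replicates, and

    rho_hat = corr(ghat, y) / mean_i r_gy(n_i, h2),

where r_gy is the selection-index accuracy of a DYD from n daughter records
(the progeny-test accuracy of a sire).  The accuracy due to LD is the
intercept of the regression of GEBV accuracy on the relative P-BLUP
accuracy across a_max scenarios,

    rho_GEBV(a_max) = rho_LD + d * x(a_max) + eps,
    x(a_max) = rho_PBLUP(a_max) / rho_PBLUP(reference a_max),

because the relative P-BLUP accuracy tracks the decay of additive-genetic
relationship information while the LD contribution stays constant across
scenarios.  The module also computes the r² decay profile of phased
haplotypes against physical distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import HaplotypeSet

__all__ = [
    "dyd_accuracy",
    "AccuracyEstimate",
    "estimate_accuracy",
    "LDRegressionResult",
    "ld_accuracy_regression",
    "LDProfile",
    "ld_r2_profile",
]


def dyd_accuracy(n_daughters, h2: float):
    """Selection-index accuracy of a sire's DYD from ``n`` daughter records:

        r_gy = sqrt( (n h²/4) / (1 + (n − 1) h²/4) ),

    the progeny-test accuracy with daughter heritability ``h2``; tends to 1
    as n grows.  Vectorised over ``n_daughters``.
    """
    n = np.asarray(n_daughters, dtype=float)
    if (n < 1).any():
        raise ValueError("daughter counts must be >= 1")
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    t = h2 / 4.0
    r = np.sqrt(n * t / (1.0 + (n - 1.0) * t))
    return float(r) if np.isscalar(n_daughters) else r


@dataclass
class AccuracyEstimate:
    """Pooled accuracy for one (method, trait, a_max, training size) cell."""

    rho: float
    raw_correlation: float
    mean_r_gy: float
    n_validation: int
    per_replicate: pd.DataFrame  # replicate, n, correlation


def estimate_accuracy(
    ebvs: pd.DataFrame,
    phenotypes: pd.DataFrame,
    h2: float,
) -> AccuracyEstimate:
    """Estimate GEBV accuracy from validation DYDs.

    Parameters
    ----------
    ebvs:
        columns ``replicate, id, ebv`` — one row per validation bull per
        replicate.
    phenotypes:
        single-trait frame with ``id, dyd, n_daughters``.
    h2:
        heritability of a daughter record for the trait.

    The estimate is reported unclipped; a magnitude above one (possible by
    sampling noise since the estimator is a ratio) triggers a warning.
    """
    if ebvs.duplicated(["replicate", "id"]).any():
        raise ValueError("duplicate (replicate, id) rows in EBV frame")
    pheno = phenotypes.set_index("id")
    rows = []
    for rep, sub in ebvs.groupby("replicate"):
        g = sub["ebv"].to_numpy(float)
        g = g - g.mean()  # correct by the replicate's mean EBV
        ids = [str(i) for i in sub["id"]]
        y = pheno.loc[ids, "dyd"].to_numpy(float)
        n = pheno.loc[ids, "n_daughters"].to_numpy(float)
        rows.append(pd.DataFrame({"replicate": rep, "id": ids, "g": g, "y": y, "n": n}))
    pooled = pd.concat(rows, ignore_index=True)
    if len(pooled) < 3:
        raise ValueError("fewer than 3 pooled validation bulls; correlation undefined")
    raw = float(np.corrcoef(pooled["g"], pooled["y"])[0, 1])
    mean_rgy = float(np.mean(dyd_accuracy(pooled["n"].to_numpy(), h2)))
    rho = raw / mean_rgy
    if abs(rho) > 1.0:
        warnings.warn(
            f"estimated accuracy {rho:.3f} exceeds 1 in magnitude (estimator "
            "noise); reported unclipped",
            RuntimeWarning,
            stacklevel=2,
        )
    per_rep = (
        pooled.groupby("replicate")
        .apply(
            lambda d: pd.Series(
                {"n": len(d), "correlation": np.corrcoef(d["g"], d["y"])[0, 1] if len(d) > 2 else np.nan}
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return AccuracyEstimate(rho, raw, mean_rgy, len(pooled), per_rep)


@dataclass
class LDRegressionResult:
    rho_ld: float                 # intercept: accuracy due to LD
    d: float                      # slope: relationship component
    x: pd.Series                  # predictor per a_max
    fitted: pd.Series
    residuals: pd.Series
    se_rho_ld: float
    se_d: float


def ld_accuracy_regression(
    gebv_accuracies: dict[float, float],
    pblup_accuracies: dict[float, float],
    reference_amax: float = 0.6,
) -> LDRegressionResult:
    """Ordinary-least-squares decomposition of GEBV accuracy.

    Regresses the GEBV accuracy at each a_max on the P-BLUP accuracy at
    that a_max divided by the P-BLUP accuracy at the reference a_max.  The
    intercept is the accuracy due to LD; the slope the relationship
    component (the gap between the reference-scenario accuracy and the LD
    accuracy).
    """
    if reference_amax not in pblup_accuracies:
        raise ValueError(f"reference a_max {reference_amax} has no P-BLUP accuracy")
    amaxes = sorted(set(gebv_accuracies) & set(pblup_accuracies), reverse=True)
    if len(amaxes) < 3:
        raise ValueError("need >= 3 a_max scenarios with both accuracies")
    ref = pblup_accuracies[reference_amax]
    x = np.array([pblup_accuracies[a] / ref for a in amaxes])
    ydat = np.array([gebv_accuracies[a] for a in amaxes])
    if np.allclose(x, x[0]):
        raise ValueError("all predictor values identical; intercept unidentifiable")
    model = sm.OLS(ydat, sm.add_constant(x)).fit()
    fitted = model.fittedvalues
    idx = pd.Index(amaxes, name="a_max")
    return LDRegressionResult(
        rho_ld=float(model.params[0]),
        d=float(model.params[1]),
        x=pd.Series(x, index=idx),
        fitted=pd.Series(fitted, index=idx),
        residuals=pd.Series(ydat - fitted, index=idx),
        se_rho_ld=float(model.bse[0]),
        se_d=float(model.bse[1]),
    )


@dataclass
class LDProfile:
    bins: pd.DataFrame            # bin_lo, bin_hi, mean_r2, sd_r2, n_pairs
    adjacent_mean_distance_mb: float
    adjacent_mean_r2: float

    def mean_r2_at(self, distance_mb: float) -> float:
        """Mean r² of the distance bin containing ``distance_mb``."""
        b = self.bins
        hit = b[(b["bin_lo"] <= distance_mb) & (distance_mb < b["bin_hi"])]
        if hit.empty or not np.isfinite(hit["mean_r2"].iloc[0]):
            raise ValueError(f"no r² estimate for distance {distance_mb} Mb")
        return float(hit["mean_r2"].iloc[0])


def _pairwise_r2(hap: np.ndarray) -> np.ndarray:
    """Squared allele-indicator correlation between all column pairs of a
    (haplotypes x sites) 0/1 matrix; monomorphic columns give NaN."""
    h = hap.astype(float)
    h -= h.mean(axis=0)
    sd = h.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (h.T @ h) / len(h)
        r = c / np.outer(sd, sd)
    return r**2


def ld_r2_profile(
    haplotypes: HaplotypeSet,
    bin_edges_mb: np.ndarray | None = None,
    markers_only: bool = True,
) -> LDProfile:
    """r² between syntenic SNP pairs, binned by physical distance.

    Per chromosome, r² is computed between all pairs closer than the last
    bin edge; per-bin means are taken per chromosome first, then averaged
    across chromosomes (the across-chromosome standard deviation is the
    reported spread).  Bins default to 0.02 Mb steps up to 1 Mb.  Also
    reports the mean spacing and mean r² of adjacent marker pairs.
    """
    if bin_edges_mb is None:
        bin_edges_mb = np.arange(0.0, 1.0 + 1e-9, 0.02)
    edges = np.asarray(bin_edges_mb, float)
    if len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be increasing")
    haps = haplotypes.markers_only() if markers_only else haplotypes
    max_d = edges[-1]

    n_bins = len(edges) - 1
    per_chrom_means = []
    per_chrom_counts = []
    adj_d, adj_r2 = [], []
    hap_matrix = haps.alleles.reshape(-1, haps.n_sites)
    for chrom, sub in haps.snp_map.groupby("chrom"):
        cols = sub.index.to_numpy()
        if len(cols) < 2:
            continue
        pos_mb = sub["pos"].to_numpy(float) / 1e6
        r2 = _pairwise_r2(hap_matrix[:, cols])
        iu, ju = np.triu_indices(len(cols), k=1)
        d = pos_mb[ju] - pos_mb[iu]
        vals = r2[iu, ju]
        ok = (d <= max_d) & np.isfinite(vals)
        which = np.digitize(d[ok], edges) - 1
        which = np.clip(which, 0, n_bins - 1)
        means = np.full(n_bins, np.nan)
        counts = np.zeros(n_bins)
        for b in range(n_bins):
            sel = which == b
            counts[b] = sel.sum()
            if counts[b]:
                means[b] = vals[ok][sel].mean()
        per_chrom_means.append(means)
        per_chrom_counts.append(counts)
        gaps = np.diff(pos_mb)
        pairs = np.isfinite(r2[np.arange(len(cols) - 1), np.arange(1, len(cols))])
        adj_d.extend(gaps[pairs])
        adj_r2.extend(r2[np.arange(len(cols) - 1), np.arange(1, len(cols))][pairs])

    if not per_chrom_means:
        raise ValueError("no chromosome with at least two sites")
    M = np.vstack(per_chrom_means)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_r2 = np.nanmean(M, axis=0)
        sd_r2 = np.nanstd(M, axis=0, ddof=1) if M.shape[0] > 1 else np.full(n_bins, np.nan)
    bins = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "mean_r2": mean_r2,
            "sd_r2": sd_r2,
            "n_pairs": np.vstack(per_chrom_counts).sum(axis=0),
        }
    )
    return LDProfile(
        bins,
        float(np.mean(adj_d)) if adj_d else float("nan"),
        float(np.mean(adj_r2)) if adj_r2 else float("nan"),
    )
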