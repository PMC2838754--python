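"""Convenience plots: r² decay and accuracy against a_max."""

from __future__ import annotations

import matplotlib.pyplot as plt
import pandas as pd

from .evaluation import LDProfile


def plot_ld_profile(profile: LDProfile, ax=None):
    """Mean r² against map distance with across-chromosome SD whiskers."""
    if ax is None:
        _, ax = plt.subplots()
    b = profile.bins.dropna(subset=["mean_r2"])
    mid = (b["bin_lo"] + b["bin_hi"]) / 2
    ax.errorbar(mid, b["mean_r2"], yerr=b["sd_r2"], fmt="o-", ms=3, capsize=2)
    ax.set_xlabel("distance (Mb)")
    ax.set_ylabel("mean $r^2$")
    ax.set_ylim(bottom=0)
    return ax


def plot_accuracy(accuracy: pd.DataFrame, trait: str, train_size: int, ax=None):
    """Accuracy per method against a_max for one trait and training size."""
    if ax is None:
        _, ax = plt.subplots()
    sub = accuracy[(accuracy["trait"] == trait) & (accuracy["train_size"] == train_size)]
    for method, grp in sub.groupby("method"):
        grp = grp.sort_values("a_max", ascending=False)
        ax.plot(grp["a_max"].astype(str), grp["rho"], "o-", label=method)
    ax.set_xlabel(r"$a_{max}$")
    ax.set_ylabel(r"accuracy $\rho$")
    ax.set_title(f"{trait}, {train_size} training bulls")
    ax.legend()
    return ax
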