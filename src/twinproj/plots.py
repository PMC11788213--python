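"""Standard figures: country rates, the age profile, and the projection bubble chart."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .ages import age_scheme_groups
from .propensity import AgeEffectPosterior, CountryRatePosterior

__all__ = ["plot_country_rates", "plot_age_profile", "plot_projection_bubble"]


def plot_country_rates(posterior: CountryRatePosterior, path=None):
    """Dot plot of per-country twinning rates (per 1000) with posterior IQRs."""
    iqr = (1000.0 * posterior.iqr()).sort_values("median")
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(iqr) + 1.5))
    y = np.arange(len(iqr))
    ax.hlines(y, iqr["q1"], iqr["q3"], color="steelblue", lw=2)
    ax.plot(iqr["median"], y, "o", color="navy")
    ax.set_yticks(y, iqr.index)
    ax.set_xlabel("twin deliveries per 1000 deliveries")
    ax.set_title("Country twinning rates (median, IQR)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_age_profile(posterior: AgeEffectPosterior, path=None):
    """Age profile of the twinning probability relative to the youngest group."""
    cats = age_scheme_groups(posterior.age_scheme)
    med, q1, q3 = [], [], []
    for c in cats:
        d = posterior.age_effect_draws(c)
        a, b, m = np.percentile(d, [25, 75, 50])
        med.append(m)
        q1.append(a)
        q3.append(b)
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(cats))
    ax.errorbar(x, med, yerr=[np.array(med) - q1, np.array(q3) - med],
                fmt="o-", color="darkred", capsize=3)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xticks(x, cats, rotation=45)
    ax.set_ylabel("change in twin probability vs reference")
    ax.set_title("Twinning probability by maternal age (median, IQR)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_projection_bubble(summary: pd.DataFrame, path=None):
    """Bubble chart: projected twin births vs projected births vs baseline rate.

    ``summary`` needs columns country, projected_births, projected_twin_births
    and baseline_rate_per_1000; bubble area scales with projected twin births.
    """
    fig, ax = plt.subplots(figsize=(7, 5))
    size = 2000 * summary["projected_twin_births"] / summary["projected_twin_births"].max()
    sc = ax.scatter(
        summary["projected_births"],
        summary["baseline_rate_per_1000"],
        s=size, alpha=0.6, c=summary["baseline_rate_per_1000"], cmap="viridis",
        edgecolor="k",
    )
    for _, row in summary.iterrows():
        ax.annotate(row["country"], (row["projected_births"], row["baseline_rate_per_1000"]),
                    fontsize=8, ha="center", va="center")
    ax.set_xlabel("projected births")
    ax.set_ylabel("baseline twinning rate (per 1000)")
    ax.set_title("Projected twin births (bubble area) by births and baseline rate")
    fig.colorbar(sc, label="per 1000")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
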