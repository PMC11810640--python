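"""Publication-style plots: duplication-mode frequencies and Ks
distributions with fitted mixture components."""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import lognorm, norm

from .ksmix import KsMixtureModel

_MODE_COLORS = {"SD": "#1b9e77", "SSD": "#66a61e", "TD": "#d95f02",
                "PD": "#7570b3", "TRD": "#e7298a", "rTRD": "#e6ab02",
                "dTRD": "#a6761d", "DD": "#666666"}


def plot_duplicate_freqs(freqs: pd.DataFrame, path,
                         species_column: str = "species") -> Optional[str]:
    """Absolute + relative frequency bars per species.

    Expects columns mode, n, fraction and optionally a species column
    (single-species tables get one implicit species).
    """
    if freqs.empty or freqs["n"].sum() == 0:
        warnings.warn("no duplicate frequencies to plot", stacklevel=2)
        return None
    df = freqs.copy()
    if species_column not in df.columns:
        df[species_column] = "species"
    species = list(dict.fromkeys(df[species_column]))
    modes = list(dict.fromkeys(df["mode"]))
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=False)
    for ax, column, title in ((axes[0], "n", "Absolute"),
                              (axes[1], "fraction", "Relative")):
        bottom = np.zeros(len(species))
        for mode in modes:
            vals = np.array([
                df[(df[species_column] == sp) & (df["mode"] == mode)][column].sum()
                for sp in species])
            ax.bar(species, vals, bottom=bottom,
                   color=_MODE_COLORS.get(mode, "#999999"), label=mode)
            bottom += vals
        ax.set_title(title)
        ax.set_ylabel("gene pairs" if column == "n" else "fraction")
        ax.tick_params(axis="x", rotation=45)
    axes[1].legend(fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)


def plot_ks_distro(ks_values: Sequence[float], path, bins: int = 50,
                   max_ks: float = 2.0) -> Optional[str]:
    """Histogram of the Ks distribution."""
    vals = np.asarray(pd.Series(ks_values).dropna(), dtype=float)
    vals = vals[(vals > 0) & (vals <= max_ks)]
    if len(vals) == 0:
        warnings.warn("no Ks values to plot", stacklevel=2)
        return None
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(vals, bins=bins, color="#4477aa", edgecolor="white")
    ax.set_xlabel("Ks")
    ax.set_ylabel("duplicate pairs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)


def plot_ks_peaks(model: KsMixtureModel, ks_values: Sequence[float], path,
                  cutpoints: Optional[Sequence[float]] = None,
                  bins: int = 50) -> Optional[str]:
    """Ks histogram with fitted component densities and cutpoint rules."""
    vals = np.asarray(pd.Series(ks_values).dropna(), dtype=float)
    vals = vals[vals > 0]
    if len(vals) == 0:
        warnings.warn("no Ks values to plot", stacklevel=2)
        return None
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(vals, bins=bins, density=True, color="#cccccc",
            edgecolor="white")
    grid = np.linspace(max(vals.min(), 1e-4), vals.max(), 500)
    for i in range(model.k):
        w = model.weights[i]
        mu, sd = model.locations[i], model.scales[i]
        if model.family == "lognormal":
            dens = w * lognorm.pdf(grid, s=sd, scale=np.exp(mu))
        else:
            dens = w * norm.pdf(grid, loc=mu, scale=sd)
        ax.plot(grid, dens, lw=2,
                label=f"component {i + 1} (peak {model.peaks[i]:.2f})")
    for cut in (cutpoints or []):
        ax.axvline(cut, color="black", ls="--", lw=1)
    ax.set_xlabel("Ks")
    ax.set_ylabel("density")
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)
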