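"""Matplotlib views of simulation output: CPN profiles and quality histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .fibre_quality import INDICES

__all__ = ["plot_cpn_profile", "plot_quality_histograms"]

_LABELS = {
    "length": "Fibre length (mm)",
    "strength": "Fibre strength (cN tex$^{-1}$)",
    "micronaire": "Micronaire",
}


def plot_cpn_profile(profile: pd.DataFrame, axes=None):
    """Per-CPN mean quality with 2×SE error bars, one panel per index."""
    if axes is None:
        _, axes = plt.subplots(1, 3, figsize=(11, 3.2), sharex=True)
    for ax, index in zip(np.ravel(axes), INDICES):
        ax.errorbar(
            profile["cpn"], profile[f"{index}_mean"],
            yerr=profile[f"{index}_2se"], fmt="o-", ms=3, lw=1, capsize=2,
        )
        ax.set_xlabel("Cumulative phytomer number")
        ax.set_ylabel(_LABELS[index])
    plt.tight_layout()
    return axes


def plot_quality_histograms(histograms: dict, axes=None):
    """Fruit-count histograms per quality index."""
    if axes is None:
        _, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    for ax, index in zip(np.ravel(axes), INDICES):
        counts, edges = histograms[index]
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", edgecolor="k")
        ax.set_xlabel(_LABELS[index])
        ax.set_ylabel("Fruit count")
    plt.tight_layout()
    return axes
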