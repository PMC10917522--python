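"""Small matplotlib helpers for the standard diagnostic figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def plot_allele_frequency(track: pd.DataFrame, path=None, ax=None):
    """Allele frequency against concatenated whole-genome position.

    Alternating chromosome shading follows the order present in the track.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    ax.scatter(track["concat_pos"], track["frequency"], s=4, alpha=0.5,
               color="#30506d", linewidths=0)
    for i, (chrom, sub) in enumerate(track.groupby("chrom", sort=False)):
        if i % 2:
            ax.axvspan(sub["concat_pos"].min(), sub["concat_pos"].max(),
                       color="0.9", zorder=0)
    ax.set_xlabel("concatenated genome position (bp)")
    ax.set_ylabel("allele frequency")
    ax.set_ylim(-0.02, 1.02)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_correlation_distributions(groups: dict, path=None, ax=None, bins=40):
    """Overlaid density histograms of correlation values per named group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    edges = np.linspace(-1, 1, bins + 1)
    for name, values in groups.items():
        ax.hist(values, bins=edges, density=True, histtype="step", label=name)
    ax.set_xlabel("Pearson r")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
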