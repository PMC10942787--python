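"""Display figures: stacked category bars and smoothed spike-count histograms."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # noqa: E402 - headless backend before pyplot import
import matplotlib.pyplot as plt
import numpy as np

from .model import HYPOTHESES
from .population import CategoryTally, smooth_count_histogram

__all__ = ["plot_category_bars", "plot_count_histogram"]

_CATEGORY_COLORS = {
    "mixture": "#b2182b",
    "intermediate": "#ef8a62",
    "single": "#67a9cf",
    "outside": "#2166ac",
}


def plot_category_bars(tallies: Sequence[CategoryTally], path=None, ax=None):
    """Stacked bars of category counts per regime."""
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 + 0.9 * len(tallies), 4.0))
    x = np.arange(len(tallies))
    bottom = np.zeros(len(tallies))
    for h in HYPOTHESES:
        heights = np.array([t.counts[h] for t in tallies], dtype=float)
        ax.bar(x, heights, bottom=bottom, color=_CATEGORY_COLORS[h], label=h)
        bottom += heights
    ax.set_xticks(x)
    ax.set_xticklabels([t.regime for t in tallies], rotation=30, ha="right")
    ax.set_ylabel("triplets")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_count_histogram(ab_counts, mean_a=None, mean_b=None, window_duration=0.2,
                         path=None, ax=None):
    """Raw AB spike-count histogram with the smoothed display curve.

    ``window_duration`` (s) sets the secondary axis conversion from counts
    per window to spikes/s (x5 for the standard 200 ms window).
    """
    counts = np.asarray(ab_counts)
    edges = np.arange(counts.max() + 2) - 0.5
    hist, _ = np.histogram(counts, bins=edges)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    centers = np.arange(hist.size, dtype=float)
    ax.bar(centers, hist, width=1.0, color="0.8", edgecolor="0.6")
    x, y = smooth_count_histogram(hist)
    ax.plot(x, y, color="black", lw=1.5)
    for mean, color, label in ((mean_a, "red", "A"), (mean_b, "blue", "B")):
        if mean is not None:
            ax.axvline(mean, color=color, ls=":", lw=1.2, label=f"{label} mean")
    ax.set_xlabel(f"spikes per {1e3 * window_duration:.0f} ms window "
                  f"(x{1 / window_duration:.0f} for spikes/s)")
    ax.set_ylabel("trials")
    if mean_a is not None or mean_b is not None:
        ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
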