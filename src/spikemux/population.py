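"""Population-level summaries: category tallies, prevalence contrasts, display.

Classified triplets are tallied per stimulus regime (dataset) into the four
categories, counting triplets whose winning hypothesis reached the posterior
threshold (0.67 or greater, matching the population figures) and tracking
the unclassified remainder.  Mixture prevalence between two regimes is
compared with a Pearson chi-squared test on the 2x2 (mixture vs not) x
(regime 1 vs regime 2) table.  Spike-count histograms are smoothed for
display by a normalised (1/4, 1/2, 1/4) sliding kernel followed by cubic
spline interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .model import HYPOTHESES, TripletClassification

__all__ = [
    "CategoryTally",
    "ComparisonResult",
    "DegenerateTableError",
    "tally_classifications",
    "mixture_proportion",
    "compare_mixture_prevalence",
    "smooth_count_histogram",
    "kernel_smooth",
    "tally_to_frame",
]


class DegenerateTableError(ValueError):
    """Raised when a contingency table has an all-zero row or column."""


@dataclass(frozen=True)
class CategoryTally:
    """Counts of classified triplets per category for one regime."""

    regime: str
    counts: Mapping[str, int]
    n_unclassified: int = 0
    n_screened_out: int = 0

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())

    @property
    def total(self) -> int:
        return self.n_classified + self.n_unclassified


@dataclass(frozen=True)
class ComparisonResult:
    """Pearson chi-squared contrast of mixture prevalence between two regimes."""

    statistic: float
    dof: int
    p_value: float
    contingency: np.ndarray  # rows: regimes; cols: (mixture, non-mixture)


def tally_classifications(
    classifications: Iterable[TripletClassification],
    threshold: float = 0.67,
    regime: str = "all",
    n_screened_out: int = 0,
) -> CategoryTally:
    """Tally winners whose posterior reached ``threshold`` (inclusive).

    Triplets whose winning hypothesis fell short of the threshold are counted
    as unclassified, mirroring the population figures which show only
    triplets with winning posterior 0.67 or greater.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    counts = {h: 0 for h in HYPOTHESES}
    unclassified = 0
    for c in classifications:
        if c.winner_posterior >= threshold:
            counts[c.winner] += 1
        else:
            unclassified += 1
    return CategoryTally(regime=regime, counts=counts,
                         n_unclassified=unclassified,
                         n_screened_out=n_screened_out)


def mixture_proportion(tally: CategoryTally) -> float:
    """Fraction of classified triplets in the mixture category."""
    if tally.n_classified == 0:
        raise ValueError(f"regime {tally.regime!r} has no classified triplets")
    return tally.counts["mixture"] / tally.n_classified


def compare_mixture_prevalence(tally_1: CategoryTally, tally_2: CategoryTally,
                               continuity_correction: bool = False) -> ComparisonResult:
    """Pearson chi-squared test (dof 1) on mixture vs non-mixture prevalence.

    Uncorrected by default; ``continuity_correction=True`` applies Yates'
    correction.
    """
    table = np.array([
        [tally_1.counts["mixture"], tally_1.n_classified - tally_1.counts["mixture"]],
        [tally_2.counts["mixture"], tally_2.n_classified - tally_2.counts["mixture"]],
    ], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateTableError(
            f"degenerate 2x2 table for {tally_1.regime!r} vs {tally_2.regime!r}: "
            f"{table.tolist()}")
    res = stats.chi2_contingency(table, correction=continuity_correction)
    return ComparisonResult(statistic=float(res.statistic), dof=int(res.dof),
                            p_value=float(res.pvalue), contingency=table)


def smooth_count_histogram(
    histogram: Sequence[float],
    upsample: int = 10,
    edge: str = "replicate",
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth a spike-count histogram for display.

    Convolves with the normalised 3-point kernel (1/4, 1/2, 1/4) — middle
    point weighted twice each outer point — then interpolates with a cubic
    spline onto a grid ``upsample`` times finer.  ``edge`` selects boundary
    handling for the convolution: ``"replicate"`` (default) or ``"zero"``.

    Returns ``(x, y)``: positions in bin units (0, 1, ..., len-1 at the
    original bins) and the interpolated smooth curve.
    """
    hist = np.asarray(histogram, dtype=float)
    if np.any(hist < 0):
        raise ValueError("histogram bins must be non-negative")
    x_bins = np.arange(hist.size, dtype=float)
    if hist.size < 3:
        warnings.warn("histogram shorter than the 3-point kernel; returned unsmoothed")
        return x_bins, hist.copy()
    if edge == "replicate":
        padded = np.pad(hist, 1, mode="edge")
    elif edge == "zero":
        padded = np.pad(hist, 1, mode="constant")
    else:
        raise ValueError("edge must be 'replicate' or 'zero'")
    kernel = np.array([0.25, 0.5, 0.25])
    smoothed = np.convolve(padded, kernel, mode="valid")
    x_fine = np.linspace(0.0, hist.size - 1.0, (hist.size - 1) * upsample + 1)
    y_fine = CubicSpline(x_bins, smoothed)(x_fine)
    return x_fine, y_fine


def kernel_smooth(histogram: Sequence[float], edge: str = "replicate") -> np.ndarray:
    """Just the (1/4, 1/2, 1/4) kernel stage of :func:`smooth_count_histogram`."""
    hist = np.asarray(histogram, dtype=float)
    if hist.size < 3:
        return hist.copy()
    padded = np.pad(hist, 1, mode="edge" if edge == "replicate" else "constant")
    return np.convolve(padded, np.array([0.25, 0.5, 0.25]), mode="valid")


def tally_to_frame(tallies: Iterable[CategoryTally]) -> pd.DataFrame:
    rows = []
    for t in tallies:
        row = {"regime": t.regime}
        row.update({h: t.counts[h] for h in HYPOTHESES})
        row["n_unclassified"] = t.n_unclassified
        row["n_screened_out"] = t.n_screened_out
        row["n_classified"] = t.n_classified
        rows.append(row)
    return pd.DataFrame(rows)
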