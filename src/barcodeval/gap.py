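"""Distance-frequency distributions and barcode-gap summaries.

An ideal barcode shows a "barcode gap": the distribution of
intraspecific distances ends below where the interspecific distribution
begins.  This module bins the two pooled distance classes (in percent,
d×100) into half-open 1-percentage-point bins by default (the terminal
bin is closed), computes the relative abundance per bin, the share of a
class falling in an arbitrary [lo, hi) range, and a gap summary: the
maximum intraspecific distance, the minimum interspecific distance,
their difference (negative = overlap), and the fraction of interspecific
pairs below the 95th percentile of the intraspecific distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .divergence import interspecific_distances, intraspecific_distances
from .k2p import DistanceMatrix

INTRA = "intraspecific"
INTER = "interspecific"


@dataclass
class DistanceHistogram:
    """Binned intra/interspecific distance distributions (percent units).

    Raw per-class distance arrays are retained so arbitrary range shares
    are exact, not bin-resolution approximations.
    """

    bin_width: float
    edges: np.ndarray           # shared bin edges, percent
    intra_counts: np.ndarray
    inter_counts: np.ndarray
    intra_pct: np.ndarray       # raw distances × 100
    inter_pct: np.ndarray

    @property
    def intra_abundance(self) -> np.ndarray:
        """Relative abundance (%) per bin; zeros when the class is empty."""
        total = self.intra_counts.sum()
        return 100.0 * self.intra_counts / total if total else np.zeros_like(self.intra_counts, dtype=float)

    @property
    def inter_abundance(self) -> np.ndarray:
        total = self.inter_counts.sum()
        return 100.0 * self.inter_counts / total if total else np.zeros_like(self.inter_counts, dtype=float)

    def _raw(self, cls: str) -> np.ndarray:
        if cls == INTRA:
            return self.intra_pct
        if cls == INTER:
            return self.inter_pct
        raise ValueError(f"unknown class {cls!r}; expected {INTRA!r} or {INTER!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls, counts, abundance in (
            (INTRA, self.intra_counts, self.intra_abundance),
            (INTER, self.inter_counts, self.inter_abundance),
        ):
            for k in range(len(counts)):
                rows.append(
                    {
                        "class": cls,
                        "bin_lo": self.edges[k],
                        "bin_hi": self.edges[k + 1],
                        "count": int(counts[k]),
                        "relative_abundance": abundance[k],
                    }
                )
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def distance_histogram(
    dm: DistanceMatrix, bin_width: float = 1.0
) -> DistanceHistogram:
    """Bin the pooled intra- and interspecific distances of a group."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    intra = intraspecific_distances(dm) * 100.0
    inter = interspecific_distances(dm) * 100.0
    top = max(intra.max(initial=0.0), inter.max(initial=0.0))
    n_bins = max(1, int(math.ceil(top / bin_width)) or 1)
    if top >= n_bins * bin_width:  # value exactly on the last edge
        n_bins += 1
    edges = np.arange(n_bins + 1) * bin_width
    intra_counts, _ = np.histogram(intra, bins=edges)
    inter_counts, _ = np.histogram(inter, bins=edges)
    return DistanceHistogram(
        bin_width=bin_width,
        edges=edges,
        intra_counts=intra_counts,
        inter_counts=inter_counts,
        intra_pct=intra,
        inter_pct=inter,
    )


def range_share(
    histogram: DistanceHistogram, cls: str, lo_pct: float, hi_pct: float
) -> float:
    """Share (%) of a class's pairs with lo ≤ d% < hi."""
    if not lo_pct < hi_pct:
        raise ValueError("range requires lo < hi")
    vals = histogram._raw(cls)
    if vals.size == 0:
        return 0.0
    return 100.0 * float(((vals >= lo_pct) & (vals < hi_pct)).sum()) / vals.size


@dataclass
class BarcodeGapSummary:
    """Overlap report between the two distance classes (percent units)."""

    max_intraspecific: float
    min_interspecific: float
    gap: float                 # min_inter − max_intra; negative = overlap
    overlap_share: float       # % of inter pairs below the intra 95th pctile
    intra_95th_percentile: float
    n_intra: int
    n_inter: int
    complete: bool = True      # False when a class was empty


def barcode_gap_summary(histogram: DistanceHistogram) -> BarcodeGapSummary:
    intra, inter = histogram.intra_pct, histogram.inter_pct
    if intra.size == 0 or inter.size == 0:
        return BarcodeGapSummary(
            max_intraspecific=math.nan,
            min_interspecific=math.nan,
            gap=math.nan,
            overlap_share=math.nan,
            intra_95th_percentile=math.nan,
            n_intra=int(intra.size),
            n_inter=int(inter.size),
            complete=False,
        )
    max_intra = float(intra.max())
    min_inter = float(inter.min())
    p95 = float(np.percentile(intra, 95))
    return BarcodeGapSummary(
        max_intraspecific=max_intra,
        min_interspecific=min_inter,
        gap=min_inter - max_intra,
        overlap_share=100.0 * float((inter < p95).sum()) / inter.size,
        intra_95th_percentile=p95,
        n_intra=int(intra.size),
        n_inter=int(inter.size),
    )


def plot_histogram(histogram: DistanceHistogram, path: str | Path, title: str = "") -> None:
    """Optional barcode-gap figure; the CSV is the canonical output."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = (histogram.edges[:-1] + histogram.edges[1:]) / 2
    width = histogram.bin_width * 0.42
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(centers - width / 2, histogram.intra_abundance, width=width, label="intraspecific")
    ax.bar(centers + width / 2, histogram.inter_abundance, width=width, label="interspecific")
    ax.set_xlabel("K2P distance (%)")
    ax.set_ylabel("relative abundance (%)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
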