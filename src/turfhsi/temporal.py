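"""Vegetation-index frequency histograms and between-date area change.

For each genotype and acquisition date, the per-pixel values of an index over
the final vegetation mask are binned into a frequency histogram of absolute
pixel counts. Replicate histograms are averaged element-wise (fractional
counts are fine downstream). The histogram area difference between an early
and a late date,

    dA = sum_i (f_late,i - f_early,i),

telescopes to (total late pixels - total early pixels): a signed proxy for
canopy expansion (positive) or contraction (negative) that is independent of
the bin placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .indices import IndexMap
from .masks import VegetationMask

__all__ = [
    "IndexHistogram",
    "AreaDelta",
    "default_bin_edges",
    "build_histogram",
    "mean_histogram",
    "delta_area",
]

DEFAULT_N_BINS = 20


@dataclass
class IndexHistogram:
    bin_edges: np.ndarray  # length n_bins + 1, strictly increasing
    counts: np.ndarray  # pixel counts (fractional after averaging)
    genotype_id: str = ""
    date_label: str = ""
    index_name: str = ""
    n_out_of_range: int = 0  # values clipped into the edge bins

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("counts length must be len(edges) - 1")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class AreaDelta:
    delta: float  # signed pixel count
    genotype_id: str = ""
    index_name: str = ""


def default_bin_edges(valid_range: tuple[float, float], n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Uniform bins over an index's valid range."""
    return np.linspace(valid_range[0], valid_range[1], n_bins + 1)


def build_histogram(
    index_map: IndexMap,
    mask: Optional[VegetationMask],
    bin_edges: np.ndarray,
    genotype_id: str = "",
    date_label: str = "",
) -> IndexHistogram:
    """Bin valid retained pixel values: bins are half-open [lo, hi), the last
    bin closed. Out-of-range values are counted in the edge bins and flagged
    via ``n_out_of_range``."""
    edges = np.asarray(bin_edges, dtype=float)
    sel = index_map.valid if mask is None else (index_map.valid & mask.mask)
    vals = index_map.values[sel]
    out_of_range = int(np.sum((vals < edges[0]) | (vals > edges[-1])))
    clipped = np.clip(vals, edges[0], edges[-1])
    counts, _ = np.histogram(clipped, bins=edges)
    return IndexHistogram(
        bin_edges=edges,
        counts=counts.astype(float),
        genotype_id=genotype_id,
        date_label=date_label,
        index_name=index_map.definition.name,
        n_out_of_range=out_of_range,
    )


def mean_histogram(replicates: Sequence[IndexHistogram]) -> IndexHistogram:
    """Element-wise mean of replicate frequency arrays (same edges required)."""
    if len(replicates) == 0:
        raise ValueError("need at least one replicate histogram")
    first = replicates[0]
    for h in replicates[1:]:
        if not np.array_equal(h.bin_edges, first.bin_edges):
            raise ValueError("replicate histograms have mismatched bin edges")
    counts = np.mean([h.counts for h in replicates], axis=0)
    return IndexHistogram(
        bin_edges=first.bin_edges.copy(),
        counts=counts,
        genotype_id=first.genotype_id,
        date_label=first.date_label,
        index_name=first.index_name,
        n_out_of_range=sum(h.n_out_of_range for h in replicates),
    )


def delta_area(early: IndexHistogram, late: IndexHistogram) -> AreaDelta:
    """Signed sum of bin-wise count differences (late minus early)."""
    if not np.array_equal(early.bin_edges, late.bin_edges):
        raise ValueError("histograms have mismatched bin edges")
    return AreaDelta(
        delta=float(np.sum(late.counts - early.counts)),
        genotype_id=early.genotype_id or late.genotype_id,
        index_name=early.index_name or late.index_name,
    )
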