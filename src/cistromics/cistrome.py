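"""Stratification of two cistromes and peak-centered density matrices.

Two peak sets are split into co-bound and exclusive classes (>=1 bp
overlap), and read-coverage profiles are extracted around peak centers,
sorted by peak height, the standard visualization of co-localization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .association import MergedIntervalIndex
from .intervals import CoverageTrack, Peak


@dataclass
class CistromePartition:
    """Peaks of sets A and B split by whether they overlap the other set.

    Invariant: ``len(both_a) + len(a_only) == len(A)`` and likewise for B;
    every peak lands in exactly one class of its own set.
    """

    both_a: list[Peak]
    a_only: list[Peak]
    both_b: list[Peak]
    b_only: list[Peak]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "both_a": len(self.both_a),
            "a_only": len(self.a_only),
            "both_b": len(self.both_b),
            "b_only": len(self.b_only),
        }


def _split(peaks: Sequence[Peak], other_index: MergedIntervalIndex):
    hit: list[Peak] = []
    miss: list[Peak] = []
    for p in peaks:
        overlaps = bool(
            other_index.hits(
                p.chrom,
                np.array([p.start], dtype=np.int64),
                np.array([p.end], dtype=np.int64),
            )[0]
        )
        (hit if overlaps else miss).append(p)
    return hit, miss


def stratify(a: Sequence[Peak], b: Sequence[Peak]) -> CistromePartition:
    """Partition each set by >=1 bp overlap with the other set.

    Empty inputs yield empty classes. Co-occurrence is any-overlap, not a
    reciprocal-fraction rule (the weakest assumption; configurable
    upstream by pre-filtering).
    """
    index_b = MergedIntervalIndex(b) if b else None
    index_a = MergedIntervalIndex(a) if a else None
    both_a, a_only = _split(a, index_b) if index_b else ([], list(a))
    both_b, b_only = _split(b, index_a) if index_a else ([], list(b))
    return CistromePartition(both_a, a_only, both_b, b_only)


@dataclass
class DensityMatrix:
    """Coverage profiles around peak centers, rows sorted by height.

    ``values[i, j]`` is the mean coverage in the j-th ``binsize``-bp bin
    of the window ``center +/- halfwidth`` around the i-th highest peak
    (ties broken by input order). Bins beyond a chromosome edge read 0.
    """

    values: np.ndarray
    row_order: list[str]
    bin_offsets: np.ndarray
    halfwidth: int
    binsize: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_order, columns=self.bin_offsets)


def density_matrix(
    peaks: Sequence[Peak],
    coverage: CoverageTrack,
    halfwidth: int = 2000,
    binsize: int = 10,
) -> DensityMatrix:
    """Build the peak-centered, height-sorted coverage matrix.

    The column count is exactly ``2 * halfwidth / binsize``; column labels
    are the bin start offsets relative to the peak center.
    """
    if halfwidth <= 0 or binsize <= 0:
        raise ValueError("halfwidth and binsize must be positive")
    if halfwidth % binsize != 0:
        raise ValueError("halfwidth must be divisible by binsize")
    n_bins = 2 * halfwidth // binsize
    order = sorted(range(len(peaks)), key=lambda i: (-peaks[i].height, i))
    values = np.zeros((len(peaks), n_bins), dtype=np.float64)
    names: list[str] = []
    for row, i in enumerate(order):
        p = peaks[i]
        c = p.center()
        window = coverage.window(p.chrom, c - halfwidth, c + halfwidth)
        values[row] = window.reshape(n_bins, binsize).mean(axis=1)
        names.append(p.name or f"peak_{i}")
    offsets = np.arange(-halfwidth, halfwidth, binsize)
    return DensityMatrix(values, names, offsets, halfwidth, binsize)
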