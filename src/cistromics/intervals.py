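"""Core genomic data model.

All coordinates are 0-based half-open everywhere in the package; formats
that use other conventions (GFF) are converted at the I/O boundary.
Chromosome names are compared as exact strings (no "chr" aliasing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name, compared as an exact string.
    start, end : int
        0-based, half-open; ``0 <= start < end`` is enforced, so every
        interval has positive length.
    strand : str
        One of ``+``, ``-``, ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def center(self) -> int:
        """Floor of the midpoint; always inside ``[start, end)``."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlap_length(self, other) > 0

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases between two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class Peak:
    """A called binding region: an interval with a height and a name.

    ``height`` is whatever the upstream peak caller reports in the BED
    score column (enrichment score or read count); it is only used for
    sorting and never interpreted further.
    """

    interval: GenomicInterval
    height: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError(f"negative peak height: {self.height}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def length(self) -> int:
        return self.interval.length()

    def center(self) -> int:
        return self.interval.center()


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand-aware TSS/TES anchors.

    Convention: on ``+`` the TSS is ``start`` and the TES is ``end``; on
    ``-`` the TSS is ``end`` and the TES is ``start`` (both still in the
    half-open coordinate frame, i.e. the exclusive bound names the
    minus-strand TSS).
    """

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be + or -, "
                f"got {self.interval.strand!r}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


class Workspace:
    """The mappable portion of the genome: sorted, disjoint segments.

    Randomized interval placements are drawn inside these segments, which
    is what makes the association test control for genomic background.
    Overlapping or book-ended input segments are merged on construction.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._segments: list[GenomicInterval] = []
        for chrom in sorted(by_chrom):
            merged: list[list[int]] = []
            for s, e in sorted(by_chrom[chrom]):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._segments.extend(
                GenomicInterval(chrom, s, e) for s, e in merged
            )
        if not self._segments:
            raise ValueError("workspace has no segments")
        self.chroms: list[str] = sorted(by_chrom)
        self._chrom_index = {c: i for i, c in enumerate(self.chroms)}
        self.seg_chrom_idx = np.array(
            [self._chrom_index[s.chrom] for s in self._segments], dtype=np.int64
        )
        self.seg_start = np.array([s.start for s in self._segments], dtype=np.int64)
        self.seg_end = np.array([s.end for s in self._segments], dtype=np.int64)
        self.seg_len = self.seg_end - self.seg_start

    @classmethod
    def from_chrom_lengths(cls, lengths: dict[str, int]) -> "Workspace":
        return cls(GenomicInterval(c, 0, n) for c, n in lengths.items())

    @property
    def segments(self) -> Sequence[GenomicInterval]:
        return tuple(self._segments)

    @property
    def total_length(self) -> int:
        return int(self.seg_len.sum())

    def contains(self, iv: GenomicInterval) -> bool:
        """True when the interval lies entirely within one segment."""
        ci = self._chrom_index.get(iv.chrom)
        if ci is None:
            return False
        mask = self.seg_chrom_idx == ci
        return bool(
            np.any((self.seg_start[mask] <= iv.start) & (iv.end <= self.seg_end[mask]))
        )

    def chrom_index(self, chrom: str) -> int:
        return self._chrom_index[chrom]


@dataclass
class CoverageTrack:
    """Per-base read depth for each chromosome.

    Values are non-negative reals held as one dense float32 vector per
    chromosome; positions outside a chromosome read as zero.
    """

    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=np.float32)
            if (arr < 0).any():
                raise ValueError(f"negative coverage on {chrom}")
            self.data[chrom] = arr

    def chrom_length(self, chrom: str) -> int:
        return len(self.data.get(chrom, ()))

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Coverage over [start, end), zero-padded beyond chromosome edges."""
        out = np.zeros(end - start, dtype=np.float32)
        arr = self.data.get(chrom)
        if arr is None:
            return out
        lo, hi = max(start, 0), min(end, len(arr))
        if lo < hi:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def total_mass(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))
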