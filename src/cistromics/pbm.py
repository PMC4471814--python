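"""PBM k-mer scoring of genomic regions, ROC analysis and motif building.

A protein-binding-microarray experiment summarizes in-vitro affinity as a
Z-score per DNA word of fixed length k. A genomic region is scored by its
best word over both strands; bound regions (true positives) are compared
with matched unbound regions (true negatives) by the area under the ROC
curve, which equals the Mann-Whitney probability that a random positive
outscores a random negative (ties counting one half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .association import MergedIntervalIndex, WorkspaceSampler
from .intervals import GenomicInterval, Peak, Workspace

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
BASES = "ACGT"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class KmerTable:
    """Lookup from DNA word (length k, alphabet ACGT) to a binding Z-score.

    Words absent from the table score as the table minimum: the designed
    probe library is not exhaustive over all k-mers, and a neutral floor
    avoids fabricating affinities.
    """

    def __init__(self, entries: Mapping[str, float]):
        if not entries:
            raise ValueError("empty k-mer table")
        lengths = {len(w) for w in entries}
        if len(lengths) != 1:
            raise ValueError(f"inconsistent word lengths: {sorted(lengths)}")
        self.k = lengths.pop()
        bad = [w for w in entries if set(w) - set(BASES)]
        if bad:
            raise ValueError(f"non-ACGT words in table: {bad[:3]}")
        self.entries = {w: float(z) for w, z in entries.items()}
        self.min_z = min(self.entries.values())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "KmerTable":
        return cls(dict(zip(df["word"], df["z"])))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.entries.items()), columns=["word", "z"]
        )

    def score_word(self, word: str) -> float:
        return self.entries.get(word, self.min_z)

    def __len__(self) -> int:
        return len(self.entries)


def score_region(seq: str, table: KmerTable, agg: str = "max") -> float:
    """Score a sequence by its k-mer content on both strands.

    Every k-length window of the sequence and of its reverse complement
    is looked up (windows containing N are skipped); the default
    aggregation is the maximum, matching best-site ROC methodology;
    "sum" and "mean" are alternatives.
    """
    if agg not in ("max", "sum", "mean"):
        raise ValueError(f"unknown aggregation {agg!r}")
    seq = seq.upper()
    k = table.k
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k = {k}")
    scores: list[float] = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        scores.append(max(table.score_word(w), table.score_word(reverse_complement(w))))
    if not scores:
        raise ValueError("no scorable window (all windows contain N)")
    if agg == "max":
        return max(scores)
    if agg == "sum":
        return float(sum(scores))
    return float(np.mean(scores))


def extract_sequences(genome: Mapping[str, str], intervals: Sequence[GenomicInterval | Peak]) -> list[str]:
    """Pull interval sequences out of an in-memory genome (chrom -> str)."""
    out = []
    for iv in intervals:
        chrom_seq = genome[iv.chrom]
        out.append(chrom_seq[iv.start : iv.end])
    return out


def sample_unbound(
    regions: Sequence[Peak],
    workspace: Workspace,
    n: int,
    seed: int = 0,
    max_attempts: int = 10_000,
    lengths: Sequence[int] | None = None,
) -> list[GenomicInterval]:
    """Sample `n` peak-free intervals matched in length to the bound set.

    Lengths are resampled (with replacement) from the bound-region length
    distribution (or the explicit `lengths` override); placements are
    uniform in the workspace and rejected on any base overlap with a
    bound region, so with zero regions this reduces to plain uniform
    placement. Deterministic per seed.
    """
    if lengths is None:
        if not regions:
            raise ValueError("no bound regions and no explicit length distribution")
        lengths = [r.length() for r in regions]
    rng = np.random.default_rng(seed)
    sampler = WorkspaceSampler(workspace)
    index = MergedIntervalIndex(regions) if regions else None
    lengths = np.array(lengths, dtype=np.int64)
    out: list[GenomicInterval] = []
    attempts = 0
    while len(out) < n:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {n} unbound intervals in {max_attempts} attempts; "
                "insufficient peak-free space"
            )
        length = int(rng.choice(lengths))
        seg_idx, start = sampler.sample(rng, length, 1)
        attempts += 1
        chrom = workspace.chroms[workspace.seg_chrom_idx[seg_idx[0]]]
        s, e = int(start[0]), int(start[0]) + length
        if index is not None and index.hits(chrom, np.array([s]), np.array([e]))[0]:
            continue
        out.append(GenomicInterval(chrom, s, e))
    return out


@dataclass
class ROCResult:
    """AUC with the Mann-Whitney U statistic it is computed from.

    Invariant: ``auc == u_statistic / (n_pos * n_neg)``.
    """

    auc: float
    u_statistic: float
    p_value: float
    n_pos: int
    n_neg: int


def roc_auc(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    alternative: str = "greater",
    exact_limit: int = 10_000,
) -> ROCResult:
    """AUC and Mann-Whitney test for positive vs negative score lists.

    AUC = (#{pos > neg} + 0.5 * #{pos == neg}) / (n_pos * n_neg),
    computed via midranks. The p-value uses the exact U distribution when
    ``n_pos * n_neg <= exact_limit`` and there are no ties, otherwise the
    tie-corrected normal approximation.
    """
    pos = np.asarray(pos_scores, dtype=np.float64)
    neg = np.asarray(neg_scores, dtype=np.float64)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = float(ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2)
    auc = u / (len(pos) * len(neg))
    has_ties = len(np.unique(np.concatenate([pos, neg]))) < len(pos) + len(neg)
    method = "exact" if (len(pos) * len(neg) <= exact_limit and not has_ties) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mannwhitneyu(pos, neg, alternative=alternative, method=method)
    return ROCResult(auc, u, float(res.pvalue), len(pos), len(neg))


@dataclass
class MotifPFM:
    """Position frequency matrix: 4 base rows (ACGT) x k columns.

    Every column sums to 1 and all entries are non-negative.
    """

    matrix: np.ndarray  # shape (4, k)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape[0] != 4:
            raise ValueError("PFM must have 4 base rows")
        if (self.matrix < 0).any():
            raise ValueError("negative PFM entries")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PFM columns must sum to 1")

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(BASES))


def pfm_from_top_kmers(table: KmerTable, top_n: int = 50) -> MotifPFM:
    """Position frequencies over the `top_n` highest-Z words.

    Words are ranked by Z descending with lexicographic tie-breaking,
    the standard route from a ranked binding library to a motif.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if top_n > len(table):
        raise ValueError(f"top_n = {top_n} exceeds table size {len(table)}")
    ranked = sorted(table.entries.items(), key=lambda kv: (-kv[1], kv[0]))
    words = [w for w, _ in ranked[:top_n]]
    counts = np.zeros((4, table.k), dtype=np.float64)
    base_index = {b: i for i, b in enumerate(BASES)}
    for w in words:
        for j, b in enumerate(w):
            counts[base_index[b], j] += 1
    return MotifPFM(counts / top_n)
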