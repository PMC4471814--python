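"""Gene-relative annotation of peaks.

Peak centers are assigned to strand-aware bins relative to their nearest
gene (five 1-kb upstream windows, the gene body, five 1-kb downstream
windows, or DISTAL), promoters are categorized by which factors bind
them, and per-bin fold enrichment is measured against the same uniform
re-placement null as the association test.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .association import MergedIntervalIndex, WorkspaceSampler
from .intervals import GeneModel, GenomicInterval, Peak, Workspace

FLANK_BINS = 5
BIN_WIDTH = 1000
BIN_LABELS = (
    [f"U{i}" for i in range(FLANK_BINS, 0, -1)]
    + ["BODY"]
    + [f"D{i}" for i in range(1, FLANK_BINS + 1)]
    + ["DISTAL"]
)
_LABEL_INDEX = {lab: i for i, lab in enumerate(BIN_LABELS)}
DISTAL = _LABEL_INDEX["DISTAL"]
BODY = _LABEL_INDEX["BODY"]


class GeneIndex:
    """Per-chromosome sorted gene arrays for vectorized nearest-gene queries.

    Assumes genes on a chromosome are non-overlapping (ties in distance
    are broken by smallest gene_id); the nearest gene to a point is then
    always one of the two neighbors in start order.
    """

    def __init__(self, genes: Sequence[GeneModel]):
        if not genes:
            raise ValueError("gene list is empty")
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        self._chroms = {}
        for chrom, gs in by_chrom.items():
            gs = sorted(gs, key=lambda g: (g.start, g.gene_id))
            ids = np.array([g.gene_id for g in gs])
            # lexicographic rank for deterministic tie-breaking
            id_rank = np.argsort(np.argsort(ids, kind="stable"), kind="stable")
            self._chroms[chrom] = {
                "start": np.array([g.start for g in gs], dtype=np.int64),
                "end": np.array([g.end for g in gs], dtype=np.int64),
                "orient": np.array([1 if g.strand == "+" else -1 for g in gs]),
                "tss": np.array([g.tss for g in gs], dtype=np.int64),
                "tes": np.array([g.tes for g in gs], dtype=np.int64),
                "ids": ids,
                "id_rank": id_rank,
            }

    def nearest(self, chrom: str, pos: np.ndarray):
        """Index of the nearest gene (span distance) for each position.

        Returns (gene array dict, index array) or None when the
        chromosome has no genes.
        """
        entry = self._chroms.get(chrom)
        if entry is None:
            return None
        S, E = entry["start"], entry["end"]
        rank = entry["id_rank"]
        n = len(S)
        j = np.searchsorted(S, pos, side="right") - 1
        c1 = np.clip(j, 0, n - 1)
        c2 = np.clip(j + 1, 0, n - 1)

        def dist(c):
            inside = (S[c] <= pos) & (pos < E[c])
            below = pos < S[c]
            d = np.where(below, S[c] - pos, pos - (E[c] - 1))
            return np.where(inside, 0, d)

        d1, d2 = dist(c1), dist(c2)
        pick2 = (d2 < d1) | ((d2 == d1) & (rank[c2] < rank[c1]))
        return entry, np.where(pick2, c2, c1)

    def labels_and_distance(self, chrom: str, pos: np.ndarray):
        """Bin label index, nearest gene index and oriented TSS distance."""
        res = self.nearest(chrom, pos)
        if res is None:
            return (
                np.full(len(pos), DISTAL, dtype=np.int64),
                None,
                np.zeros(len(pos), dtype=np.int64),
            )
        entry, gi = res
        S, E = entry["start"][gi], entry["end"][gi]
        o = entry["orient"][gi]
        anchor_tss = np.where(o > 0, entry["tss"][gi], entry["tss"][gi] - 1)
        anchor_tes = np.where(o > 0, entry["tes"][gi], entry["tes"][gi] - 1)
        d_tss = o * (pos - anchor_tss)
        d_tes = o * (pos - anchor_tes)
        labels = np.full(len(pos), DISTAL, dtype=np.int64)
        span = FLANK_BINS * BIN_WIDTH
        up = (d_tss >= -span) & (d_tss < 0)
        labels[up] = (FLANK_BINS - 1) - (-d_tss[up] - 1) // BIN_WIDTH
        down = (d_tes >= 0) & (d_tes < span)
        labels[down] = BODY + 1 + d_tes[down] // BIN_WIDTH
        inside = (S <= pos) & (pos < E)
        labels[inside] = BODY
        return labels, gi, d_tss


def assign_gene_bins(peaks: Sequence[Peak], genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Assign each peak center to a bin relative to its nearest gene.

    Returns a frame with one row per peak: peak name, nearest gene_id,
    bin label and the signed TSS distance in the gene's transcriptional
    orientation (negative = upstream).
    """
    gindex = GeneIndex(genes)
    by_chrom: dict[str, list[tuple[int, Peak]]] = {}
    for i, p in enumerate(peaks):
        by_chrom.setdefault(p.chrom, []).append((i, p))
    out: list[dict | None] = [None] * len(peaks)
    for chrom, items in by_chrom.items():
        pos = np.array([p.center() for _, p in items], dtype=np.int64)
        labels, gi, d_tss = gindex.labels_and_distance(chrom, pos)
        entry = gindex._chroms.get(chrom)
        for k, (i, p) in enumerate(items):
            gene = entry["ids"][gi[k]] if entry is not None else ""
            out[i] = {
                "peak": p.name or f"peak_{i}",
                "gene_id": gene,
                "bin": BIN_LABELS[labels[k]],
                "distance_tss": int(d_tss[k]),
            }
    return pd.DataFrame([r for r in out if r is not None])


def _bin_counts(labels: np.ndarray) -> np.ndarray:
    return np.bincount(labels, minlength=len(BIN_LABELS)).astype(np.float64)


def bin_enrichment(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    workspace: Workspace,
    n_samples: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-bin fold enrichment of peak centers against the placement null.

    The same randomized placements (uniform re-placement of every peak,
    length-preserving, as in the association test) are reused for all
    bins; fold = observed bin count over the null mean, with an add-one
    empirical p for enrichment.
    """
    if not peaks:
        raise ValueError("peak list is empty")
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    gindex = GeneIndex(genes)
    obs_labels = []
    for p in peaks:
        if not workspace.contains(p.interval):
            raise ValueError(f"peak interval {p.interval} outside workspace")
        lab, _, _ = gindex.labels_and_distance(
            p.chrom, np.array([p.center()], dtype=np.int64)
        )
        obs_labels.append(lab[0])
    observed = _bin_counts(np.array(obs_labels, dtype=np.int64))

    sampler = WorkspaceSampler(workspace)
    rng = np.random.default_rng(seed)
    lengths = np.array([p.length() for p in peaks], dtype=np.int64)
    null_counts = np.zeros((n_samples, len(BIN_LABELS)), dtype=np.float64)
    for length in np.unique(lengths):
        count = int((lengths == length).sum())
        seg_idx, starts = sampler.sample(rng, int(length), count * n_samples)
        centers = starts + int(length) // 2
        chrom_idx = workspace.seg_chrom_idx[seg_idx]
        sample_col = np.broadcast_to(
            np.arange(n_samples), (count, n_samples)
        ).ravel()
        labels = np.empty(count * n_samples, dtype=np.int64)
        for ci in np.unique(chrom_idx):
            mask = chrom_idx == ci
            lab, _, _ = gindex.labels_and_distance(
                workspace.chroms[ci], centers[mask]
            )
            labels[mask] = lab
        np.add.at(null_counts, (sample_col, labels), 1.0)

    mean = null_counts.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean > 0, observed / np.where(mean > 0, mean, 1), np.inf)
    fold = np.where((mean == 0) & (observed == 0), 1.0, fold)
    exceed = (null_counts >= observed[None, :]).sum(axis=0)
    p = (1 + exceed) / (1 + n_samples)
    return pd.DataFrame(
        {
            "bin": BIN_LABELS,
            "observed": observed,
            "expected_mean": mean,
            "fold": fold,
            "empirical_p": p,
        }
    ).set_index("bin")


def promoter_window(gene: GeneModel, upstream: int = 10_000, downstream: int = 500) -> GenomicInterval:
    """Strand-aware promoter span: `upstream` bp before the TSS plus
    `downstream` bp past it (clipped at the chromosome origin)."""
    if gene.strand == "+":
        lo, hi = gene.tss - upstream, gene.tss + downstream
    else:
        lo, hi = gene.tss - downstream, gene.tss + upstream
    return GenomicInterval(gene.chrom, max(lo, 0), hi, gene.strand)


def categorize_promoters(
    genes: Sequence[GeneModel],
    a_peaks: Sequence[Peak],
    b_peaks: Sequence[Peak],
    upstream: int = 10_000,
    downstream: int = 500,
) -> pd.DataFrame:
    """Classify gene promoters by factor occupancy.

    Category 1: promoter overlaps (>=1 bp) peaks of both factors;
    2: B only; 3: A only; 0: neither. Categories are mutually exclusive
    and exhaustive over genes. Factor A plays the IRF-like role and B
    the NF-kB-like role in the pipeline's naming.
    """
    index_a = MergedIntervalIndex(a_peaks) if a_peaks else None
    index_b = MergedIntervalIndex(b_peaks) if b_peaks else None
    rows = []
    for g in genes:
        win = promoter_window(g, upstream, downstream)
        s = np.array([win.start], dtype=np.int64)
        e = np.array([win.end], dtype=np.int64)
        has_a = bool(index_a.hits(g.chrom, s, e)[0]) if index_a else False
        has_b = bool(index_b.hits(g.chrom, s, e)[0]) if index_b else False
        category = 1 if (has_a and has_b) else 2 if has_b else 3 if has_a else 0
        rows.append({"gene_id": g.gene_id, "category": category})
    return pd.DataFrame(rows)


def tes_downstream_fraction(
    peaks: Sequence[Peak], genes: Sequence[GeneModel], window: int = 5000
) -> float:
    """Fraction of peak-targeted genes with a peak downstream of the TES.

    A gene is "targeted" when >=1 peak is assigned to it in a non-DISTAL
    bin; it counts as downstream-bound when >=1 of its peaks sits in a
    D bin within `window` bases of the TES.
    """
    n_bins = window // BIN_WIDTH
    down_labels = {f"D{i}" for i in range(1, n_bins + 1)}
    assignments = assign_gene_bins(peaks, genes)
    non_distal = assignments[assignments["bin"] != "DISTAL"]
    eligible = set(non_distal["gene_id"])
    if not eligible:
        raise ValueError("no gene has an assigned non-DISTAL peak")
    with_down = set(non_distal.loc[non_distal["bin"].isin(down_labels), "gene_id"])
    return len(with_down) / len(eligible)
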