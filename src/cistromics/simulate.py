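"""Synthetic inputs with planted, parameterized structure.

Every generator is a pure function of its configuration: all randomness
flows from a single master seed through fixed per-generator substreams
(numpy SeedSequence spawn keys), so reruns are bit-identical and every
planted effect is recorded in a truth table.

The generators emulate a two-factor ChIP-seq study: factor B (the
NF-kB-like factor) binds with a positional bias toward TSSs, a planted
fraction of factor A (the IRF-like factor) peaks co-occur with B peaks,
coverage tracks pile up over the peaks, an ISRE-like motif is written
into designated peak sequences with a k-mer table concentrating high
Z-scores on it, and a WT/KO stimulation time course carries planted
fold-change effects removed in the knockout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import WorkspaceSampler
from .intervals import CoverageTrack, GeneModel, GenomicInterval, Peak, Workspace
from .pbm import KmerTable

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

GENE_SPACING = 10_000

_STREAMS = {"genome": 0, "genes": 1, "peaks": 2, "coverage": 3, "motifs": 4, "expression": 5}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic two-factor ChIP-seq experiment.

    Defaults describe a desk-scale version of the real study: a 10-Mb
    two-chromosome genome, a few hundred genes, ~1,000 peaks per factor
    of realistic ChIP peak width, 30% planted co-occurrence, a moderate
    TSS bias, the ISRE consensus as the planted motif (k = 12 words),
    and a 2.5-fold knockout-removable expression effect with noise such
    that the per-gene t statistic is about 4 at three replicates.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 300
    gene_length: tuple[int, int] = (2_000, 8_000)
    n_peaks_a: int = 1_000
    n_peaks_b: int = 1_000
    co_occurrence_fraction: float = 0.30
    tss_bias_fraction: float = 0.30
    peak_length: tuple[int, int] = (150, 350)
    coverage_depth_scale: float = 5.0
    coverage_background: float = 0.2
    motif_consensus: str = "RNGAAANNGAAACT"  # canonical ISRE
    kmer_k: int = 12
    kmer_table_size: int = 3_072
    planted_effect_genes: int = 200
    planted_log2_fc: float = math.log2(2.5)
    noise_sd: float = 0.40
    samples_per_condition: int = 3
    times: tuple[float, ...] = (0, 1, 2, 4, 8)

    def __post_init__(self) -> None:
        for name in ("co_occurrence_fraction", "tss_bias_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.peak_length[0] <= 0 or self.peak_length[0] > self.peak_length[1]:
            raise ValueError(f"bad peak_length range {self.peak_length}")
        if self.n_genes * (self.gene_length[1] + GENE_SPACING) > self.n_chroms * self.chrom_length:
            raise ValueError("gene packing infeasible for this genome size")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the master seed (documented stream split)."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(ss)

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, 4, size=length)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode()


def generate_genome_and_genes(
    cfg: SyntheticConfig, with_sequence: bool = True
) -> tuple[dict[str, str] | None, list[GeneModel], Workspace]:
    """I.i.d. uniform-ACGT genome, non-overlapping genes, whole-genome workspace.

    Genes are packed with >=10 kb spacing and random strands; set
    `with_sequence=False` to skip sequence synthesis for coordinate-only
    experiments on large genomes.
    """
    rng_genome = cfg.rng("genome")
    rng_genes = cfg.rng("genes")
    genome = None
    if with_sequence:
        genome = {c: _random_sequence(rng_genome, cfg.chrom_length) for c in cfg.chrom_names}
    # distribute genes round-robin across chromosomes
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    gi = 0
    for chrom, count in zip(cfg.chrom_names, per_chrom):
        if count == 0:
            continue
        lengths = rng_genes.integers(cfg.gene_length[0], cfg.gene_length[1] + 1, size=count)
        offset = GENE_SPACING // 2
        packed = int(lengths.sum()) + count * GENE_SPACING + offset
        slack = cfg.chrom_length - packed
        if slack < 0:
            raise ValueError(f"gene packing infeasible on {chrom}")
        cuts = np.sort(rng_genes.integers(0, slack + 1, size=count))
        pos = offset
        for j in range(count):
            start = int(cuts[j]) + pos
            end = start + int(lengths[j])
            strand = "+" if rng_genes.integers(0, 2) == 0 else "-"
            gi += 1
            genes.append(GeneModel(f"g{gi:05d}", GenomicInterval(chrom, start, end, strand)))
            pos += int(lengths[j]) + GENE_SPACING
    workspace = Workspace.from_chrom_lengths(cfg.chrom_lengths)
    return genome, genes, workspace


def _clip_peak(chrom: str, center: int, length: int, chrom_len: int) -> tuple[int, int]:
    start = center - length // 2
    start = max(0, min(start, chrom_len - length))
    return start, start + length


def generate_peaks(
    cfg: SyntheticConfig, genes: Sequence[GeneModel], workspace: Workspace
) -> tuple[list[Peak], list[Peak], pd.DataFrame]:
    """Two peak sets with planted TSS bias (B) and co-occurrence (A with B).

    B peaks are placed first: a `tss_bias_fraction` of them centered
    inside the 1-kb window directly upstream of a random TSS, the rest
    uniform. Then a `co_occurrence_fraction` of A peaks are centered
    within a +/-(min peak length / 2 - 1) jitter of a random B peak
    (guaranteeing >=1 bp overlap while varying overlap widths); the rest
    are placed independently and uniformly. Heights are log-normal.

    Returns (a_peaks, b_peaks, truth) where truth records the planted
    role of every peak.
    """
    rng = cfg.rng("peaks")
    sampler = WorkspaceSampler(workspace)
    lmin, lmax = cfg.peak_length
    chrom_len = cfg.chrom_lengths
    truth_rows = []

    def uniform_center(length: int) -> tuple[str, int]:
        seg_idx, start = sampler.sample(rng, length, 1)
        chrom = workspace.chroms[workspace.seg_chrom_idx[seg_idx[0]]]
        return chrom, int(start[0]) + length // 2

    b_peaks: list[Peak] = []
    n_tss = round(cfg.tss_bias_fraction * cfg.n_peaks_b) if genes else 0
    for i in range(cfg.n_peaks_b):
        length = int(rng.integers(lmin, lmax + 1))
        height = float(rng.lognormal(1.0, 0.5))
        if i < n_tss:
            g = genes[int(rng.integers(0, len(genes)))]
            off = int(rng.integers(0, 1000))
            center = (g.tss - 1 - off) if g.strand == "+" else (g.tss + off)
            chrom = g.chrom
            placement = "tss"
        else:
            chrom, center = uniform_center(length)
            placement = "uniform"
        s, e = _clip_peak(chrom, center, length, chrom_len[chrom])
        name = f"b_{i + 1:05d}"
        b_peaks.append(Peak(GenomicInterval(chrom, s, e), height, name))
        truth_rows.append({"peak": name, "set": "b", "placement": placement})

    a_peaks: list[Peak] = []
    n_co = round(cfg.co_occurrence_fraction * cfg.n_peaks_a) if b_peaks else 0
    jitter = max(lmin // 2 - 1, 0)
    for i in range(cfg.n_peaks_a):
        length = int(rng.integers(lmin, lmax + 1))
        height = float(rng.lognormal(1.0, 0.5))
        if i < n_co:
            partner = b_peaks[int(rng.integers(0, len(b_peaks)))]
            delta = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            chrom, center = partner.chrom, partner.center() + delta
            placement = "cooccur"
        else:
            chrom, center = uniform_center(length)
            placement = "uniform"
        s, e = _clip_peak(chrom, center, length, chrom_len[chrom])
        name = f"a_{i + 1:05d}"
        a_peaks.append(Peak(GenomicInterval(chrom, s, e), height, name))
        truth_rows.append({"peak": name, "set": "a", "placement": placement})

    return a_peaks, b_peaks, pd.DataFrame(truth_rows)


def generate_polii_peaks(
    cfg: SyntheticConfig, genes: Sequence[GeneModel], fraction: float = 0.5
) -> list[Peak]:
    """PolII-like occupancy: one peak at the TSS of a random gene subset.

    Emulates polymerase recruitment at transcribed promoters; drawn from
    the "peaks" substream after the A/B sets, so it is deterministic but
    independent of them only through the seed.
    """
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(_STREAMS["peaks"], 1))
    rng = np.random.default_rng(ss)
    lmin, lmax = cfg.peak_length
    out: list[Peak] = []
    for i, g in enumerate(genes):
        if rng.random() >= fraction:
            continue
        length = int(rng.integers(lmin, lmax + 1))
        height = float(rng.lognormal(1.0, 0.5))
        center = g.tss if g.strand == "+" else g.tss - 1
        s, e = _clip_peak(g.chrom, center, length, cfg.chrom_lengths[g.chrom])
        out.append(Peak(GenomicInterval(g.chrom, s, e), height, f"pol_{i + 1:05d}"))
    return out


def generate_coverage(
    cfg: SyntheticConfig, peaks: Sequence[Peak], background: float | None = None
) -> CoverageTrack:
    """Triangular read pileups over peaks plus Poisson background.

    Each peak contributes a triangle spanning its interval with apex
    ``coverage_depth_scale * height`` at the center; the background is
    i.i.d. Poisson per base at rate `coverage_background`.
    """
    rng = cfg.rng("coverage")
    if background is None:
        background = cfg.coverage_background
    data = {}
    for chrom, length in cfg.chrom_lengths.items():
        if background > 0:
            arr = rng.poisson(background, size=length).astype(np.float32)
        else:
            arr = np.zeros(length, dtype=np.float32)
        data[chrom] = arr
    for p in peaks:
        arr = data[p.chrom]
        c = p.center()
        half = max(p.length() // 2, 1)
        apex = cfg.coverage_depth_scale * p.height
        lo, hi = max(p.start, 0), min(p.end, len(arr))
        x = np.arange(lo, hi)
        arr[lo:hi] += (apex * np.clip(1.0 - np.abs(x - c) / half, 0.0, None)).astype(
            np.float32
        )
    return CoverageTrack(data)


def consensus_realizations(consensus: str) -> list[str]:
    """All concrete sequences matching an IUPAC consensus."""
    choices = [IUPAC[b] for b in consensus.upper()]
    return ["".join(p) for p in itertools.product(*choices)]


def realize_consensus(rng: np.random.Generator, consensus: str) -> str:
    return "".join(
        IUPAC[b][int(rng.integers(0, len(IUPAC[b])))] for b in consensus.upper()
    )


def plant_motifs(
    cfg: SyntheticConfig,
    genome: Mapping[str, str],
    peaks: Sequence[Peak],
) -> tuple[dict[str, str], KmerTable, pd.DataFrame]:
    """Write one consensus realization at each designated peak center and
    build a matching k-mer table.

    The table assigns Z ~ N(8, 1) to every k-mer window of every
    consensus realization and Z ~ N(0, 1) to a decoy set of random
    k-mers, padding the table to `kmer_table_size` entries.
    """
    if len(cfg.motif_consensus) > min((p.length() for p in peaks), default=10**9):
        raise ValueError("motif longer than the shortest designated peak")
    rng = cfg.rng("motifs")
    chrom_seqs = {c: bytearray(s, "ascii") for c, s in genome.items()}
    truth_rows = []
    m = len(cfg.motif_consensus)
    for p in peaks:
        word = realize_consensus(rng, cfg.motif_consensus)
        pos = p.center() - m // 2
        pos = max(0, min(pos, len(chrom_seqs[p.chrom]) - m))
        chrom_seqs[p.chrom][pos : pos + m] = word.encode()
        truth_rows.append({"peak": p.name, "chrom": p.chrom, "pos": pos, "motif": word})

    # like a designed probe library, all high-affinity words share one
    # alignment frame (the central k-window of the consensus)
    k = cfg.kmer_k
    off = (m - k) // 2
    high_words = sorted(
        {real[off : off + k] for real in consensus_realizations(cfg.motif_consensus)}
    )
    entries = {w: float(rng.normal(8.0, 1.0)) for w in high_words}
    high_set = set(high_words)
    while len(entries) < cfg.kmer_table_size:
        w = _random_sequence(rng, k)
        if w not in high_set and w not in entries:
            entries[w] = float(rng.normal(0.0, 1.0))
    new_genome = {c: bytes(b).decode() for c, b in chrom_seqs.items()}
    return new_genome, KmerTable(entries), pd.DataFrame(truth_rows)


def generate_expression(
    cfg: SyntheticConfig,
    genes: Sequence[GeneModel] | Sequence[str],
    categories: pd.DataFrame | None = None,
    genotypes: tuple[str, ...] = ("WT", "KO_A", "KO_B"),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """WT/KO stimulation time course with planted, KO-removable effects.

    Responsive genes (preferentially drawn from category-1 genes when a
    promoter categorization is supplied) gain `planted_log2_fc` at every
    post-stimulation time point in WT. In a knockout, the effect is
    removed for genes whose category says the knocked-out factor binds
    their promoter (category 1: both knockouts; 2: KO_B; 3: KO_A).
    Gaussian noise with `noise_sd` is added throughout.

    Returns (expression matrix, sample metadata, truth table).
    """
    rng = cfg.rng("expression")
    gene_ids = [g.gene_id if isinstance(g, GeneModel) else str(g) for g in genes]
    if not gene_ids:
        raise ValueError("no genes supplied")
    n_resp = min(cfg.planted_effect_genes, len(gene_ids))
    cat_of: dict[str, int] = {}
    if categories is not None:
        cat_of = dict(zip(categories["gene_id"], categories["category"]))
        pool1 = [g for g in gene_ids if cat_of.get(g, 0) == 1]
        rest = [g for g in gene_ids if cat_of.get(g, 0) != 1]
        take1 = min(n_resp, len(pool1))
        responsive = list(rng.choice(pool1, size=take1, replace=False)) + list(
            rng.choice(rest, size=n_resp - take1, replace=False)
        )
    else:
        responsive = list(rng.choice(gene_ids, size=n_resp, replace=False))
    responsive_set = set(responsive)

    def depends(gene: str) -> str:
        c = cat_of.get(gene, 1 if categories is None else 0)
        return {1: "both", 2: "b", 3: "a"}.get(c, "none")

    meta_rows = []
    columns = []
    for gt in genotypes:
        for t in cfg.times:
            for r in range(1, cfg.samples_per_condition + 1):
                sid = f"{gt}_t{t:g}_r{r}"
                columns.append((sid, gt, t))
                meta_rows.append(
                    {"sample_id": sid, "genotype": gt, "time_hr": t, "replicate": r}
                )
    baseline = rng.normal(8.0, 1.0, size=len(gene_ids))
    values = np.empty((len(gene_ids), len(columns)))
    dep = np.array([depends(g) for g in gene_ids])
    resp = np.array([g in responsive_set for g in gene_ids])
    for j, (sid, gt, t) in enumerate(columns):
        effect = np.zeros(len(gene_ids))
        if t > 0:
            active = resp.copy()
            if gt == "KO_A":
                active &= ~np.isin(dep, ("a", "both"))
            elif gt == "KO_B":
                active &= ~np.isin(dep, ("b", "both"))
            effect[active] = cfg.planted_log2_fc
        values[:, j] = baseline + effect + rng.normal(0, cfg.noise_sd, size=len(gene_ids))
    expr = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                        columns=[c[0] for c in columns])
    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "responsive": resp,
            "effect_log2_fc": np.where(resp, cfg.planted_log2_fc, 0.0),
            "depends_on": dep,
        }
    )
    return expr, meta, truth


def simulate_two_group_matrix(
    n_genes: int,
    n_planted: int,
    log2_fc: float,
    noise_sd: float,
    n_per_group: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], list[str], set[str]]:
    """Minimal two-group log2 matrix with the first `n_planted` genes shifted.

    Convenience generator for differential-expression calibration and
    power experiments; returns (matrix, group1 columns, group2 columns,
    planted gene ids).
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    g1 = [f"s1_r{r + 1}" for r in range(n_per_group)]
    g2 = [f"s2_r{r + 1}" for r in range(n_per_group)]
    baseline = rng.normal(8.0, 1.0, size=n_genes)
    x = baseline[:, None] + rng.normal(0, noise_sd, size=(n_genes, 2 * n_per_group))
    x[:n_planted, :n_per_group] += log2_fc
    df = pd.DataFrame(x, index=pd.Index(gene_ids, name="gene_id"), columns=g1 + g2)
    return df, g1, g2, set(gene_ids[:n_planted])
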