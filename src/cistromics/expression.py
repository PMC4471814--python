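"""Permutation-based differential expression and gene-set enrichment.

The moderated d-statistic follows the SAM construction: the ordinary
two-sample t numerator divided by the pooled standard error plus a small
positive "fudge" constant s0 that stabilizes genes with tiny variance.
Significance uses label permutations: for each candidate |d| cutoff, the
false-call estimate is the median, across permutations, of the number of
permuted statistics exceeding the cutoff, divided by the observed count,
monotonized into per-gene q-values. Gene-set enrichment is the one-sided
hypergeometric tail with Benjamini-Hochberg correction across sets.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom


@dataclass
class ExpressionMatrix:
    """A genes x samples log2-intensity matrix with a sample sheet.

    `meta` must carry sample_id, genotype (e.g. WT / a KO label),
    time_hr and replicate; every matrix column must appear in it.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = set(self.values.columns) - set(self.meta["sample_id"])
        if missing:
            raise ValueError(f"samples absent from metadata: {sorted(missing)}")

    def samples(self, genotype: str | None = None, time_hr: float | None = None) -> list[str]:
        m = self.meta
        if genotype is not None:
            m = m[m["genotype"] == genotype]
        if time_hr is not None:
            m = m[m["time_hr"] == time_hr]
        return [s for s in m["sample_id"] if s in self.values.columns]

    @property
    def times(self) -> list[float]:
        return sorted(self.meta["time_hr"].unique())


def _pooled_se(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Row-wise pooled standard error of the mean difference (Tusher-style)."""
    n1, n2 = x1.shape[1], x2.shape[1]
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    return np.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2))


def sam_statistic(group1: Sequence[float], group2: Sequence[float], s0: float = 0.0) -> float:
    """Moderated difference statistic d = (mean1 - mean2) / (s + s0).

    `s` is the pooled standard error of the mean difference; at s0 = 0
    this is the ordinary equal-variance two-sample t statistic.
    """
    x1 = np.asarray(group1, dtype=np.float64)[None, :]
    x2 = np.asarray(group2, dtype=np.float64)[None, :]
    if x1.shape[1] < 2 or x2.shape[1] < 2:
        raise ValueError("each group needs at least 2 values")
    s = float(_pooled_se(x1, x2)[0])
    if s + s0 == 0:
        raise ValueError("zero variance in both groups with s0 = 0")
    return float(x1.mean() - x2.mean()) / (s + s0)


def _d_vector(x1: np.ndarray, x2: np.ndarray, s0: float) -> np.ndarray:
    diff = x1.mean(axis=1) - x2.mean(axis=1)
    s = _pooled_se(x1, x2)
    return diff / (s + s0)


def _count_ge(sorted_abs_desc: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """#{values >= t} for each threshold, given values sorted descending."""
    asc = sorted_abs_desc[::-1]
    return len(asc) - np.searchsorted(asc, thresholds, side="left")


def _distinct_group_assignments(n1: int, n2: int, n_permutations: int, rng: np.random.Generator):
    """Index tuples (into the pooled columns) taken by group 1.

    Enumerates all C(n1+n2, n1) assignments when that is no more than the
    requested count (with a warning), otherwise samples distinct ones.
    """
    n = n1 + n2
    total = math.comb(n, n1)
    if total <= n_permutations:
        if total < n_permutations:
            warnings.warn(
                f"only {total} distinct permutations exist; using all of them"
            )
        return [tuple(c) for c in itertools.combinations(range(n), n1)]
    chosen: set[tuple[int, ...]] = set()
    while len(chosen) < n_permutations:
        chosen.add(tuple(sorted(rng.choice(n, size=n1, replace=False))))
    return sorted(chosen)


def sam_test(
    matrix: pd.DataFrame,
    group1: Sequence[str],
    group2: Sequence[str],
    n_permutations: int = 1000,
    seed: int = 0,
    fdr_threshold: float = 0.10,
    fold_threshold: float | None = None,
    s0: float | None = None,
) -> pd.DataFrame:
    """Permutation differential expression between two sample groups.

    Parameters
    ----------
    matrix : DataFrame
        Genes x samples of log2 intensities.
    group1, group2 : sequences of column names
        The contrast is group1 minus group2 (>=2 samples each).
    fold_threshold : float or None
        Intensity-scale fold filter applied on top of the q cutoff
        (strict inequality, e.g. 2.0 keeps only >2-fold changes on the
        antilogged means); None disables it.
    s0 : float or None
        Fudge constant; defaults to the median per-gene pooled SE.

    Returns one row per gene: log2_fc, d_statistic, q_value and call in
    {up, down, ns}. Deterministic for a fixed seed.
    """
    g1 = list(group1)
    g2 = list(group2)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    x1 = matrix[g1].to_numpy(dtype=np.float64)
    x2 = matrix[g2].to_numpy(dtype=np.float64)
    if s0 is None:
        s0 = float(np.median(_pooled_se(x1, x2)))
    d = _d_vector(x1, x2, s0)
    abs_d = np.abs(d)
    order = np.argsort(-abs_d, kind="stable")
    sorted_abs = abs_d[order]
    obs_counts = _count_ge(sorted_abs, abs_d)

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x1, x2], axis=1)
    n1 = x1.shape[1]
    assignments = _distinct_group_assignments(n1, x2.shape[1], n_permutations, rng)
    perm_counts = np.empty((len(assignments), len(d)), dtype=np.float64)
    all_idx = np.arange(pooled.shape[1])
    for pi, take in enumerate(assignments):
        take = np.asarray(take)
        rest = np.setdiff1d(all_idx, take, assume_unique=True)
        d_perm = _d_vector(pooled[:, take], pooled[:, rest], s0)
        perm_counts[pi] = _count_ge(np.sort(np.abs(d_perm))[::-1], abs_d)
    median_false = np.median(perm_counts, axis=0)
    q = np.clip(median_false / np.maximum(obs_counts, 1), 0.0, 1.0)
    # monotonize: a gene with larger |d| never gets a larger q
    asc_rank = np.argsort(abs_d, kind="stable")
    q_sorted = np.minimum.accumulate(q[asc_rank])
    q_mono = np.empty_like(q)
    q_mono[asc_rank] = q_sorted

    log2_fc = x1.mean(axis=1) - x2.mean(axis=1)
    fc = np.power(2.0, log2_fc)  # antilogged means, intensity scale
    passes = q_mono <= fdr_threshold
    if fold_threshold is not None:
        passes &= (fc > fold_threshold) | (fc < 1.0 / fold_threshold)
    call = np.where(~passes, "ns", np.where(log2_fc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "gene_id": matrix.index,
            "log2_fc": log2_fc,
            "d_statistic": d,
            "q_value": q_mono,
            "call": call,
        }
    ).set_index("gene_id")


def lps_response_genes(
    em: ExpressionMatrix,
    fold_threshold: float = 2.0,
    fdr_threshold: float = 0.01,
    genotype: str = "WT",
    times: Iterable[float] | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[set[str], set[str]]:
    """Genes strongly responding to stimulation in the given genotype.

    Each post-stimulation time point is contrasted against the matched
    0-hr baseline; a gene is "up" ("down") when any time point calls it
    up (down) at the strict >fold_threshold change and q cutoff. Returns
    (up, down) gene-id sets.
    """
    baseline = em.samples(genotype=genotype, time_hr=0)
    if not baseline:
        raise ValueError(f"no 0-hr baseline samples for genotype {genotype!r}")
    stim_times = [t for t in (times if times is not None else em.times) if t != 0]
    if not stim_times:
        raise ValueError("no stimulated time points present")
    up: set[str] = set()
    down: set[str] = set()
    for i, t in enumerate(stim_times):
        stim = em.samples(genotype=genotype, time_hr=t)
        if not stim:
            raise ValueError(f"no samples for genotype {genotype!r} at {t} hr")
        de = sam_test(
            em.values,
            stim,
            baseline,
            n_permutations=n_permutations,
            seed=seed + i,
            fdr_threshold=fdr_threshold,
            fold_threshold=fold_threshold,
        )
        up |= set(de.index[de["call"] == "up"])
        down |= set(de.index[de["call"] == "down"])
    return up, down - up


def integrate_categories(
    de_by_genotype: Mapping[str, pd.DataFrame],
    categories: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[tuple[int, str, str], list[str]]]:
    """Count knockout-affected genes per promoter category.

    `de_by_genotype` maps a genotype label to a sam_test result for the
    KO-vs-WT contrast (so "down" means the regulator induces the gene and
    "up" means it represses it). Returns the category x (genotype,
    direction) count table plus the underlying gene lists.
    """
    cat_of = dict(zip(categories["gene_id"], categories["category"]))
    cats = sorted(categories["category"].unique())
    rows = {c: {} for c in cats}
    gene_lists: dict[tuple[int, str, str], list[str]] = {}
    for genotype, de in de_by_genotype.items():
        for direction in ("down", "up"):
            hits = [g for g in de.index[de["call"] == direction] if g in cat_of]
            for c in cats:
                genes_c = sorted(g for g in hits if cat_of[g] == c)
                rows[c][(genotype, direction)] = len(genes_c)
                gene_lists[(c, genotype, direction)] = genes_c
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    table.index.name = "category"
    if len(table.columns):
        table.columns = pd.MultiIndex.from_tuples(table.columns, names=["genotype", "direction"])
    return table, gene_lists


def geneset_enrichment(selected: set, geneset: set, universe: set) -> float:
    """One-sided hypergeometric tail P(overlap >= observed).

    `selected` and `geneset` must be subsets of `universe`.
    """
    if not universe:
        raise ValueError("empty universe")
    if not geneset <= universe or not selected <= universe:
        raise ValueError("selected and geneset must be subsets of the universe")
    M, n, N = len(universe), len(geneset), len(selected)
    k = len(selected & geneset)
    return float(hypergeom.sf(k - 1, M, n, N))


def geneset_enrichment_table(
    selected: set, genesets: Mapping[str, set], universe: set
) -> pd.DataFrame:
    """Hypergeometric enrichment for several gene sets with BH q-values."""
    rows = [
        {
            "geneset": name,
            "overlap": len(selected & gs),
            "geneset_size": len(gs),
            "p_value": geneset_enrichment(selected, gs, universe),
        }
        for name, gs in genesets.items()
    ]
    df = pd.DataFrame(rows)
    df["q_value"] = false_discovery_control(df["p_value"], method="bh")
    return df.set_index("geneset")
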