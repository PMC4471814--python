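"""Calibration, recovery and power experiments on synthetic data.

These are the package's validation experiments: each one generates its
inputs with the synthetic-data module, runs the corresponding analysis
stage, and returns the measured quantities. They are used by the test
suite and by the reproduction script; sizes are chosen to finish on a
single CPU in minutes (the methods note records them).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import annotation, association, expression, pbm, simulate
from .cistrome import stratify
from .pipeline import RunConfig, run_pipeline
from .simulate import SyntheticConfig


def _uniform_peak_config(seed: int, n_peaks: int, genome_bp: int, n_chroms: int = 2):
    return SyntheticConfig(
        seed=seed,
        n_chroms=n_chroms,
        chrom_length=genome_bp // n_chroms,
        n_genes=0,
        n_peaks_a=n_peaks,
        n_peaks_b=n_peaks,
        co_occurrence_fraction=0.0,
        tss_bias_fraction=0.0,
    )


def null_association_calibration(
    seed: int = 0,
    n_peaks: int = 2000,
    genome_bp: int = 10_000_000,
    n_samples_fold: int = 10_000,
    n_runs: int = 200,
    n_samples_per_run: int = 300,
) -> dict:
    """Fold and p-value calibration of the association test under the null.

    One full-size run (uniformly placed query and reference, 10^4
    randomizations) measures the null fold; `n_runs` independent smaller
    runs collect empirical p-values, which are compared with U(0,1) by a
    Kolmogorov-Smirnov test.
    """
    cfg = _uniform_peak_config(seed, n_peaks, genome_bp)
    _, genes, ws = simulate.generate_genome_and_genes(cfg, with_sequence=False)
    a, b, _ = simulate.generate_peaks(cfg, genes, ws)
    res = association.randomized_overlap_test(
        a, b, ws, n_samples=n_samples_fold, seed=seed + 1
    )
    pvals = []
    for i in range(n_runs):
        cfg_i = _uniform_peak_config(seed + 1000 + i, n_peaks, genome_bp)
        _, genes_i, ws_i = simulate.generate_genome_and_genes(cfg_i, with_sequence=False)
        a_i, b_i, _ = simulate.generate_peaks(cfg_i, genes_i, ws_i)
        r = association.randomized_overlap_test(
            a_i, b_i, ws_i, n_samples=n_samples_per_run, seed=seed + 2000 + i
        )
        pvals.append(r.empirical_p)
    ks_stat, ks_p = stats.kstest(pvals, "uniform")
    return {
        "null_fold": res.fold,
        "full_run_p": res.empirical_p,
        "ks_statistic": float(ks_stat),
        "ks_p": float(ks_p),
        "n_runs": n_runs,
        "n_peaks": n_peaks,
    }


def enumeration_oracle_check(seed: int = 0, n_samples: int = 10_000) -> dict:
    """Sampling expectation vs exhaustive enumeration on tiny workspaces.

    Includes the worked half-covered-workspace case (expectation exactly
    455/91 = 5) and randomized <=200-bp toys; reports the largest
    |mean - exact| / SE across all cases.
    """
    from .intervals import GenomicInterval, Peak, Workspace

    rng = np.random.default_rng(seed)
    cases = [(Workspace([GenomicInterval("chr1", 0, 100)]),
              [Peak(GenomicInterval("chr1", 0, 50))], 10)]
    for _ in range(5):
        L = int(rng.integers(60, 201))
        ws = Workspace([GenomicInterval("chr1", 0, L)])
        ref = [
            Peak(GenomicInterval("chr1", int(s), min(int(s) + int(rng.integers(5, 40)), L)))
            for s in rng.integers(0, L - 5, size=2)
        ]
        cases.append((ws, ref, int(rng.integers(2, 25))))
    worst_z = 0.0
    worked_exact = worked_mean = None
    for idx, (ws, ref, qlen) in enumerate(cases):
        exact = association.exact_expected_overlap([qlen], ref, ws)
        query = [Peak(GenomicInterval(ws.chroms[0], 0, qlen))]
        res = association.randomized_overlap_test(
            query, ref, ws, n_samples=n_samples, seed=seed + idx
        )
        se = res.expected_sd / np.sqrt(res.n_samples)
        z = abs(res.expected_mean - exact) / se if se > 0 else 0.0
        worst_z = max(worst_z, z)
        if idx == 0:
            worked_exact, worked_mean = exact, res.expected_mean
    return {
        "worked_case_exact": worked_exact,
        "worked_case_mean": worked_mean,
        "worst_z": worst_z,
        "n_cases": len(cases),
    }


def cooccurrence_recovery(
    seed: int = 0,
    n_peaks: int = 2000,
    genome_bp: int = 100_000_000,
    planted: float = 0.30,
) -> dict:
    """Recover a planted co-occurrence fraction from the stratification.

    Uses a gene-free workspace large enough that chance co-binding of the
    independently placed peaks is negligible relative to the +/-0.03
    binomial band around the planted value.
    """
    cfg = SyntheticConfig(
        seed=seed, n_chroms=4, chrom_length=genome_bp // 4, n_genes=0,
        n_peaks_a=n_peaks, n_peaks_b=n_peaks,
        co_occurrence_fraction=planted, tss_bias_fraction=0.0,
    )
    _, genes, ws = simulate.generate_genome_and_genes(cfg, with_sequence=False)
    a, b, _ = simulate.generate_peaks(cfg, genes, ws)
    part = stratify(a, b)
    return {
        "planted": planted,
        "recovered": len(part.both_a) / len(a),
        "n_peaks": n_peaks,
    }


def u1_fold_ordering(
    seed: int = 0,
    n_runs: int = 50,
    n_peaks: int = 600,
    n_genes: int = 100,
    genome_bp: int = 10_000_000,
    n_samples: int = 100,
) -> dict:
    """How often the co-bound class out-enriches the exclusive class at U1.

    Factor B carries the planted TSS bias; co-occurring A peaks inherit
    it through their B partners while exclusive A peaks are uniform, so
    the co-bound U1 fold should exceed the exclusive U1 fold in nearly
    every seeded run.
    """
    wins = 0
    for i in range(n_runs):
        cfg = SyntheticConfig(
            seed=seed + i, n_chroms=2, chrom_length=genome_bp // 2,
            n_genes=n_genes, n_peaks_a=n_peaks, n_peaks_b=n_peaks,
            co_occurrence_fraction=0.30, tss_bias_fraction=0.40,
        )
        _, genes, ws = simulate.generate_genome_and_genes(cfg, with_sequence=False)
        a, b, _ = simulate.generate_peaks(cfg, genes, ws)
        part = stratify(a, b)
        f_co = annotation.bin_enrichment(part.both_a, genes, ws, n_samples=n_samples, seed=seed + i)
        f_ex = annotation.bin_enrichment(part.a_only, genes, ws, n_samples=n_samples, seed=seed + i + 1)
        wins += f_co.loc["U1", "fold"] > f_ex.loc["U1", "fold"]
    return {"ordering_rate": wins / n_runs, "n_runs": n_runs}


def pbm_roc_experiment(seed: int = 0, n_per_class: int = 200, n_shuffles: int = 100) -> dict:
    """Planted-motif discrimination and label-shuffle calibration.

    Bound regions carry one planted consensus instance each; unbound
    regions are peak-free placements of matched length. Reports the
    bound-vs-unbound AUC, the agreement between the rank-formula AUC and
    a brute-force pair count, and the mean AUC over label shuffles.
    """
    cfg = SyntheticConfig(
        seed=seed, n_chroms=2, chrom_length=2_000_000, n_genes=100,
        n_peaks_a=n_per_class * 3, n_peaks_b=n_per_class * 3,
    )
    genome, genes, ws = simulate.generate_genome_and_genes(cfg)
    a, b, _ = simulate.generate_peaks(cfg, genes, ws)
    part = stratify(a, b)
    bound = part.both_a[:n_per_class]
    genome2, table, _ = simulate.plant_motifs(cfg, genome, bound)
    unbound = pbm.sample_unbound(
        a + b, ws, n=n_per_class, seed=seed + 1, max_attempts=10_000_000
    )
    pos = [pbm.score_region(s, table) for s in pbm.extract_sequences(genome2, bound)]
    neg = [pbm.score_region(s, table) for s in pbm.extract_sequences(genome2, unbound)]
    res = pbm.roc_auc(pos, neg)
    brute = sum(
        (p > n) + 0.5 * (p == n) for p in pos for n in neg
    ) / (len(pos) * len(neg))
    rng = np.random.default_rng(seed + 2)
    scores = np.array(pos + neg)
    shuffled = []
    for _ in range(n_shuffles):
        perm = rng.permutation(scores)
        shuffled.append(pbm.roc_auc(perm[: len(pos)], perm[len(pos) :]).auc)
    return {
        "auc": res.auc,
        "auc_pair_count": float(brute),
        "mw_p": res.p_value,
        "shuffle_mean_auc": float(np.mean(shuffled)),
        "n_per_class": n_per_class,
    }


def de_calibration_and_power(
    seed: int = 0,
    n_genes: int = 2000,
    n_planted: int = 200,
    fold: float = 2.5,
    n_per_group: int = 4,
    n_null_seeds: int = 20,
) -> dict:
    """Null false-call rate and planted-effect sensitivity of the DE test.

    Null matrices carry no effects; the power matrix plants `n_planted`
    genes at the given fold with noise chosen so the per-gene t statistic
    is about 4 (sigma = log2(fold) / (4 * sqrt(2/n))).
    """
    lfc = float(np.log2(fold))
    sd = lfc / (4 * np.sqrt(2 / n_per_group))
    null_fractions = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_null_seeds):
            df, g1, g2, _ = simulate.simulate_two_group_matrix(
                n_genes, 0, 0.0, sd, n_per_group, seed=seed + 100 + i
            )
            de = expression.sam_test(df, g1, g2, n_permutations=200, seed=seed + i,
                                     fdr_threshold=0.10)
            null_fractions.append(float((de["call"] != "ns").mean()))
        df, g1, g2, planted = simulate.simulate_two_group_matrix(
            n_genes, n_planted, lfc, sd, n_per_group, seed=seed
        )
        de = expression.sam_test(df, g1, g2, n_permutations=200, seed=seed,
                                 fdr_threshold=0.10)
    called = set(de.index[de["call"] != "ns"])
    sensitivity = len(called & planted) / len(planted)
    return {
        "null_call_fraction_mean": float(np.mean(null_fractions)),
        "sensitivity": sensitivity,
        "noise_sd": sd,
        "n_genes": n_genes,
        "n_planted": n_planted,
    }


def exact_value_checks() -> dict:
    """The hand-computable deterministic examples, recomputed."""
    from .intervals import GenomicInterval, overlap_length
    from .pbm import KmerTable, pfm_from_top_kmers

    d = expression.sam_statistic([1, 2], [3, 4], s0=0.0)
    p_hyper = expression.geneset_enrichment(
        set("abcd"), set("abcde"), set("abcdefghij")
    )
    auc = pbm.roc_auc([3, 5], [1, 4]).auc
    ov_half = overlap_length(GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150))
    ov_adjacent = overlap_length(GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 100, 200))
    ov_cross = overlap_length(GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 10))
    pfm = pfm_from_top_kmers(KmerTable({"ACGT": 2.0, "AGGT": 1.0, "TTTT": 0.0}), top_n=2)
    return {
        "sam_d": d,
        "hypergeom_p": p_hyper,
        "auc": auc,
        "overlap_half": ov_half,
        "overlap_adjacent": ov_adjacent,
        "overlap_cross_chrom": ov_cross,
        "pfm_max_column_sum_error": float(np.abs(pfm.matrix.sum(axis=0) - 1).max()),
    }


def pipeline_smoke(out_root, seed: int = 0) -> dict:
    """Default-configuration end-to-end run, rerun determinism, consistency.

    Runs the default pipeline twice in independent directories with the
    same seed and compares the reports byte for byte (ignoring the output
    path recorded in the config block), then checks the cross-module
    consistency of the report against the written files.
    """
    out_root = Path(out_root)
    reports = []
    for tag in ("run1", "run2"):
        cfg = RunConfig(out_dir=str(out_root / tag))
        cfg.synthetic = SyntheticConfig(seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run_pipeline(cfg)
        text = (out_root / tag / "report.json").read_text()
        obj = json.loads(text)
        obj["config"].pop("out_dir")
        reports.append(json.dumps(obj, sort_keys=True))
    identical = reports[0] == reports[1]
    report = json.loads(reports[0])
    cats = pd.read_csv(out_root / "run1" / "categories.tsv", sep="\t")
    cat1_recount = int((cats["category"] == 1).sum())
    consistent = (
        report["categorize"].get("category_1", 0) == cat1_recount
        and report["stratify"]["both_a"] + report["stratify"]["a_only"]
        == report["simulate"]["n_peaks_a"]
        and report["matrix"]["rows"] == report["simulate"]["n_peaks_b"]
    )
    return {
        "completed": True,
        "rerun_identical": identical,
        "consistency_ok": bool(consistent),
        "category_1_genes": cat1_recount,
        "auc": report["roc"]["auc"],
        "association_fold_bases": report["associate"]["tests"][0]["fold"],
    }
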