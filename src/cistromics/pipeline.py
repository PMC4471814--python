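"""End-to-end orchestration of the synthetic two-factor analysis.

Stages: simulate -> associate -> stratify -> matrix -> annotate ->
categorize -> de -> integrate -> roc. Each stage reads files written by
earlier stages, writes its outputs plus a small JSON summary, and is
skipped when its outputs are newer than its inputs; the consolidated
report.json is rebuilt from the stage summaries on every run, so a rerun
with an identical configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import annotation, association, cistrome, expression, io, pbm, simulate
from .intervals import Workspace
from .simulate import SyntheticConfig


@dataclass
class RunConfig:
    """All pipeline parameters in one auditable place.

    Defaults mirror the study's printed analysis parameters: +/-2 kb
    density windows, 10 kb / 0.5 kb promoter, >2-fold with 1% FDR for
    stimulation-response calls, 10% FDR for knockout effects; the
    randomization sample count is configurable (the full study used
    10^4; the default here is sized for a desk-scale run).
    """

    out_dir: str = "pipeline_out"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    assoc_n_samples: int = 1000
    assoc_seed: int = 17
    bin_n_samples: int = 200
    density_halfwidth: int = 2000
    density_binsize: int = 10
    promoter_upstream: int = 10_000
    promoter_downstream: int = 500
    de_n_permutations: int = 1000
    de_seed: int = 7
    de_fdr: float = 0.10
    de_time: float = 4.0
    lps_fdr: float = 0.01
    lps_fold: float = 2.0
    roc_n_unbound: int = 200
    roc_seed: int = 23

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = SyntheticConfig(**raw.pop("synthetic", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(synthetic=syn, **raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_synthetic_inputs(
    syn: SyntheticConfig,
    out_dir,
    promoter_upstream: int = 10_000,
    promoter_downstream: int = 500,
) -> dict:
    """Generate and write every synthetic input file into `out_dir`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, genes, workspace = simulate.generate_genome_and_genes(syn)
    a_peaks, b_peaks, truth_peaks = simulate.generate_peaks(syn, genes, workspace)
    polii = simulate.generate_polii_peaks(syn, genes)
    part = cistrome.stratify(a_peaks, b_peaks)
    genome, table, truth_motifs = simulate.plant_motifs(syn, genome, part.both_a)
    coverage = simulate.generate_coverage(syn, a_peaks)
    categories = annotation.categorize_promoters(
        genes, a_peaks, b_peaks, promoter_upstream, promoter_downstream
    )
    expr, meta, truth_expr = simulate.generate_expression(syn, genes, categories)
    io.write_fasta(genome, out / "genome.fa")
    io.write_genes(genes, out / "genes.tsv")
    io.write_intervals_bed(workspace.segments, out / "workspace.bed")
    io.write_bed(a_peaks, out / "irf5.bed")
    io.write_bed(b_peaks, out / "rela.bed")
    io.write_bed(polii, out / "polII.bed")
    io.write_bedgraph(coverage, out / "cov_irf5.bedGraph")
    table.to_frame().to_csv(out / "kmers.tsv", sep="\t", index=False)
    expr.to_csv(out / "expr.tsv", sep="\t")
    meta.to_csv(out / "meta.tsv", sep="\t", index=False)
    truth_peaks.to_csv(out / "truth_peaks.tsv", sep="\t", index=False)
    truth_expr.to_csv(out / "truth_expr.tsv", sep="\t", index=False)
    truth_motifs.to_csv(out / "truth_motifs.tsv", sep="\t", index=False)
    return {
        "seed": syn.seed,
        "genome_bp": syn.n_chroms * syn.chrom_length,
        "n_genes": len(genes),
        "n_peaks_a": len(a_peaks),
        "n_peaks_b": len(b_peaks),
        "n_polii": len(polii),
    }


class _Stage:
    def __init__(self, name: str, inputs: list[Path], outputs: list[Path], func: Callable[[], dict]):
        self.name = name
        self.inputs = inputs
        self.outputs = outputs
        self.func = func

    def current(self) -> bool:
        if not all(p.exists() for p in self.outputs):
            return False
        if not self.inputs:
            return True
        newest_in = max(p.stat().st_mtime_ns for p in self.inputs)
        oldest_out = min(p.stat().st_mtime_ns for p in self.outputs)
        return oldest_out >= newest_in


def run_pipeline(cfg: RunConfig) -> tuple[dict, list[str]]:
    """Run (or resume) the full analysis; returns (report, executed stages).

    Any stage failure raises with the stage name attached. Outputs that
    are current (present and newer than their inputs) are not recomputed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn = cfg.synthetic

    p = {
        name: out / name
        for name in (
            "genome.fa", "genes.tsv", "workspace.bed", "irf5.bed", "rela.bed",
            "polII.bed", "cov_irf5.bedGraph", "kmers.tsv", "expr.tsv", "meta.tsv",
            "truth_peaks.tsv", "truth_expr.tsv", "truth_motifs.tsv",
            "assoc.tsv", "part_both_a.bed", "part_a_only.bed", "part_both_b.bed",
            "part_b_only.bed", "matrix_b.tsv", "bins.tsv", "bin_folds_cobound.tsv",
            "bin_folds_exclusive.tsv", "categories.tsv", "de_ko_a.tsv",
            "de_ko_b.tsv", "lps_up.txt", "lps_down.txt", "category_counts.tsv",
            "roc.tsv",
        )
    }

    def summary_path(stage: str) -> Path:
        return out / f"{stage}.summary.json"

    def load_workspace() -> Workspace:
        return Workspace(io.read_intervals_bed(p["workspace.bed"]))

    # --- stage implementations ------------------------------------------
    def st_simulate() -> dict:
        return write_synthetic_inputs(
            syn, out, cfg.promoter_upstream, cfg.promoter_downstream
        )

    def st_associate() -> dict:
        a = io.read_bed(p["irf5.bed"])
        b = io.read_bed(p["rela.bed"])
        ws = load_workspace()
        rows = []
        for mode in ("bases", "peaks"):
            res = association.randomized_overlap_test(
                a, b, ws, n_samples=cfg.assoc_n_samples, seed=cfg.assoc_seed, mode=mode
            )
            rows.append({"query": "irf5", "reference": "rela", **res.as_dict()})
        pd.DataFrame(rows).to_csv(p["assoc.tsv"], sep="\t", index=False)
        return {"seed": cfg.assoc_seed, "n_samples": cfg.assoc_n_samples, "tests": rows}

    def st_stratify() -> dict:
        a = io.read_bed(p["irf5.bed"])
        b = io.read_bed(p["rela.bed"])
        part = cistrome.stratify(a, b)
        io.write_bed(part.both_a, p["part_both_a.bed"])
        io.write_bed(part.a_only, p["part_a_only.bed"])
        io.write_bed(part.both_b, p["part_both_b.bed"])
        io.write_bed(part.b_only, p["part_b_only.bed"])
        merged = association.MergedIntervalIndex(part.both_a + part.both_b)
        n_merged = sum(len(v[0]) for v in merged._chroms.values())
        return {**part.counts, "cobound_merged_regions": n_merged}

    def st_matrix() -> dict:
        b = io.read_bed(p["rela.bed"])
        lengths = {c: n for c, n in syn.chrom_lengths.items()}
        cov = io.read_bedgraph(p["cov_irf5.bedGraph"], lengths)
        dm = cistrome.density_matrix(b, cov, cfg.density_halfwidth, cfg.density_binsize)
        dm.to_frame().to_csv(p["matrix_b.tsv"], sep="\t")
        return {
            "rows": int(dm.values.shape[0]),
            "cols": int(dm.values.shape[1]),
            "total_mass": float(dm.values.sum() * dm.binsize),
        }

    def st_annotate() -> dict:
        genes = io.read_genes(p["genes.tsv"])
        ws = load_workspace()
        a_both = io.read_bed(p["part_both_a.bed"])
        a_only = io.read_bed(p["part_a_only.bed"])
        bins = annotation.assign_gene_bins(io.read_bed(p["irf5.bed"]), genes)
        bins.to_csv(p["bins.tsv"], sep="\t", index=False)
        summaries = {}
        for label, peaks, path in (
            ("cobound", a_both, p["bin_folds_cobound.tsv"]),
            ("exclusive", a_only, p["bin_folds_exclusive.tsv"]),
        ):
            if peaks:
                folds = annotation.bin_enrichment(
                    peaks, genes, ws, n_samples=cfg.bin_n_samples, seed=cfg.assoc_seed
                )
                folds.to_csv(path, sep="\t")
                summaries[label] = {"u1_fold": float(folds.loc["U1", "fold"])}
            else:
                pd.DataFrame().to_csv(path, sep="\t")
                summaries[label] = {"u1_fold": None}
        tes_frac = annotation.tes_downstream_fraction(
            io.read_bed(p["irf5.bed"]), genes
        )
        return {"bins_assigned": len(bins), "tes_downstream_fraction": tes_frac, **summaries}

    def st_categorize() -> dict:
        genes = io.read_genes(p["genes.tsv"])
        cats = annotation.categorize_promoters(
            genes,
            io.read_bed(p["irf5.bed"]),
            io.read_bed(p["rela.bed"]),
            cfg.promoter_upstream,
            cfg.promoter_downstream,
        )
        cats.to_csv(p["categories.tsv"], sep="\t", index=False)
        counts = cats["category"].value_counts().to_dict()
        return {f"category_{k}": int(v) for k, v in sorted(counts.items())}

    def st_de() -> dict:
        expr, meta = io.read_expression(p["expr.tsv"], p["meta.tsv"])
        em = expression.ExpressionMatrix(expr, meta)
        summaries = {}
        for label, genotype, path in (
            ("ko_a", "KO_A", p["de_ko_a.tsv"]),
            ("ko_b", "KO_B", p["de_ko_b.tsv"]),
        ):
            de = expression.sam_test(
                em.values,
                em.samples(genotype=genotype, time_hr=cfg.de_time),
                em.samples(genotype="WT", time_hr=cfg.de_time),
                n_permutations=cfg.de_n_permutations,
                seed=cfg.de_seed,
                fdr_threshold=cfg.de_fdr,
            )
            de.to_csv(path, sep="\t")
            summaries[label] = {
                "down": int((de["call"] == "down").sum()),
                "up": int((de["call"] == "up").sum()),
            }
        up, down = expression.lps_response_genes(
            em, fold_threshold=cfg.lps_fold, fdr_threshold=cfg.lps_fdr,
            times=[cfg.de_time], seed=cfg.de_seed,
        )
        p["lps_up.txt"].write_text("".join(f"{g}\n" for g in sorted(up)))
        p["lps_down.txt"].write_text("".join(f"{g}\n" for g in sorted(down)))
        summaries["lps"] = {"up": len(up), "down": len(down)}
        return {"fdr": cfg.de_fdr, "time_hr": cfg.de_time, **summaries}

    def st_integrate() -> dict:
        cats = pd.read_csv(p["categories.tsv"], sep="\t")
        de_by_genotype = {
            "KO_A": pd.read_csv(p["de_ko_a.tsv"], sep="\t", index_col=0),
            "KO_B": pd.read_csv(p["de_ko_b.tsv"], sep="\t", index_col=0),
        }
        table, _ = expression.integrate_categories(de_by_genotype, cats)
        flat = table.copy()
        flat.columns = [f"{g}_{d}" for g, d in table.columns]
        flat.to_csv(p["category_counts.tsv"], sep="\t")
        return {
            "counts": {
                f"cat{c}_{col}": int(flat.loc[c, col])
                for c in flat.index
                for col in flat.columns
            }
        }

    def st_roc() -> dict:
        import pyfaidx

        genome = {
            name: str(rec[:]) for name, rec in pyfaidx.Fasta(str(p["genome.fa"])).items()
        }
        table = pbm.KmerTable.from_frame(io.read_kmer_table(p["kmers.tsv"]))
        bound = io.read_bed(p["part_both_a.bed"])
        ws = load_workspace()
        all_peaks = io.read_bed(p["irf5.bed"]) + io.read_bed(p["rela.bed"])
        unbound = pbm.sample_unbound(
            all_peaks, ws, n=min(cfg.roc_n_unbound, max(len(bound), 1)),
            seed=cfg.roc_seed,
            max_attempts=100_000,
            lengths=[b.length() for b in bound] or None,
        )
        pos = [pbm.score_region(s, table) for s in pbm.extract_sequences(genome, bound)]
        neg = [pbm.score_region(s, table) for s in pbm.extract_sequences(genome, unbound)]
        res = pbm.roc_auc(pos, neg)
        pd.DataFrame(
            [
                {
                    "comparison": "cobound_vs_unbound",
                    "auc": res.auc,
                    "u_statistic": res.u_statistic,
                    "p_value": res.p_value,
                    "n_pos": res.n_pos,
                    "n_neg": res.n_neg,
                }
            ]
        ).to_csv(p["roc.tsv"], sep="\t", index=False)
        return {"auc": res.auc, "p_value": res.p_value, "n_pos": res.n_pos, "n_neg": res.n_neg}

    stages = [
        _Stage("simulate", [], [p[k] for k in (
            "genome.fa", "genes.tsv", "workspace.bed", "irf5.bed", "rela.bed",
            "polII.bed", "cov_irf5.bedGraph", "kmers.tsv", "expr.tsv", "meta.tsv",
            "truth_peaks.tsv", "truth_expr.tsv", "truth_motifs.tsv")], st_simulate),
        _Stage("associate", [p["irf5.bed"], p["rela.bed"], p["workspace.bed"]],
               [p["assoc.tsv"]], st_associate),
        _Stage("stratify", [p["irf5.bed"], p["rela.bed"]],
               [p[k] for k in ("part_both_a.bed", "part_a_only.bed", "part_both_b.bed", "part_b_only.bed")],
               st_stratify),
        _Stage("matrix", [p["rela.bed"], p["cov_irf5.bedGraph"]], [p["matrix_b.tsv"]], st_matrix),
        _Stage("annotate", [p["irf5.bed"], p["genes.tsv"], p["workspace.bed"],
                            p["part_both_a.bed"], p["part_a_only.bed"]],
               [p["bins.tsv"], p["bin_folds_cobound.tsv"], p["bin_folds_exclusive.tsv"]],
               st_annotate),
        _Stage("categorize", [p["genes.tsv"], p["irf5.bed"], p["rela.bed"]],
               [p["categories.tsv"]], st_categorize),
        _Stage("de", [p["expr.tsv"], p["meta.tsv"]],
               [p["de_ko_a.tsv"], p["de_ko_b.tsv"], p["lps_up.txt"], p["lps_down.txt"]], st_de),
        _Stage("integrate", [p["categories.tsv"], p["de_ko_a.tsv"], p["de_ko_b.tsv"]],
               [p["category_counts.tsv"]], st_integrate),
        _Stage("roc", [p["genome.fa"], p["kmers.tsv"], p["part_both_a.bed"],
                       p["irf5.bed"], p["rela.bed"], p["workspace.bed"]],
               [p["roc.tsv"]], st_roc),
    ]

    executed: list[str] = []
    for stage in stages:
        spath = summary_path(stage.name)
        if stage.current() and spath.exists():
            continue
        try:
            summary = stage.func()
        except Exception as exc:
            raise RuntimeError(f"stage {stage.name!r} failed: {exc}") from exc
        spath.write_text(json.dumps(_jsonable(summary), sort_keys=True, indent=2) + "\n")
        executed.append(stage.name)

    report = {"config": _config_block(cfg)}
    for stage in stages:
        report[stage.name] = json.loads(summary_path(stage.name).read_text())
    (out / "report.json").write_text(
        json.dumps(_jsonable(report), sort_keys=True, indent=2) + "\n"
    )
    return report, executed


def _config_block(cfg: RunConfig) -> dict:
    block = dataclasses.asdict(cfg)
    return _jsonable(block)
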