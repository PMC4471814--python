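"""Synthetic-data generators: determinism and planted structure."""

import numpy as np
import pytest

from cistromics.cistrome import stratify
from cistromics.pbm import score_region
from cistromics.simulate import (
    SyntheticConfig,
    generate_coverage,
    generate_expression,
    generate_genome_and_genes,
    generate_peaks,
    plant_motifs,
    realize_consensus,
)

SMALL = dict(n_chroms=2, chrom_length=1_000_000, n_genes=40, n_peaks_a=300, n_peaks_b=300)


@pytest.fixture(scope="module")
def small_world():
    cfg = SyntheticConfig(seed=21, **SMALL)
    genome, genes, ws = generate_genome_and_genes(cfg)
    return cfg, genome, genes, ws


class TestGenomeAndGenes:
    def test_same_seed_is_bit_identical(self):
        cfg = SyntheticConfig(seed=5, **SMALL)
        g1, genes1, _ = generate_genome_and_genes(cfg)
        g2, genes2, _ = generate_genome_and_genes(cfg)
        assert g1 == g2
        assert [(g.gene_id, g.start, g.end, g.strand) for g in genes1] == [
            (g.gene_id, g.start, g.end, g.strand) for g in genes2
        ]

    def test_gc_content_near_half(self, small_world):
        _, genome, _, _ = small_world
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.01

    def test_zero_genes_allowed(self):
        cfg = SyntheticConfig(seed=1, n_genes=0, **{k: v for k, v in SMALL.items() if k != "n_genes"})
        genome, genes, ws = generate_genome_and_genes(cfg)
        assert genes == [] and len(genome) == cfg.n_chroms

    def test_genes_spaced_and_inside_genome(self, small_world):
        cfg, _, genes, _ = small_world
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs = sorted(gs, key=lambda g: g.start)
            assert all(g.end <= cfg.chrom_length for g in gs)
            gaps = [b.start - a.end for a, b in zip(gs, gs[1:])]
            assert all(gap >= 10_000 for gap in gaps)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            SyntheticConfig(seed=0, n_chroms=1, chrom_length=100_000, n_genes=50)


class TestPeaks:
    def test_full_cooccurrence_empties_a_only(self, small_world):
        cfg0, _, genes, ws = small_world
        cfg = SyntheticConfig(seed=3, co_occurrence_fraction=1.0, **SMALL)
        a, b, _ = generate_peaks(cfg, genes, ws)
        part = stratify(a, b)
        assert part.a_only == []

    def test_planted_fraction_recovered(self, small_world):
        # modest chance co-binding inflates the raw fraction slightly;
        # compare against the truth table instead of the nominal value
        cfg, _, genes, ws = small_world
        a, b, truth = generate_peaks(cfg, genes, ws)
        planted = set(truth.loc[truth["placement"] == "cooccur", "peak"])
        part = stratify(a, b)
        cobound = {p.name for p in part.both_a}
        assert planted <= cobound
        assert len(planted) == round(cfg.co_occurrence_fraction * cfg.n_peaks_a)

    def test_determinism(self, small_world):
        cfg, _, genes, ws = small_world
        a1, b1, _ = generate_peaks(cfg, genes, ws)
        a2, b2, _ = generate_peaks(cfg, genes, ws)
        assert [(p.start, p.end, p.height) for p in a1] == [
            (p.start, p.end, p.height) for p in a2
        ]

    def test_tss_biased_peaks_sit_in_u1(self, small_world):
        from cistromics.annotation import assign_gene_bins

        cfg, _, genes, ws = small_world
        _, b, truth = generate_peaks(cfg, genes, ws)
        biased = set(truth.loc[truth["placement"] == "tss", "peak"])
        bins = assign_gene_bins(b, genes).set_index("peak")
        u1_rate = (bins.loc[sorted(biased), "bin"] == "U1").mean()
        assert u1_rate > 0.9


class TestCoverage:
    def test_triangle_mass_matches_closed_form(self):
        cfg = SyntheticConfig(seed=2, coverage_background=0.0, **SMALL)
        from conftest import make_peak

        peak = make_peak("chr1", 10_000, 10_400, height=2.0, name="p")
        track = generate_coverage(cfg, [peak])
        mass = float(track.data["chr1"].sum())
        apex = cfg.coverage_depth_scale * peak.height
        expected = apex * peak.length() / 2  # triangle area
        assert mass == pytest.approx(expected, rel=0.02)

    def test_density_matrix_argmax_at_center(self, small_world):
        from cistromics.cistrome import density_matrix

        # non-overlapping peaks: each triangle peaks at its own center
        cfg0 = SyntheticConfig(
            seed=21, coverage_background=0.0, co_occurrence_fraction=0.0,
            tss_bias_fraction=0.0, **SMALL,
        )
        _, genes, ws = generate_genome_and_genes(
            SyntheticConfig(seed=21, **SMALL), with_sequence=False
        )
        a, _, _ = generate_peaks(cfg0, genes, ws)
        track = generate_coverage(cfg0, a[:20])
        dm = density_matrix(a[:20], track, halfwidth=500, binsize=10)
        center = 500 // 10
        argmaxes = dm.values.argmax(axis=1)
        assert np.all(np.abs(argmaxes - center) <= 1)

    def test_coverage_nonnegative(self, small_world):
        cfg, _, genes, ws = small_world
        a, _, _ = generate_peaks(cfg, genes, ws)
        track = generate_coverage(cfg, a[:50])
        assert all((arr >= 0).all() for arr in track.data.values())


class TestPlantMotifs:
    def test_every_designated_peak_scores_high(self, small_world):
        cfg, genome, genes, ws = small_world
        a, b, _ = generate_peaks(cfg, genes, ws)
        designated = a[:50]
        genome2, table, truth = plant_motifs(cfg, genome, designated)
        for p in designated:
            seq = genome2[p.chrom][p.start : p.end]
            assert score_region(seq, table) >= 5.0  # planted floor ~ N(8,1)
        assert len(truth) == len(designated)

    def test_background_match_rate_is_near_random_expectation(self, small_world):
        cfg, genome, genes, ws = small_world
        a, b, _ = generate_peaks(cfg, genes, ws)
        genome2, table, _ = plant_motifs(cfg, genome, a[:50])
        # probability a random 12-mer matches the planted frame:
        # 9 fixed positions (0.25 each) and 3 free, both strands
        p_word = 2 * 0.25**9
        n, trials = 0, 4000
        rng = np.random.default_rng(1)
        high = {w for w, z in table.entries.items() if z > 5}
        seq = genome2["chr2"]
        for _ in range(trials):
            s = int(rng.integers(0, len(seq) - 12))
            w = seq[s : s + 12]
            from cistromics.pbm import reverse_complement

            n += w in high or reverse_complement(w) in high
        # expectation ~ trials * p_word ~ 0.03; allow Poisson slack
        assert n <= 5

    def test_realize_consensus_respects_iupac(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            word = realize_consensus(rng, "RNGAAANNGAAACT")
            assert word[0] in "AG"
            assert word[2:6] == "GAAA"
            assert word[8:14] == "GAAACT"


class TestExpression:
    def test_same_seed_identical_matrices(self):
        cfg = SyntheticConfig(seed=9, **SMALL)
        ids = [f"g{i}" for i in range(50)]
        e1, m1, t1 = generate_expression(cfg, ids)
        e2, m2, t2 = generate_expression(cfg, ids)
        assert e1.equals(e2) and m1.equals(m2) and t1.equals(t2)

    def test_zero_planted_fold_change_means_null_ko_contrast(self):
        cfg = SyntheticConfig(seed=10, planted_log2_fc=0.0, planted_effect_genes=30, **SMALL)
        ids = [f"g{i}" for i in range(200)]
        expr, meta, truth = generate_expression(cfg, ids)
        wt = [s for s in expr.columns if s.startswith("WT_t4")]
        ko = [s for s in expr.columns if s.startswith("KO_A_t4")]
        diff = expr[ko].mean(axis=1) - expr[wt].mean(axis=1)
        assert abs(diff.mean()) < 0.1

    def test_ko_removes_effect_only_for_dependent_genes(self):
        import pandas as pd

        cfg = SyntheticConfig(seed=11, planted_effect_genes=60, noise_sd=0.05, **SMALL)
        ids = [f"g{i:03d}" for i in range(100)]
        cats = pd.DataFrame({"gene_id": ids, "category": [1] * 50 + [2] * 50})
        expr, meta, truth = generate_expression(cfg, ids, categories=cats)
        resp = truth[truth["responsive"]]
        cat1 = resp[resp["depends_on"] == "both"]["gene_id"]
        cat2 = resp[resp["depends_on"] == "b"]["gene_id"]
        assert len(cat1) > 0 and len(cat2) > 0
        wt4 = [s for s in expr.columns if s.startswith("WT_t4")]
        koa4 = [s for s in expr.columns if s.startswith("KO_A_t4")]
        delta = expr[wt4].mean(axis=1) - expr[koa4].mean(axis=1)
        # category-1 genes lose the effect in KO_A, category-2 genes keep it
        assert delta.loc[cat1].mean() == pytest.approx(cfg.planted_log2_fc, abs=0.1)
        assert abs(delta.loc[cat2].mean()) < 0.1
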