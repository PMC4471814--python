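"""Gene-relative bins, promoter categories, TES-downstream statistics."""

import numpy as np
import pandas as pd
import pytest

from cistromics.annotation import (
    assign_gene_bins,
    bin_enrichment,
    categorize_promoters,
    promoter_window,
    tes_downstream_fraction,
)
from cistromics.intervals import GenomicInterval, Peak, Workspace

from conftest import make_gene, make_peak

GENOME = 100_000


def reflect_peak(p: Peak, size: int = GENOME) -> Peak:
    return make_peak(p.chrom, size - p.end, size - p.start, p.height, p.name)


def reflect_gene(g, size: int = GENOME):
    return make_gene(
        g.gene_id, g.chrom, size - g.end, size - g.start,
        "+" if g.strand == "-" else "-",
    )


class TestAssignGeneBins:
    def test_u1_definition_plus_strand(self):
        gene = make_gene("g1", "chr1", 50_000, 60_000, "+")
        peak = make_peak("chr1", 49_450, 49_550, name="p")  # center 49500, 500 bp upstream
        (row,) = assign_gene_bins([peak], [gene]).to_dict("records")
        assert row["bin"] == "U1" and row["gene_id"] == "g1"
        assert row["distance_tss"] == -500

    def test_u1_definition_minus_strand_mirrors_plus(self):
        # strand-reflection oracle: mirror the genome and re-run the
        # plus-strand rule; the bin label must be invariant
        gene = make_gene("g1", "chr1", 50_000, 60_000, "+")
        peak = make_peak("chr1", 49_450, 49_550, name="p")
        fwd = assign_gene_bins([peak], [gene])
        rev = assign_gene_bins([reflect_peak(peak)], [reflect_gene(gene)])
        assert rev.loc[0, "bin"] == fwd.loc[0, "bin"] == "U1"

    @pytest.mark.parametrize(
        "center, expected",
        [
            (49_999, "U1"), (49_000, "U1"), (48_999, "U2"), (45_000, "U5"),
            (44_999, "DISTAL"), (50_000, "BODY"), (59_999, "BODY"),
            (60_000, "D1"), (60_999, "D1"), (61_000, "D2"), (64_999, "D5"),
            (65_000, "DISTAL"), (43_000, "DISTAL"),
        ],
    )
    def test_bin_boundaries_plus_strand(self, center, expected):
        gene = make_gene("g1", "chr1", 50_000, 60_000, "+")
        peak = make_peak("chr1", center, center + 1, name="p")
        assert assign_gene_bins([peak], [gene]).loc[0, "bin"] == expected

    def test_strand_reflection_invariance_random_fixture(self, rng):
        genes = [
            make_gene(f"g{i}", "chr1", int(s), int(s) + 4000, "+" if i % 2 else "-")
            for i, s in enumerate(np.arange(5, 90, 20) * 1000)
        ]
        peaks = [
            make_peak("chr1", int(s), int(s) + 100, name=f"p{i}")
            for i, s in enumerate(rng.integers(0, GENOME - 100, 100))
        ]
        fwd = assign_gene_bins(peaks, genes)
        rev = assign_gene_bins([reflect_peak(p) for p in peaks], [reflect_gene(g) for g in genes])
        assert list(fwd["bin"]) == list(rev["bin"])
        assert list(fwd["gene_id"]) == list(rev["gene_id"])

    def test_far_peak_is_distal_and_every_peak_assigned(self):
        genes = [make_gene("g1", "chr1", 50_000, 60_000, "+")]
        peaks = [make_peak("chr1", 7_000, 7_100, name="far"),
                 make_peak("chr2", 10, 90, name="nochrom")]
        df = assign_gene_bins(peaks, genes)
        assert len(df) == 2
        assert set(df["bin"]) == {"DISTAL"}

    def test_nearest_gene_tie_broken_lexicographically(self):
        ga = make_gene("ga", "chr1", 10_000, 12_000, "+")
        gb = make_gene("gb", "chr1", 14_001, 16_001, "+")
        # center 13000: equidistant (1001 bp) from ga's last base 11999
        # and gb's first base 14001
        peak = make_peak("chr1", 12_950, 13_050, name="mid")
        df = assign_gene_bins([peak], [gb, ga])
        assert df.loc[0, "gene_id"] == "ga"


class TestBinEnrichment:
    def test_planted_u1_peaks_enriched_everything_else_depleted(self, rng):
        genes = [
            make_gene(f"g{i}", "chr1", int(s), int(s) + 4000, "+")
            for i, s in enumerate(np.arange(5, 95, 15) * 1000)
        ]
        ws = Workspace([GenomicInterval("chr1", 0, GENOME)])
        peaks = [
            make_peak("chr1", g.tss - 600, g.tss - 400, name=f"p{i}{j}")
            for j, g in enumerate(genes) for i in range(10)
        ]
        df = bin_enrichment(peaks, genes, ws, n_samples=200, seed=1)
        assert df.loc["U1", "fold"] > 3
        assert df.loc["U1", "empirical_p"] <= 1 / 100
        others = df.drop(index=["U1"])
        assert (others["fold"] < 1).all()

    def test_null_bin_folds_average_to_one_weighted_by_null_mass(self, rng):
        genes = [
            make_gene(f"g{i}", "chr1", int(s), int(s) + 4000, "+")
            for i, s in enumerate(np.arange(5, 95, 15) * 1000)
        ]
        ws = Workspace([GenomicInterval("chr1", 0, GENOME)])
        peaks = [
            make_peak("chr1", int(s), int(s) + 200, name=f"p{i}")
            for i, s in enumerate(rng.integers(0, GENOME - 200, 400))
        ]
        df = bin_enrichment(peaks, genes, ws, n_samples=300, seed=2)
        weights = df["expected_mean"] / df["expected_mean"].sum()
        assert float((df["fold"] * weights).sum()) == pytest.approx(1.0, abs=0.15)


class TestCategorizePromoters:
    def test_no_peaks_everything_category_zero(self):
        genes = [make_gene("g1", "chr1", 50_000, 60_000, "+")]
        df = categorize_promoters(genes, [], [])
        assert list(df["category"]) == [0]

    def test_single_factor_gives_category_three(self):
        gene = make_gene("g1", "chr1", 10_000, 20_000, "+")
        a = [make_peak("chr1", 9_500, 9_600)]
        df = categorize_promoters([gene], a, [])
        assert list(df["category"]) == [3]

    def test_promoter_window_strand_aware(self):
        plus = make_gene("g1", "chr1", 50_000, 60_000, "+")
        minus = make_gene("g2", "chr1", 50_000, 60_000, "-")
        wp = promoter_window(plus)
        wm = promoter_window(minus)
        assert (wp.start, wp.end) == (40_000, 50_500)
        assert (wm.start, wm.end) == (59_500, 70_000)

    def test_matches_brute_force_double_loop(self, rng):
        genes = [
            make_gene(f"g{i:02d}", "chr1", int(s), int(s) + 3000, "+" if i % 2 else "-")
            for i, s in enumerate(rng.integers(20_000, 400_000, 30))
        ]
        peaks_a = [make_peak("chr1", int(s), int(s) + 300) for s in rng.integers(0, 420_000, 60)]
        peaks_b = [make_peak("chr1", int(s), int(s) + 300) for s in rng.integers(0, 420_000, 60)]
        df = categorize_promoters(genes, peaks_a, peaks_b)
        for g, cat in zip(genes, df["category"]):
            win = promoter_window(g)
            has_a = any(max(win.start, p.start) < min(win.end, p.end) for p in peaks_a)
            has_b = any(max(win.start, p.start) < min(win.end, p.end) for p in peaks_b)
            expected = 1 if has_a and has_b else 2 if has_b else 3 if has_a else 0
            assert cat == expected

    def test_categories_exhaustive_and_exclusive(self, rng):
        genes = [
            make_gene(f"g{i}", "chr1", int(s), int(s) + 3000, "+")
            for i, s in enumerate(rng.integers(20_000, 200_000, 25))
        ]
        a = [make_peak("chr1", int(s), int(s) + 300) for s in rng.integers(0, 210_000, 40)]
        b = [make_peak("chr1", int(s), int(s) + 300) for s in rng.integers(0, 210_000, 40)]
        df = categorize_promoters(genes, a, b)
        assert len(df) == len(genes)
        assert df["category"].isin([0, 1, 2, 3]).all()


class TestTesDownstreamFraction:
    def _genes(self, n):
        return [make_gene(f"g{i:03d}", "chr1", 20_000 * i + 5_000, 20_000 * i + 10_000, "+")
                for i in range(n)]

    def test_all_upstream_peaks_give_zero(self):
        genes = self._genes(5)
        peaks = [make_peak("chr1", g.tss - 600, g.tss - 400) for g in genes]
        assert tes_downstream_fraction(peaks, genes) == 0.0

    def test_every_gene_with_d1_peak_gives_one(self):
        genes = self._genes(5)
        peaks = [make_peak("chr1", g.tes + 100, g.tes + 300) for g in genes]
        assert tes_downstream_fraction(peaks, genes) == 1.0

    def test_planted_thirty_three_of_one_hundred(self):
        genes = self._genes(100)
        peaks = [make_peak("chr1", g.tss - 600, g.tss - 400, name=f"u{g.gene_id}") for g in genes]
        peaks += [
            make_peak("chr1", g.tes + 100, g.tes + 300, name=f"d{g.gene_id}")
            for g in genes[:33]
        ]
        assert tes_downstream_fraction(peaks, genes) == pytest.approx(0.33)

    def test_zero_eligible_genes_is_error(self):
        genes = self._genes(3)
        distal = [make_peak("chr1", 200_000, 200_050)]
        with pytest.raises(ValueError):
            tes_downstream_fraction(distal, genes)
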