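# cistromics

Tools for asking whether two transcription factors bind the genome
together, and what that co-binding does to gene regulation.

A ChIP-seq experiment yields, per factor, a set of *peaks* — genomic
intervals enriched for immunoprecipitated reads, each with a height.
Given two such cistromes (for example an IRF-family factor and an
NF-κB subunit in stimulated macrophages), this package provides:

- **Association testing** — is the overlap between the two peak sets
  larger than expected from genomic background? The null distribution is
  built by re-placing every query interval uniformly at random inside a
  *workspace* (the mappable genome), preserving interval lengths, and the
  result is a fold enrichment `observed / E[overlap]` with an add-one
  empirical p-value `(1 + #{sim ≥ obs}) / (1 + N)`.
- **Cistrome stratification** — splitting each set into co-bound and
  exclusive classes (≥ 1 bp overlap), plus peak-centered, height-sorted
  coverage matrices (the data behind the usual co-localization heatmaps).
- **TSS-relative annotation** — assigning peak centers to strand-aware
  bins around the nearest gene (five 1-kb upstream windows U5..U1, the
  gene body, five 1-kb downstream windows D1..D5, or DISTAL), per-bin
  fold enrichment against the same placement null, promoter
  categorization (bound by both factors / one / neither over the
  10 kb upstream + 0.5 kb window at the TSS), and fractions of genes
  with peaks downstream of the transcription end site.
- **Differential expression** — a SAM-style permutation test with the
  moderated statistic `d = (x̄₁ − x̄₂) / (s + s₀)`, where `s` is the
  pooled standard error and `s₀` a small fudge constant; q-values come
  from the median number of permuted statistics exceeding each observed
  |d| divided by the observed count. Knockout effects are intersected
  with the promoter categories, and gene-set enrichment uses the
  one-sided hypergeometric tail with Benjamini–Hochberg correction.
- **PBM k-mer ROC scoring** — regions scored by their best k-mer
  Z-score over both strands from a protein-binding-microarray table;
  bound vs unbound discrimination summarized as the Mann–Whitney AUC
  `(#{pos > neg} + ½·#{pos = neg}) / (n₊ n₋)`; position-frequency
  motifs built from the top-ranked words.
- **A synthetic-data generator** that plants every one of these signals
  (co-occurrence fraction, TSS bias, coverage pileups, motif instances
  with a matching k-mer table, knockout-removable expression effects)
  with truth tables, so the whole pipeline is testable end to end
  without any external data.

All coordinates are 0-based half-open; BED/bedGraph are native, GFF is
converted on read.

## Worked example

```python
from cistromics import SyntheticConfig, randomized_overlap_test, stratify
from cistromics.simulate import generate_genome_and_genes, generate_peaks

cfg = SyntheticConfig(seed=1)          # 10-Mb genome, 1,000 peaks/factor,
                                       # 30% planted co-occurrence
_, genes, ws = generate_genome_and_genes(cfg, with_sequence=False)
a, b, _ = generate_peaks(cfg, genes, ws)

res = randomized_overlap_test(a, b, ws, n_samples=10_000, seed=1)
part = stratify(a, b)
print(f"observed overlap : {res.observed_overlap:.0f} bp")
print(f"expected (null)  : {res.expected_mean:.1f} bp")
print(f"fold enrichment  : {res.fold:.2f}")
print(f"empirical p      : {res.empirical_p:.2e}")
print(f"co-bound A peaks : {len(part.both_a)} / {len(a)}")
```

prints

```
observed overlap : 66326 bp
expected (null)  : 5942.1 bp
fold enrichment  : 11.16
empirical p      : 1.00e-04
co-bound A peaks : 323 / 1000
```

The planted 30% co-occurrence produces a base-pair overlap about 11-fold
above the randomization expectation; the p-value sits at its add-one
floor `1/10001`, reported as p < 10⁻⁴. The 323 co-bound peaks are the
300 planted ones plus a handful of chance overlaps.

The same analyses are available from the shell:

```bash
cistromics simulate --out-dir fixtures/
cistromics associate --query fixtures/irf5.bed --reference fixtures/rela.bed \
    --workspace fixtures/workspace.bed --samples 10000 --seed 17 --out assoc.tsv
cistromics pipeline --out-dir run/     # full analysis + report.json
```

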