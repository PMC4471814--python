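# Methods

This note records the models implemented by the package, the parameter
choices that matter, what the synthetic data does and does not emulate,
and the numerical decisions taken where the design was open.

## Interval randomization test

The association between a query and a reference peak set is measured as
the total base-pair overlap (or, in `mode="peaks"`, the number of query
peaks with ≥ 1 bp overlap) and compared against a placement null: in
each of `n_samples` randomizations every query interval is re-placed
uniformly at random inside the workspace, preserving its length.
Placement is uniform over *feasible start positions*: a segment of
length `L` contributes `max(0, L − ℓ + 1)` starts for an interval of
length `ℓ`, segments are chosen with probability proportional to that
count, and sampled intervals never straddle segment boundaries. This
makes the null exactly enumerable on small workspaces, which is how the
sampler is validated (`exact_expected_overlap` enumerates every start).

Choices:

- **Sampled intervals may overlap each other.** Rejecting self-overlap
  would bias the expectation and break enumerability; the observed
  query set may of course also contain overlaps.
- **Cross-chromosome re-placement** is the default: the workspace is
  treated as one background. Per-chromosome placement would condition on
  the observed chromosome occupancy, which is itself part of the signal
  being tested; callers who want it can pass per-chromosome workspaces.
- **Add-one empirical p**, `(1 + #{sim ≥ obs}) / (1 + n_samples)`, so p
  is never zero and has floor `1/(n+1)`; the enrichment side is the
  default, depletion available via `alternative="less"`.
- **Fold on a zero expectation** is reported as +inf with a warning;
  this is reachable only on degenerate toy inputs.

## Stratification and density matrices

Co-occurrence is ≥ 1 bp overlap — the weakest assumption, chosen because
nothing stronger (reciprocal fractions, summit distances) is implied by
the analysis; it is the same rule the association test's "peaks" mode
uses, and the two agree by construction. Density matrices average
coverage in fixed bins over `center ± halfwidth` (defaults ±2000 bp,
10-bp bins) with the peak center defined as the floor midpoint (BED
carries no summit); rows are sorted by height descending with input
order breaking ties, and windows running off a chromosome are
zero-padded so the row count always equals the peak count.

## Gene-relative annotation

Peak centers are assigned to their nearest gene by base distance to the
gene span (ties broken by smallest gene_id). Bins are strand-aware: five
1-kb upstream windows (U1 adjacent to the TSS), the undivided gene BODY,
five 1-kb downstream windows past the TES, else DISTAL. On the minus
strand the TSS/TES anchors are the half-open bounds shifted by one base
so that reflecting all coordinates and flipping strands leaves every
label invariant (verified by a reflection oracle in the tests). Bin
enrichment reuses the association module's placement null — the same
randomized placements are scored for all bins, so the folds are
mass-conserving: weighted by null bin probabilities they average to 1.

Promoter categorization uses a different membership rule — any ≥ 1 bp
overlap of the strand-aware `[TSS − 10 kb, TSS + 0.5 kb)` window —
because a promoter "contains" a peak whether or not the peak center
falls inside. Categories: 1 = both factors, 2 = factor B only, 3 =
factor A only, 0 = neither; exhaustive and mutually exclusive.

The downstream-of-TES statistic is the fraction of genes with ≥ 1 peak
in a D bin, among genes with ≥ 1 non-DISTAL peak (genes never targeted
anywhere are excluded from the denominator).

## Differential expression

The moderated statistic is `d = (x̄₁ − x̄₂)/(s + s₀)` with `s` the
pooled standard error of the mean difference; at `s₀ = 0` it is the
equal-variance t statistic (checked numerically against scipy). `s₀`
defaults to the median of the per-gene `s` values — the common automatic
choice for the fudge constant. Significance uses balanced label
permutations: for each observed |d| used as a cutoff, the estimated
false count is the median across permutations of `#{|d*| ≥ cutoff}`,
divided by the observed count at that cutoff; per-gene q-values take the
minimum over all cutoffs that include the gene, making q monotone
non-increasing in |d|. When fewer distinct permutations exist than
requested, all of them are used with a warning (e.g. 20 for a 3 vs 3
contrast). Calls optionally add a strict fold filter on the antilogged
means (`2^(x̄₁−x̄₂) > threshold`), matching ">2-fold" phrasing on the
intensity scale — a gene at exactly 2.0-fold is excluded.

Stimulation-response genes contrast each post-stimulation time point
against the genotype-matched 0-hr baseline (union over time points);
knockout effects contrast KO vs WT at matched times. Gene-set
enrichment is the one-sided hypergeometric tail with Benjamini–Hochberg
q-values across sets; the permutation FDR is used only for the DE calls
themselves.

## PBM scoring and ROC

A region's score is the maximum Z over every k-length window of the
sequence and its reverse complement (sum and mean are available, but the
best-site score is the default, matching best-k-mer ROC methodology).
Windows containing N are skipped; words absent from the table score the
table minimum — the designed probe library is not exhaustive over all
k-mers, and a neutral floor avoids fabricating affinities. Unbound
(true-negative) regions are placed uniformly in the workspace with
lengths resampled from the bound set and rejected on any peak overlap.
AUC is computed from midranks (`U / (n₊ n₋)`); the p-value uses scipy's
exact Mann–Whitney distribution when `n₊·n₋ ≤ 10⁴` and there are no
ties, else the tie-corrected normal approximation. PFMs are column base
frequencies over the top-N words ranked by Z (lexicographic
tie-breaking).

## Synthetic data

The generator emulates a two-factor ChIP-seq study with an expression
time course. All randomness flows from one master seed through named
SeedSequence substreams (genome, genes, peaks, coverage, motifs,
expression), so every artifact is bit-identical across reruns and every
planted effect is recorded in a truth table.

Default conditions: a 10-Mb genome on two chromosomes of i.i.d. uniform
ACGT; 300 non-overlapping genes (2–8 kb, ≥ 10 kb spacing, random
strands); 1,000 peaks per factor of 150–350 bp with log-normal heights;
factor B placed with a 30% bias into the 1-kb window upstream of random
TSSs; 30% of factor A peaks centered within a small jitter
(±(min length/2 − 1) bp, guaranteeing ≥ 1 bp overlap with varying
widths) of random B peaks, the rest placed independently — so a zero
co-occurrence fraction reduces to full independence and the association
fold calibrates to 1. Coverage is a triangular pileup per peak (apex =
`coverage_depth_scale` × height) over Poisson background. The planted
motif is the ISRE consensus `RNGAAANNGAAACT`; one realization is written
at each designated (co-bound) peak center, and the k-mer table (k = 12,
3,072 entries, mimicking a designed probe library in which all
high-affinity words share one alignment frame) gives consensus-frame
words Z ~ N(8,1) and random decoys Z ~ N(0,1). Expression is log2
intensity = gene baseline N(8,1) + a step induction of `planted_log2_fc`
(default log₂ 2.5) at all post-stimulation times for responsive genes
(drawn preferentially from category-1 promoters) + N(0, 0.4) noise; in
a knockout the induction is removed for genes whose category includes
the deleted factor.

What the generator does *not* emulate: sequence composition structure
(no dinucleotide/GC model), read-level noise, mappability gaps, peak
calling artifacts, probe effects or batch structure in the arrays.
Passing tests therefore demonstrate correctness and calibration of the
statistical machinery on its stated assumptions, not robustness to
those real-data complications.

## Validation experiment sizes

Chosen to give tight checks in a few minutes on one CPU:

- Null calibration: fold measured at 2,000 peaks per set on a 10-Mb
  workspace with 10⁴ randomizations; p-uniformity from 200 independent
  runs at 300 randomizations each (p granularity 1/301, far below the
  KS critical deviation at n = 200), tested against U(0,1) at α = 0.01.
- Enumeration oracle: the worked 455/91 case plus five random ≤ 200-bp
  workspaces, sampled mean within 2 SE of the enumerated expectation.
- Co-occurrence recovery: planted 0.30 at 2,000 peaks on a 100-Mb
  gene-free workspace, so chance co-binding of the independent portion
  (≈ 1%) is negligible against the ±0.03 binomial band; TSS-bias
  ordering over 50 seeded runs at 600 peaks / 10 Mb / 100 placements.
- ROC: 200 regions per class; 100 label shuffles.
- DE: 2,000 genes, 4 replicates per group; power at 200 planted genes
  with 2.5-fold effects and noise σ = log₂2.5/(4√(2/4)) ≈ 0.47 so the
  per-gene t is ≈ 4; null error control over 20 seeds.
- Smoke: the default pipeline run twice in independent directories with
  the same seed, reports compared byte for byte.

## Known limitations

- The nearest-gene search assumes genes on a chromosome do not overlap
  (true of the generator; real annotations with nested genes would need
  an interval tree).
- `sample_unbound` uses rejection sampling; workspaces that are almost
  fully covered by peaks hit the attempt limit by design.
- The permutation FDR is coarse when few distinct permutations exist
  (small replicate counts); the implementation warns rather than
  interpolating.
- bedGraph coverage is materialized densely per chromosome (float32),
  which is simple and fast at the ~100-Mb scales used here but not
  suited to full mammalian genomes.
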