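# Methods

This note documents the models, estimators, defaults and numerical choices
behind `hmcscan`, and what the synthetic-data generator does and does not
emulate.

## Coordinate and annotation conventions

All internal coordinates are 0-based half-open. GTF input (1-based closed) is
converted on read; BED is native. A gene's "intragenic" region is its full
annotated span from TSS to TTS, introns included — exon flattening is
deliberately not performed, because gene-body enrichment of 5hmC is a
span-level phenomenon and the flattened alternative changes denominators
without changing ranks. Overlapping gene spans are allowed; coverage is
computed per gene independently, so a base shared by two genes counts toward
both. Chromosome names are matched by exact string equality.

Biotypes are collapsed onto a controlled vocabulary (protein_coding,
lincRNA, processed_transcript, pseudogene, short_ncRNA, other); anything
ending in "pseudogene" is a pseudogene and the small-RNA classes (miRNA,
snoRNA, snRNA, rRNA, tRNA, …) are short_ncRNA.

## Island caller

The caller follows the window-clustering design of the SICER family:

1. **Deduplication.** At most *r* fragments with identical
   (chrom, start, end, strand) are retained (*r* = 1 by default).
2. **Window counts.** Each fragment contributes one point — the read start
   shifted by `fragment_size / 2` in the strand direction, i.e. the fragment
   midpoint — to the non-overlapping *w*-bp window containing it
   (*w* = 100 bp, fragment size 200 bp).
3. **Eligibility.** With background rate λ_bg = N·w / (f_eff · G) (N retained
   fragments, G genome length, f_eff the effective mappable fraction,
   default 0.74), a window is eligible when its count reaches the smallest
   l₀ with P(X ≥ l₀ | Poisson(λ_bg)) < p₀. p₀ defaults to 0.2, the
   conventional value for this algorithm family.
4. **Clustering.** Islands are maximal runs of eligible windows in which
   consecutive eligible windows are separated by at most *g* bp of
   ineligible windows (*g* ∈ {100, 200}, default 200); the island span runs
   from the first to the last eligible window, gaps included. The island
   score is Σ −ln Poisson pmf(count; λ_bg) over its eligible windows.
5. **Control scoring.** The expected treatment count of an island is the
   control count scaled by the library-size ratio N_treat/N_ctrl, floored at
   λ_bg · span/w so islands in control gaps never reach p = 0. p-values are
   Poisson upper tails, q-values Benjamini–Hochberg, and islands with
   q < 0.01 are retained, ordered by (chrom, start).

Local background estimation, broad/narrow mode switching and mappability
tracks are out of scope; the caller is validated instead by its error rates:
across 50 background-only simulations on a 1 Mb genome the median number of
retained islands is 0, and planted 2 kb regions at 10× background are
recovered at ≥ 95 % (both recomputed by the test suite and
`scripts/acceptance.py`).

## Coverage statistics

Per-gene coverage is `overlap(gene span, merged peaks) / gene length`,
computed with prefix-sum interval arithmetic that is exact (tested against a
per-base boolean oracle). Class boundaries are lower-inclusive —
[0.2, 0.5), [0.5, 0.8), [0.8, 1.0] — chosen so the five classes partition
[0, 1] totally and disjointly; 0 is its own class.

Metagene profiles use 40 length-scaled body bins and 25 fixed 100-bp bins per
flank (2.5 kb each side); the counts are configurable, and the defaults give
flank bins the same 100-bp granularity as the island caller's windows.
Minus-strand gene profiles are reversed before averaging so every profile
reads 5′→3′ (an exact symmetry, tested by strand-flipped twins). Flank bins
truncated at a chromosome boundary use their realized width as denominator;
zero-width bins are excluded from the average rather than counted as zero.
Genes shorter than the bin count still yield all bins by proportional edge
placement (bin edges are real-valued and floored to integer bases).

Genome summaries split each chromosome into intragenic space (the merged
union of gene spans) and its complement; covered base counts in the two
compartments always sum to the merged peak total (a conservation law the
tests assert).

## Expression

TMM normalization: the reference is the sample whose 75th-percentile count
fraction is closest to the mean of those quantiles; for each sample,
M = log2 ratio and A = average log abundance are computed over genes nonzero
in both sample and reference, the 30 % most extreme M and 5 % most extreme A
are trimmed (15 %/2.5 % per tail, mid-ranks), and the factor is the
precision-weighted mean of the retained M (inverse asymptotic binomial
variance weights). Factors are rescaled to geometric mean 1. The test suite
checks this against an independent double-loop implementation to 1e-9.

log2 CPM uses a prior count of 0.5:
`log2((count + 0.5) / (libsize·factor + 1) · 1e6)`. The moderate-to-high
expression threshold is log2 CPM ≥ 2.5 (inclusive); the "expressed at all"
threshold τ_on defaults to log2 CPM ≥ 0. Group-level status flags combine
replicates with the ALL rule (every replicate must pass); an ANY rule is
available but the ALL rule is the default because every downstream
specificity definition quantifies over samples universally.

## Association analytics

- Sample similarity is Spearman's ρ with mid-rank ties over all genes.
- Marked-vs-unmarked expression comparisons use the Wilcoxon rank-sum test:
  exact enumeration when n₁ + n₂ ≤ 12, otherwise the tie-corrected normal
  approximation with continuity correction; groups with fewer than two
  members on either side are reported untestable rather than tested.
- Gene clustering is agglomerative hierarchical clustering of body-bin
  coverage vectors (no flanks) with Euclidean distance and Ward linkage
  (complete/average available), cut at k = 5 and relabeled C1…C5 by strictly
  ascending mean profile coverage. The input order is fixed, so assignments
  are deterministic.
- The coverage–expression correlation is computed **within each coverage
  sample**: gene coverage fractions are paired with the replicate-averaged
  log2 CPM of the matching design cell and the Spearman ρ is averaged over
  samples. A pooled gene × sample correlation is deliberately avoided: CPM
  is compositional, so a gene set whose absolute expression is constant
  acquires a spurious negative pooled correlation whenever the surrounding
  library shifts between organs. The within-sample estimator measures the
  link itself.
- Cluster-level expression medians in the acceptance checks are pooled over
  a cluster's genes × the organ's own libraries; per-library medians of
  adjacent clusters can differ by less than sampling noise when Ward places
  a cut between near-identical profiles, and the other organ's libraries
  legitimately invert the order for organ-specific genes.
- Gene-set membership percentages are rounded half-away-from-zero to
  integers, matching integer-percent reporting conventions.
- The Welch t-test guards zero-variance inputs: if both groups are constant
  the result is flagged degenerate with p = 1 (equal means) or p < 1e-12
  (different means) instead of dividing by zero.

## Specificity definitions

Organ-specific genes use a deterministic threshold rule rather than a
differential-expression model: brain-specific means log2 CPM ≥ 2.5 in every
brain library AND < τ_off (default 0) in every liver library; liver-specific
is symmetric. Sex-specific enrichment requires coverage > τ_cov (default:
any overlap) in every sample of one sex and exactly 0 in every sample of the
other, evaluated genome-wide and per organ; sex chromosomes are included
here because the canonical positive control is X-linked. The exception
classes are evaluated on autosomal protein-coding genes only: class 1 is
moderate-to-high expression in all libraries with zero coverage in all
samples; class 2 is expression below τ_on in all libraries with coverage in
all samples. The two classes are disjoint by construction.

## Synthetic-data generator

The generator emulates the study design the pipeline targets, at toy scale
chosen to keep any single run under ~10 s: a 30 Mb genome (three autosomes
plus X/Y analogs), 1,000 genes with log-normal lengths clipped to
1–100 kb and non-overlapping placement, 12 coverage samples (cerebellum,
cortex, hippocampus, hypothalamus, thalamus, liver × F/M) and 24 expression
libraries (two replicates each, ~1.2 M counts per library).

Planted structure:

- **Coverage targets.** Per-gene latent ranks feed organ-level Beta mixtures
  (brain Beta(2, 1.2), liver Beta(1.2, 2.5)), reproducing the brain > liver
  enrichment ordering. Region deviations implement the relatedness
  hierarchy: thalamus and hypothalamus share a common deviation (σ = 0.03
  between them, 0.01 within), cortex/hippocampus deviate at σ = 0.04,
  cerebellum at σ = 0.07, and liver shares only 55 % of the latent rank —
  so within-brain similarity always exceeds brain–liver similarity and the
  thalamus–hypothalamus pair is tightest. Targets below 0.03 collapse to 0;
  pseudogenes and short ncRNAs are scaled to a quarter.
- **Peaks.** Each gene body is laid out as alternating gap/peak segments:
  peak lengths are Normal(800, 200) truncated to [100, 3000] and rescaled so
  realized coverage equals the target up to rounding; gap weights decrease
  linearly 5′→3′ and nearly vanish at the gene end, producing the planted 3′
  coverage gradient. Sparse intergenic background peaks are added. Mean
  realized peak length across samples is ~795 bp.
- **Sex chromosomes** carry zero coverage except one X-linked gene covered
  at 0.6 only in female samples (both organs) — the Xist-like positive
  control, which the sex-specific scan must recover as its unique
  genome-wide call.
- **Counts.** NB(mean, φ = 0.1) with log2 mean = 9.5 + 1.5·coverage plus a
  small liver shift, scaled to a fixed expected library so planted levels
  are CPM-scale. Housekeeping genes (five classes of 12) are pinned at a
  constitutively high CPM independent of coverage; exception class 1 is
  expressed with zero coverage, class 2 has hard-zero counts with high
  coverage; 40 brain-specific and 20 liver-specific genes are expressed only
  in their organ.
- **Fragments** (for the island caller) are uniform background plus
  (fold − 1)× extra midpoints inside true islands, 200 bp each.

Every planted quantity is recorded in `SyntheticTruth` and echoed to a truth
TSV; all generators are deterministic under a fixed seed (byte-identical
outputs, tested).

What the generator does **not** emulate: read-level sequencing noise,
mappability and GC bias, exon/intron structure, transcript isoforms,
overlapping gene dense regions, and realistic biological dispersion of the
coverage–expression link. Passing tests therefore demonstrate that the
estimators recover the stated structure under the stated noise — not that
real capture-seq data meet those assumptions.

## Problem sizes and determinism

Test and acceptance runs use the generator defaults (1,000 genes, 12 + 24
samples), 50 replicates for the island caller's error-rate simulations on a
1 Mb toy genome, and three seeds for the metagene gradient property. All
randomness flows from `numpy.random.default_rng` seeded per stage, so every
pipeline output is reproducible byte-for-byte for a fixed seed.

## Known limitations

- The island caller is a faithful member of the window-clustering family but
  not a numerical clone of any specific release; retained-island boundaries
  can differ from other implementations at gap edges.
- The threshold-based organ-specificity rule is deliberately simpler than a
  count-model differential-expression test; with few replicates it is
  conservative for genes near the expression threshold.
- Ward clustering at k = 5 gives no uncertainty on cluster boundaries;
  adjacent clusters with near-identical mean profiles are ordered by their
  (close) means, and per-library median expression of such neighbours may
  tie or invert even when the planted link holds.
- TMM assumes most genes are non-differential between samples; the
  compositional caveat discussed under association analytics applies to any
  CPM-scale comparison across organs.
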