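# Methods

## Problem and model

A lncRNA's downstream pathways are inferred from co-variation with
coding genes across a tumor cohort. The pipeline has three stages:
sample harmonization, gene ranking, and pre-ranked GSEA; a fourth
component quantifies concordance between rankings and between
enrichment tables.

### Input handling

Expression matrices are genes × samples tables of non-negative
FPKM/TPM-like abundances. Duplicate gene rows (transcript-level
duplicates) are collapsed by keeping the row with the highest mean —
deterministic and standard. Samples are matched across the lncRNA and
coding matrices by truncating TCGA-style barcodes to their first 4
dash-separated fields (through the vial field); the field count is
configurable because lncRNA quantifications and coding matrices often
disagree on barcode length. Inputs are treated as already normalized;
unless the caller asserts log scale, the pipeline applies log2(x+1)
before any statistic, because fold changes and Pearson correlations on
raw abundances are dominated by outliers.

### Ranking metrics

* **DGE**: samples are ordered by (target abundance, sample id) and the
  top/bottom ⌈q·n⌉ form the high/low groups (q default 0.25). Fixed
  group sizes with a lexicographic tie-break make the split
  deterministic and keep the groups disjoint for any q ≤ 0.5. The score
  is the difference of group means on log2 data — a log2 fold change —
  not a moderated/shrunken estimate, which would change ranks without
  adding information at these group sizes.
* **GBA**: Pearson correlation of each gene with the target across all
  samples; Spearman is Pearson on midranks (average ranks for ties).
  Zero-variance genes are excluded (correlation undefined; scoring them
  0 would interleave them among true near-zero correlations) with the
  count recorded; a zero-variance target is an error.

Ranked lists sort by score descending with ties broken by gene id, so
every downstream statistic is reproducible. Genes absent from all gene
sets stay in the list — they contribute to the "miss" walk, as
pre-ranked GSEA semantics require.

### Enrichment statistic

Classic weighted KS running sum with weight exponent p (default 1): at a
hit the sum rises by |s|ᵖ/N_R, at a miss falls by 1/(N−N_H); ES is the
value of maximal |deviation|, first occurrence winning ties. If all hit
weights are zero (possible with p > 0 and zero scores) hits increment
uniformly by 1/N_H. A set covering the whole list is degenerate; a set
with empty intersection is skipped, not an error, at collection level.

The null is gene-label permutation: uniform random same-size subsets of
the ranked genes. Pools are cached per set size within a run, each pool
seeded by a sub-seed derived deterministically from (master seed, set
size), so results do not depend on the order in which sets are visited.

**NES** divides ES by the mean magnitude of same-sign null values,
making scores comparable across set sizes; an empty same-sign pool
leaves NES undefined (NaN, reported, never silently 0).

**Nominal p** is the two-sided magnitude tail over the full same-size
pool, `(1 + #{|null ES| ≥ |ES|}) / (1 + n_perm)`. Under the gene-label
null the observed ES is exchangeable with the pool, so this p is exactly
uniform, and its floor is 1/(n_perm+1) regardless of how the pool splits
by sign. A sign-restricted denominator was considered and rejected: it
roughly doubles the attainable floor (≈1/(n_perm/2+1)), which after BH
correction across a 50-set collection makes q < 0.05 unreachable for
even a perfect hit at n_perm = 1000. No adaptive/multilevel refinement
of extreme p-values is implemented; the floor is a documented limit.

**FDR** is Benjamini–Hochberg across tested sets (statsmodels), matching
the "FDR q-value" thresholding convention, rather than the original
GSEA sign-stratified NES-based FDR.

**Leading edge**: members at positions ≤ peak for ES ≥ 0, ≥ peak for
ES < 0, in ranking order.

### Ranked-list similarity

For lists A and B restricted to their common universe, the score is
Σₙ e^(−αn) (|topAₙ ∩ topBₙ| + |botAₙ ∩ botBₙ|), n = 1..n_top. Default
n_top = 100 and α = ln(100)/n_top, so the weight at the depth limit is
~1%; the data-driven α tuning of the original ordered-list method is
out of scope. Because a reversed ranking is equally informative, the
reported statistic is the max over both orientations of B, and the
permutation null applies the same max rule — the test never rewards the
orientation search itself. p = (1 + #{null ≥ observed}) / (1 + n_perm).

The implementation is O(N) per evaluation: the gene at A-position i
with B-position p(i) first enters both top-n windows at
n = max(i, p(i)) + 1, so the overlap profile is a cumulative histogram
of max(i, p(i)) (mirrored for bottoms). Tests check it against a
literal set-intersection oracle.

Per-comparison p-values combine with Fisher's method,
X = −2Σ ln pᵢ ~ χ²(2k); "meta p" has no canonical definition for
permutation p-values, and Fisher is the default, exactly testable
choice. Note the combination only strengthens evidence when each
−2 ln p exceeds the per-study null mean of 2 (p ≲ 0.37); for weak
p-values the combined p can legitimately exceed the components.

Enrichment tables are compared on shared set names ordered by NES
descending (weighted overlap + direction) plus the Spearman correlation
of the NES vectors; sets with undefined NES are dropped first.

## Synthetic cohorts

The generator emulates a TCGA-like cohort: the target lncRNA's log2
abundance is Normal(lnc_mean = 4, lnc_sd = 1); per-gene baselines are
Normal(5, 1.5) in log2 space (an FPKM-like spread); responsive genes add
β·(lncRNA log2 abundance) plus Normal(0, noise_sd) noise; null genes are
baseline plus noise. Matrices are emitted on the raw scale (2^x − 1,
floored at 0), and an optional dropout fraction zeroes the lncRNA in a
random sample subset — the heterogeneity scenario (expressed in only
part of the tumors) where the quantile-split DGE metric is preferable to
correlation. Responsive genes react to the *realized* (post-dropout)
lncRNA abundance.

The linear-in-log2 model makes expectations analytic: a responsive
gene's correlation with the target is β·σ_lnc/√(β²σ_lnc² + σ_noise²)
(0.894 at the defaults β = 1, σ_lnc = 1, σ_noise = 0.5), and its
expected log2 fold change is β times the high/low group difference in
mean lncRNA log2 abundance. Test thresholds are derived from these
forms, not tuned.

Reference study conditions (generator defaults): 200 samples, 2000
coding genes, one planted 30-gene set (β = 1, all members responsive),
49 null sets of 10–60 genes drawn from non-planted genes, noise SD 0.5.
A catalog of degenerate fixtures (zero-variance gene, all-tied target,
disjoint samples, duplicate rows, malformed GMT lines) pins the
documented edge-case handling.

What the simulation does **not** model: library-size and batch effects,
count noise/mean–variance coupling, correlated co-expression modules
among null genes, real gene symbol vocabularies, and overlapping gene
sets. Passing tests therefore demonstrate correctness and calibration
of the statistics under a clean signal model, not performance on real
tumor data.

## Numerical and design notes

* All permutation machinery is vectorized (one cumulative sum over an
  n_perm × N increment matrix per set size); null-pool caching makes a
  50-set, 2000-gene, 1000-permutation run take a few seconds.
* Ties: running-sum peak → first occurrence; ranked lists → gene id
  ascending; quantile split → sample id; orientation tie → "same".
* Reproducibility: every random step flows from an explicit seed;
  rerunning any command with identical inputs and seed is byte-identical
  (plots strip embedded timestamps; timestamps live only in logs).
* Validation sizes in the test suite (20 replicates for recovery, 8 for
  meta-analysis, 200 sets / 200 replicate pairs for calibration) were
  chosen to give stable pass/fail behavior at the reference conditions.

## Limitations

* The Monte-Carlo p floor (1/(n_perm+1)) bounds attainable significance;
  very strong enrichments saturate rather than separate.
* Gene-label permutation ignores inter-gene correlation; on real data
  nominal p-values are anti-conservative for sets of co-regulated genes
  (the standard caveat for pre-ranked GSEA).
* The DGE metric is a plain fold change: no covariate adjustment, batch
  correction, or variance moderation.
* The similarity α is fixed, not data-driven; scores are comparable only
  at matching (α, n_top).
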