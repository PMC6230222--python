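# Methods

This note documents the models, conventions and design choices behind
`bipromstate`, in the spirit of a statistical-software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and the BP definition

Internally all coordinates are 0-based half-open; GTF is read and written
as 1-based inclusive.  A minus-strand TSS is the half-open *end* of the
5′-most exon, so `|tss_watson − tss_crick|` is the TSS distance on both
strand configurations without special cases.

A bidirectional promoter is a (+,−) gene pair with anchor-TSS distance
≤ 500 bp whose ± 2 kb TSS windows contain no third annotated gene region.
Divergence is, by default, *not* additionally constrained: opposite strands
plus the distance and exclusion rules suffice.  An optional
`strict_divergent` flag also requires the minus gene's TSS not to lie
downstream of the plus gene's TSS, so both genes transcribe away from the
shared region; the default is permissive because the catalog definition is
stated only in terms of the listed rules.  When a gene could join two
candidate pairs, the pair with the smaller TSS distance wins (ties: the
leftmost pair); each gene joins at most one BP.  This tie rule is a
determinism requirement, not a biological claim.

**Transcribed regions.**  For a gene, the *qualifying transcripts* are
those whose TSS falls within 2 kb downstream of the anchor TSS, inclusive
at both ends (offset 0 qualifies — the anchor transcript itself).  The
*transcripts span* is the half-open TSS-relative interval covering the
exon+intron extent of qualifying transcripts; the *transcript length* is
the length of the genomic union of their exons.  Span length ≥ transcript
length always; both are invariant under transcript reordering and strand
mirroring.

## The scBP matrix

Gene expression is the sum of qualifying isoform TPMs (no renormalization
after aggregation — TPM is used as provided).  The H/L decision compares
Sum(g) = Σ_cells TPM with ties to the Watson gene (the "≥" branch), is
made once on the matrix actually being analyzed (optionally the externally
imputed one — imputation itself is out of scope and handled by a
pass-through hook that records provenance), and is frozen for all
downstream modules.  The scBP matrix is M × 2N with the L half first; by
construction every row's H-half sum dominates its L-half sum.

## Clustering and naming

Rows are transformed log2(TPM + 1) — pseudocount 1 preserves zeros — and
clustered with complete linkage on Euclidean distances
(`scipy.cluster.hierarchy.linkage`).  The tree is cut by cluster *count*
(k = 4), not height, for reproducibility.  All-zero BPs are retained (they
fall into the BLE-like cluster) and are only removed for the concordance
test.  Naming is deterministic: with mL, mH the per-cluster means of the
transformed L and H halves, the lowest mL + mH is BLE; among the rest the
smallest mH − mL is BND, the largest is BSD (ties broken toward the higher
mH, logged), the remainder BWD.  k ≠ 4 keeps numeric labels.

## Statistics

* **Signed-rank test.**  Two-sided paired Wilcoxon; zero differences are
  dropped before ranking (standard practice — the source analysis is
  silent on zeros).  The exact null is used for ≤ 25 tie-free informative
  pairs, otherwise the normal approximation with continuity correction.
  The caption phrase "paired Mann–Whitney" is implemented as this paired
  signed-rank test, its paired form.
* **BH correction** is applied once over all non-excluded BPs (one
  genome-wide family, not per cluster); concordant means q ≤ 0.05.
* **Hypergeometric enrichment** for a contingency cell C_ij uses the upper
  tail of h(x; N = grand total, k = column total, n = row total); on a
  2 × 2 reduction this equals the one-sided Fisher exact test (a test
  asserts this).  Depletion is not tested.
* **Stability model.**  OLS with intercept on 12 features: six HM tracks ×
  {2 kb upstream, 2 kb downstream} strand-aware flank means, log2(x + 1)
  transformed; the response is log2(mean-over-cells TPM + 1).  The log
  transforms are configurable conventions.  Residuals are *internally*
  studentized (single overall σ, leverage-corrected); |r| > 1 calls
  stable/unstable.  A numerically exact fit (residual variance below
  1e-10 of the response scale) yields all-zero studentized residuals
  rather than noise ratios.  Rank-deficient designs raise an error naming
  the collinear columns.

## Spatial binning and enrichment

The 41-bin vector is: 20 × 100 bp bins downstream of the L gene's TSS
ordered distal→TSS, one variable bin covering exactly the inter-TSS region
(width = TSS distance, possibly 0), then 20 bins downstream of the H gene
TSS→distal — the vector reads left-to-right across the locus.  The
ordering does not change the enrichment score (a sum over bins) but is
fixed so intermediate files are reproducible.  Bin contents are coverage
integrals, so the vector total conserves the coverage over the binned
extent.  The background BG_j is the per-bin median over all BPs for that
track; a BP equal to the background scores exactly 0.

ChIP/Input profile matrices use the same bins with counts-per-million
scaling of both tracks (configurable, default on — whether depth
normalization preceded binning in the source analysis is unstated) and a
pseudocount of 1 in the ratio.

**ChromScore.**  The window W_g starts at the anchor TSS and extends the
transcripts-span length in the transcription direction.  Segment overlaps
with W_g are summed per collapsed label and divided by |W_g|; vectors sum
to 1 by construction, and segmentation gaps are counted as Others with a
warning.  The default 18-state ChromHMM collapse maps Tss*/TssBiv → TSS,
Enh* → Enhancer, ReprPC/ReprPCWk/Het → Repressed, and the transcription,
ZNF/repeat and quiescent states → Others; the map is a plain dict/YAML
config input, and already-collapsed labels pass through unchanged.
Per-state aggregation sums gene vectors and renormalizes to percentages so
states with different gene counts and span lengths are comparable.

## Synthetic data: what it emulates, and what it does not

The generator is the package's study-conditions definition, not a
visualization aid.  One chromosome; pairs spaced 70 kb so exclusion
windows never interact by accident, keeping interval logic auditable by
hand.  Defaults: 50 BPs per state × 60 cells.

Per state archetype (log2-TPM units):

| state | mu_L | mu_H | sigma | flip | dropout | cell_corr |
|-------|------|------|-------|------|---------|-----------|
| BLE   | 0.8  | 1.2  | 0.8   | 0.30 | 0.30    | 0.2       |
| BWD   | 3.5  | 5.5  | 0.8   | 0.10 | 0.10    | 0.4       |
| BSD   | 2.5  | 8.5  | 0.8   | 0.00 | 0.05    | 0.1       |
| BND   | 6.0  | 6.3  | 0.8   | 0.40 | 0.05    | 0.8       |

Expression is log-normal around the archetype means with a shared per-cell
factor (variance fraction `cell_corr`) that plants the state ordering of
L–H correlation (BND highest); `flip` swaps the two genes' values within a
cell (frequent in BND, never in BSD); Bernoulli dropout zeroes values,
with probability decreasing in expression as in full-length scRNA-seq
chemistry.  Means separate the four archetypes by several log2 units —
"moderate noise" conditions under which hierarchical clustering is
expected to recover the states.  TSS distances are largest in BLE and
smallest in BND; transcripts spans are drawn shorter for the H gene in
BWD/BSD; biotype mixes plant a PC→PC excess in BWD/BND and NC-containing
pairs in BLE.  Track amplitudes put active marks and TFs highest in BND
and repressive marks highest in BLE; segmentation compositions follow the
same logic with exact per-window label proportions.

Deliberate *decoy* records violate each catalog rule (a pair at 501 bp; a
pair with a third gene inside the exclusion window) and are marked in the
truth table, giving the filters negative tests.

The stability dataset draws per-flank coverage levels, extracts the
realized 12-feature matrix through the public `build_features`, and sets
the response to intercept + Xβ + N(0, 0.5²) with 10% of genes offset by
± 5σ (± 2.5).  Deriving the response from realized features keeps the
planted linear model exact even where the two genes' flanks overlap
additively.

Not emulated: read-level data, cell-type mixtures, expression-dependent
dropout curves, correlated noise between neighboring pairs, realistic
ChIP-seq fragment-size effects.  Passing tests therefore demonstrate the
correctness and calibration of the *computations* under controlled planted
signal, not the biological effect sizes of any real cell line.

Determinism: every stage draws from a substream spawned from the single
seed, and text outputs are byte-identical across reruns (tested).

## Problem sizes

Tests run the full default study (200 BPs × 60 cells, ~1 s per stage) for
acceptance-grade checks and a reduced 12 × 20 study for unit fixtures;
brute-force oracles (2ⁿ sign-pattern enumeration at n ≤ 12, O(n³) linkage
at n ≤ 8, per-base counting over kb-scale windows) are kept at sizes where
exhaustive computation is instant.  These sizes were chosen as the
smallest at which every planted effect is comfortably detectable.

## Known limitations

* The catalog's pair-matching is greedy by TSS distance; a globally
  optimal matching could differ in rare chained configurations.
* The exact signed-rank path requires tie-free absolute differences; tied
  continuous data silently fall back to the corrected normal
  approximation.
* ChromScore assumes the segmentation tiles each window; overlapping
  segmentation records would be double-counted (none are produced by the
  generator, and ChromHMM output is non-overlapping).
* The stability model is deliberately linear (OLS); regularized or
  nonlinear predictors are out of scope.
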