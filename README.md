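# bipromstate

Transcription-state analysis of **bidirectional promoters (BPs)** — pairs of
genes on opposite DNA strands whose transcription start sites (TSSs) lie
within 500 bp of each other, each driven by its own core promoter.  Bulk
RNA-seq averages over cells and can hide how the two genes of a pair behave
together; single-cell RNA-seq resolves it.  `bipromstate` is for
computational genomicists who want to classify BPs into single-cell
transcription states and relate those states to structural and epigenomic
features (TF binding, histone modifications, chromatin-state segmentations,
inferred RNA stability).

## The method

1. **Catalog.**  From an Ensembl-style GTF, divergent gene pairs are kept
   when the anchor TSSs (each gene's most 5′ TSS) are ≤ 500 bp apart and no
   third annotated gene region intersects ± 2 kb of either TSS.
2. **scBP matrix.**  Isoform TPMs are summed per gene over transcripts
   starting within 2 kb of the anchor TSS.  Per pair, the gene with the
   larger total expression Sum(g) = Σ_c TPM(g, c) is the **H** (higher)
   gene — ties go to the Watson gene — and the M × 2N *swapped* matrix
   stores each BP's **L**-gene expression in all N cells followed by its
   H-gene expression.
3. **States.**  Rows, transformed log2(TPM + 1), are clustered by
   complete-linkage hierarchical clustering with Euclidean distance and cut
   into four clusters, named by mean expression: **BLE** (both low),
   **BWD** (weak L–H difference), **BSD** (strong difference), **BND** (no
   difference).
4. **Concordance.**  Per BP, a paired two-sided Wilcoxon signed-rank test
   on the L and H cell vectors, Benjamini–Hochberg corrected; the
   *concordant ratio* is the fraction of significant (q ≤ 0.05) BPs per
   state.  Gene-product (protein-coding vs non-coding) composition per
   state is scored with an upper-tail hypergeometric test on the 4 × 4
   contingency table.
5. **Spatial TF enrichment.**  Coverage is counted in 41 bins per BP
   (20 × 100 bp downstream of each TSS plus one variable-width inter-TSS
   bin) and scored against the per-bin median over all BPs:
   `Enrich(TF) = Σ_j log2((TF_j + 1)/(BG_j + 1))`.
6. **ChromScore.**  The fraction of each gene's *transcripts span* window
   (the exon+intron extent of transcripts starting within 2 kb of the
   anchor TSS) covered by collapsed chromatin states {TSS, Enhancer,
   Repressed, Others}; vectors sum to 1 and aggregate to per-state
   percentages.
7. **RNA stability.**  OLS predicts each gene's average single-cell
   expression from 12 histone features (6 marks × 2 kb up/downstream flank
   means); genes with internally studentized residual > 1 are called
   *stable*, < −1 *unstable*, with per-state hypergeometric enrichment.

A seeded synthetic-data generator emulates all input modalities with four
planted state archetypes, so the whole pipeline runs and is tested without
any external data.

## Worked example

```python
from bipromstate import (SimConfig, generate_annotation, generate_sc_expression,
                         find_bps, gene_expression, build_scbp, cluster_states,
                         call_concordance, concordant_ratio)
from bipromstate.clustering import correlation_table

cfg = SimConfig(seed=0)                      # 4 states x 50 BPs x 60 cells
ann = generate_annotation(cfg)
iso, _ = generate_sc_expression(cfg, ann)
bps = find_bps(ann.genes)                    # TSS distance <= 500 bp, +/-2 kb clear
scbp = build_scbp(bps, gene_expression(iso, ann.genes))
assignment = cluster_states(scbp, k=4)       # complete linkage on log2(TPM+1)

states = assignment.to_frame()["state"]
print(states.value_counts().sort_index().to_string())
ratios = concordant_ratio(call_concordance(scbp, alpha=0.05), assignment)
print(ratios.round(2).to_string())
corr = correlation_table(scbp)["pearson_r"].groupby(states).median()
print(corr.round(2).to_string())
```

prints

```
state
BLE    50
BND    50
BSD    50
BWD    50
state
BLE    0.08
BND    0.10
BSD    1.00
BWD    1.00
state
BLE    0.01
BND    0.63
BSD    0.07
BWD   -0.09
```

All 200 planted BPs land in their archetype's cluster.  The BSD and BWD
states — where one gene consistently dominates — are fully concordant,
while BND (both genes expressed alike, frequent per-cell switching) is
mostly discordant yet shows the highest L–H correlation across cells, and
BLE is too lowly expressed to call.

The same analysis runs from the shell:

```sh
bipromstate all --demo --seed 0 --outdir results/demo   # synthetic end-to-end
bipromstate simulate --outdir sim --seed 0              # or stage by stage
bipromstate catalog --gtf sim/annotation.gtf --out catalog.tsv
```

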