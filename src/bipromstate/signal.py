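"""Spatial coverage binning around BPs, TF enrichment scores, ChIP/Input
profile matrices, and chromatin-state (ChromScore) summaries.

The spatial unit is the 41-bin BP vector: 20 bins of 100 bp downstream of
the L gene's TSS (ordered distal -> TSS), one variable-width bin covering
the inter-TSS region, and 20 bins downstream of the H gene's TSS (TSS ->
distal), so the vector reads left-to-right across the locus in the L -> H
orientation.  The enrichment score of a TF at a BP is

    Enrich = sum_j log2((TF_j + 1) / (BG_j + 1)),   j = 1..41

with BG_j the per-bin median of that TF's signal across all BPs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .annotation import BidirectionalPromoter, GeneModel, transcripts_span_length
from .genomic import Coverage

GENE_BINS = 20
BIN_SIZE = 100
COLLAPSED_STATES = ("TSS", "Enhancer", "Repressed", "Others")

#: default collapse of the 18-state ChromHMM mnemonics; TSS-, enhancer- and
#: repression-related states are grouped, everything else is Others.
DEFAULT_COLLAPSE_MAP: dict[str, str] = {
    "TssA": "TSS", "TssFlnk": "TSS", "TssFlnkU": "TSS", "TssFlnkD": "TSS", "TssBiv": "TSS",
    "EnhG1": "Enhancer", "EnhG2": "Enhancer", "EnhA1": "Enhancer", "EnhA2": "Enhancer",
    "EnhWk": "Enhancer", "EnhBiv": "Enhancer",
    "ReprPC": "Repressed", "ReprPCWk": "Repressed", "Het": "Repressed",
    "Tx": "Others", "TxWk": "Others", "ZNF/Rpts": "Others", "Quies": "Others",
    # identity on already-collapsed labels
    "TSS": "TSS", "Enhancer": "Enhancer", "Repressed": "Repressed", "Others": "Others",
}


def downstream_bins(gene: GeneModel, n_bins: int = GENE_BINS, bin_size: int = BIN_SIZE):
    """Genomic intervals of the n 100-bp bins downstream of the TSS.

    Index 0 abuts the TSS; bins run in the gene's transcription direction.
    """
    tss = gene.anchor_tss
    if gene.strand == "+":
        return [(tss + i * bin_size, tss + (i + 1) * bin_size) for i in range(n_bins)]
    return [(tss - (i + 1) * bin_size, tss - i * bin_size) for i in range(n_bins)]


def bin_bp(coverage: Coverage, bp: BidirectionalPromoter, h_gene: str) -> np.ndarray:
    """The 41-element binned signal vector for one BP and one track.

    ``h_gene`` is "watson" or "crick".  A zero TSS distance yields a
    zero-width middle bin with count 0.
    """
    if h_gene not in ("watson", "crick"):
        raise ValueError("h_gene must be 'watson' or 'crick'")
    gh = bp.gene(h_gene)
    gl = bp.gene("crick" if h_gene == "watson" else "watson")
    l_bins = [coverage.interval_sum(bp.chrom, s, e) for s, e in downstream_bins(gl)]
    h_bins = [coverage.interval_sum(bp.chrom, s, e) for s, e in downstream_bins(gh)]
    lo = min(gl.anchor_tss, gh.anchor_tss)
    hi = max(gl.anchor_tss, gh.anchor_tss)
    middle = coverage.interval_sum(bp.chrom, lo, hi)
    return np.array(l_bins[::-1] + [middle] + h_bins)


def bin_all_bps(
    coverage: Coverage, bps: list[BidirectionalPromoter], h_gene_of: dict[str, str]
) -> np.ndarray:
    """Stack 41-bin vectors for all BPs (rows follow the input order)."""
    return np.vstack([bin_bp(coverage, bp, h_gene_of[bp.bp_id]) for bp in bps])


def tf_enrichment(binned: np.ndarray) -> np.ndarray:
    """Per-BP enrichment scores for one TF from its n_bp x 41 bin matrix.

    The background is the per-bin median across BPs; a BP identical to the
    background everywhere scores exactly 0.
    """
    binned = np.asarray(binned, dtype=float)
    if binned.ndim != 2 or binned.shape[1] != 2 * GENE_BINS + 1:
        raise ValueError(f"expected an n x {2 * GENE_BINS + 1} bin matrix")
    bg = np.median(binned, axis=0)
    return np.log2((binned + 1.0) / (bg + 1.0)).sum(axis=1)


def enrichment_table(
    coverages: dict[str, Coverage],
    bps: list[BidirectionalPromoter],
    h_gene_of: dict[str, str],
) -> pd.DataFrame:
    """BP x TF table of enrichment scores (rows follow catalog order)."""
    cols = {}
    for tf, cov in coverages.items():
        cols[tf] = tf_enrichment(bin_all_bps(cov, bps, h_gene_of))
    return pd.DataFrame(cols, index=pd.Index([bp.bp_id for bp in bps], name="bp_id"))


def percent_positive_tfs(scores: pd.DataFrame) -> pd.Series:
    """Percentage of TFs with enrichment score > 0, per BP."""
    return (scores > 0).mean(axis=1) * 100.0


def profile_matrix(
    chip: Coverage,
    input_cov: Coverage,
    bps: list[BidirectionalPromoter],
    h_gene_of: dict[str, str],
    depth_normalize: bool = True,
) -> pd.DataFrame:
    """Per-BP 41-bin ChIP/Input ratio profiles.

    Both tracks are scaled to counts-per-million before the pseudocounted
    ratio (chip + 1) / (input + 1) when ``depth_normalize`` is set.  Use
    ``np.log2`` of the result for heatmap display and
    :func:`median_profiles` for per-state median profiles.
    """
    chip_bins = bin_all_bps(chip, bps, h_gene_of)
    input_bins = bin_all_bps(input_cov, bps, h_gene_of)
    if depth_normalize:
        for arr, cov in ((chip_bins, chip), (input_bins, input_cov)):
            total = cov.total()
            if total > 0:
                arr *= 1e6 / total
    ratio = (chip_bins + 1.0) / (input_bins + 1.0)
    return pd.DataFrame(ratio, index=pd.Index([bp.bp_id for bp in bps], name="bp_id"))


def median_profiles(profiles: pd.DataFrame, states: pd.Series) -> pd.DataFrame:
    """Median 41-bin profile per transcription state."""
    return profiles.groupby(states.reindex(profiles.index)).median()


def chromscore(
    gene: GeneModel,
    segmentation: pd.DataFrame,
    collapse_map: dict[str, str] | None = None,
    window: int = 2000,
    span_length: int | None = None,
) -> pd.Series:
    """Fraction of a gene's transcripts-span window in each collapsed state.

    The window starts at the gene's anchor TSS and extends the length of
    its transcripts span in the direction of transcription.  Segments are
    clipped to the window; un-annotated gaps count as Others (with a
    warning).  The four fractions sum to 1.
    """
    cmap = DEFAULT_COLLAPSE_MAP if collapse_map is None else collapse_map
    length = transcripts_span_length(gene, window) if span_length is None else span_length
    tss = gene.anchor_tss
    if gene.strand == "+":
        w_start, w_end = tss, tss + length
    else:
        w_start, w_end = tss - length, tss
    sub = segmentation[segmentation["chrom"] == gene.chrom]
    totals = dict.fromkeys(COLLAPSED_STATES, 0.0)
    covered = 0
    for row in sub.itertuples():
        lo, hi = max(row.start, w_start), min(row.end, w_end)
        if hi <= lo:
            continue
        label = cmap.get(row.label)
        if label is None:
            raise KeyError(f"segmentation label {row.label!r} missing from collapse map")
        totals[label] += hi - lo
        covered += hi - lo
    if covered < length:
        warnings.warn(
            f"{gene.gene_id}: segmentation gap of {length - covered} bp in span window; "
            "counted as Others"
        )
        totals["Others"] += length - covered
    return pd.Series(totals, name=gene.gene_id) / length


def chromscore_table(
    genes: list[GeneModel],
    segmentation: pd.DataFrame,
    collapse_map: dict[str, str] | None = None,
    window: int = 2000,
) -> pd.DataFrame:
    """Per-gene ChromScore vectors (rows sum to 1)."""
    return pd.DataFrame(
        [chromscore(g, segmentation, collapse_map, window) for g in genes]
    ).rename_axis("gene_id")


def chromscore_state_percent(scores: pd.DataFrame, gene_states: pd.Series) -> pd.DataFrame:
    """Aggregate gene ChromScores per state and convert to percentages.

    Per state the gene vectors are summed and renormalized to sum to 100,
    making states with different gene counts and spans comparable.
    """
    summed = scores.groupby(gene_states.reindex(scores.index)).sum()
    return summed.div(summed.sum(axis=1), axis=0) * 100.0
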