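"""Gene annotation parsing, the bidirectional-promoter catalog, and
structural features.

A *bidirectional promoter* (BP) here is a pair of genes on opposite strands
whose anchor TSSs (the most 5' TSS over each gene's transcripts) lie at most
``max_tss_distance`` bp apart, with no third annotated gene region inside a
``exclusion_flank`` window around either TSS.

Coordinates are internal 0-based half-open; a minus-strand TSS is the
half-open *end* coordinate of its 5'-most exon, so TSS distances and window
arithmetic need no strand special-casing beyond direction signs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gffutils
import pandas as pd

from .genomic import Interval, merge_intervals, union_length

PC = "PC"
NC = "NC"

#: Ensembl biotypes counted as protein-coding; everything else is non-coding.
PROTEIN_CODING_BIOTYPES = frozenset({"protein_coding"})


@dataclass
class TranscriptModel:
    """One transcript: sorted, disjoint exons on a single strand."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.transcript_id}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping exons in {self.transcript_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """5' end: leftmost coordinate on '+', rightmost (exclusive) on '-'."""
        return self.start if self.strand == "+" else self.end


@dataclass
class GeneModel:
    """A gene with its transcripts and a collapsed PC/NC biotype class."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        for t in self.transcripts:
            if t.strand != self.strand or t.gene_id != self.gene_id:
                raise ValueError(f"transcript {t.transcript_id} inconsistent with gene {self.gene_id}")

    @property
    def biotype_class(self) -> str:
        return PC if self.biotype in PROTEIN_CODING_BIOTYPES else NC

    @property
    def anchor_tss(self) -> int:
        """Most 5' TSS over all transcripts (strand-aware extreme)."""
        tsss = [t.tss for t in self.transcripts]
        return min(tsss) if self.strand == "+" else max(tsss)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def direction(self) -> int:
        return 1 if self.strand == "+" else -1


@dataclass
class BidirectionalPromoter:
    """A validated divergent gene pair."""

    bp_id: str
    gene_watson: GeneModel
    gene_crick: GeneModel
    tss_distance: int = field(init=False)

    def __post_init__(self) -> None:
        if self.gene_watson.strand != "+" or self.gene_crick.strand != "-":
            raise ValueError(f"{self.bp_id}: watson must be '+', crick '-'")
        self.tss_distance = abs(self.gene_watson.anchor_tss - self.gene_crick.anchor_tss)

    @property
    def chrom(self) -> str:
        return self.gene_watson.chrom

    def gene(self, which: str) -> GeneModel:
        if which == "watson":
            return self.gene_watson
        if which == "crick":
            return self.gene_crick
        raise KeyError(which)


def parse_annotation(gtf_path) -> list[GeneModel]:
    """Read an Ensembl-dialect GTF into :class:`GeneModel` records.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Exons are grouped under their ``transcript_id``/``gene_id`` attributes;
    explicit gene/transcript feature lines are used for biotype lookup only.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    biotypes: dict[str, str] = {}
    for g in db.features_of_type("gene"):
        bt = g.attributes.get("gene_biotype", g.attributes.get("gene_type", ["protein_coding"]))
        biotypes[g.attributes["gene_id"][0]] = bt[0]

    tx_exons: dict[str, list[Interval]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}
    for ex in db.features_of_type("exon"):
        tid = ex.attributes["transcript_id"][0]
        gid = ex.attributes["gene_id"][0]
        tx_exons.setdefault(tid, []).append((ex.start - 1, ex.end))
        tx_meta[tid] = (gid, ex.seqid, ex.strand)

    genes: dict[str, GeneModel] = {}
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tid, exons in tx_exons.items():
        gid, chrom, strand = tx_meta[tid]
        by_gene.setdefault(gid, []).append(
            TranscriptModel(tid, gid, chrom, strand, merge_intervals(exons))
        )
    for gid, txs in by_gene.items():
        txs.sort(key=lambda t: t.transcript_id)
        genes[gid] = GeneModel(
            gid, txs[0].chrom, txs[0].strand, txs, biotypes.get(gid, "protein_coding")
        )
    return [genes[g] for g in sorted(genes)]


def find_bps(
    genes: list[GeneModel],
    max_tss_distance: int = 500,
    exclusion_flank: int = 2000,
    strict_divergent: bool = False,
) -> list[BidirectionalPromoter]:
    """Extract the BP catalog from a gene list.

    Rules: opposite strands; anchor-TSS distance <= ``max_tss_distance``;
    no other gene's annotated extent intersects the ``+/- exclusion_flank``
    window around either anchor TSS.  With ``strict_divergent`` the minus
    gene's TSS must additionally not lie downstream of the plus gene's TSS,
    so transcription proceeds away from the shared region.

    Each gene joins at most one BP: candidate pairs are accepted greedily by
    increasing TSS distance, ties broken by leftmost coordinate.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    candidates: list[tuple[int, int, GeneModel, GeneModel]] = []
    for chrom, glist in by_chrom.items():
        plus = [g for g in glist if g.strand == "+"]
        minus = [g for g in glist if g.strand == "-"]
        for gw in plus:
            for gc in minus:
                dist = abs(gw.anchor_tss - gc.anchor_tss)
                if dist > max_tss_distance:
                    continue
                if strict_divergent and gc.anchor_tss > gw.anchor_tss:
                    continue
                # exclusion zone around either TSS must be free of third genes
                ok = True
                for tss in (gw.anchor_tss, gc.anchor_tss):
                    lo, hi = tss - exclusion_flank, tss + exclusion_flank
                    for other in glist:
                        if other.gene_id in (gw.gene_id, gc.gene_id):
                            continue
                        if other.start < hi and other.end > lo:
                            ok = False
                            break
                    if not ok:
                        break
                if ok:
                    candidates.append((dist, min(gw.start, gc.start), gw, gc))

    candidates.sort(key=lambda c: (c[0], c[1], c[2].gene_id))
    used: set[str] = set()
    bps: list[BidirectionalPromoter] = []
    for dist, _, gw, gc in candidates:
        if gw.gene_id in used or gc.gene_id in used:
            continue
        used.update((gw.gene_id, gc.gene_id))
        bps.append(BidirectionalPromoter(f"BP_{gw.gene_id}_{gc.gene_id}", gw, gc))
    bps.sort(key=lambda b: (b.chrom, min(b.gene_watson.anchor_tss, b.gene_crick.anchor_tss)))
    return bps


def qualifying_transcripts(gene: GeneModel, window: int = 2000) -> list[TranscriptModel]:
    """Transcripts whose TSS lies within ``window`` bp downstream (inclusive)
    of the gene's anchor TSS, along the gene's direction of transcription."""
    anchor = gene.anchor_tss
    out = []
    for t in gene.transcripts:
        offset = (t.tss - anchor) * gene.direction
        if 0 <= offset <= window:
            out.append(t)
    return out


def transcripts_span(gene: GeneModel, window: int = 2000) -> Interval:
    """Genomic extent (exons + introns) of qualifying transcripts, as a
    half-open interval in TSS-relative coordinates along transcription.

    Raises ``ValueError`` when no transcript qualifies.
    """
    txs = qualifying_transcripts(gene, window)
    if not txs:
        raise ValueError(f"gene {gene.gene_id}: no transcript starts within {window} bp of anchor TSS")
    anchor = gene.anchor_tss
    if gene.strand == "+":
        rel = [(t.start - anchor, t.end - anchor) for t in txs]
    else:
        rel = [(anchor - t.end, anchor - t.start) for t in txs]
    return (min(s for s, _ in rel), max(e for _, e in rel))


def transcripts_span_length(gene: GeneModel, window: int = 2000) -> int:
    s, e = transcripts_span(gene, window)
    return e - s


def transcript_length(gene: GeneModel, window: int = 2000) -> int:
    """Length of the genomic union of exons of qualifying transcripts."""
    txs = qualifying_transcripts(gene, window)
    if not txs:
        raise ValueError(f"gene {gene.gene_id}: no transcript starts within {window} bp of anchor TSS")
    exons = [iv for t in txs for iv in t.exons]
    return union_length(exons)


def catalog_table(bps: list[BidirectionalPromoter], window: int = 2000) -> pd.DataFrame:
    """Tabulate the BP catalog with structural features, one row per BP."""
    rows = []
    for bp in bps:
        row = {
            "bp_id": bp.bp_id,
            "chrom": bp.chrom,
            "watson_gene": bp.gene_watson.gene_id,
            "crick_gene": bp.gene_crick.gene_id,
            "watson_tss": bp.gene_watson.anchor_tss,
            "crick_tss": bp.gene_crick.anchor_tss,
            "tss_distance": bp.tss_distance,
            "watson_biotype": bp.gene_watson.biotype_class,
            "crick_biotype": bp.gene_crick.biotype_class,
        }
        for which in ("watson", "crick"):
            g = bp.gene(which)
            try:
                row[f"{which}_span"] = transcripts_span_length(g, window)
                row[f"{which}_transcript_length"] = transcript_length(g, window)
            except ValueError:
                warnings.warn(f"{g.gene_id}: no qualifying transcript; span flagged missing")
                row[f"{which}_span"] = pd.NA
                row[f"{which}_transcript_length"] = pd.NA
        rows.append(row)
    return pd.DataFrame(rows)


def write_gtf(genes: list[GeneModel], path) -> None:
    """Write genes as Ensembl-dialect GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\tbipromstate\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; gene_biotype "{g.biotype}";'
                fh.write(
                    f"{g.chrom}\tbipromstate\ttranscript\t{t.start + 1}\t{t.end}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for i, (s, e) in enumerate(t.exons, 1):
                    eattrs = tattrs + f' exon_number "{i}";'
                    fh.write(
                        f"{g.chrom}\tbipromstate\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{eattrs}\n"
                    )
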