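"""Synthetic data generator for the bidirectional-promoter analysis.

Emulates, at desk scale, the data modalities the analysis consumes:

* an Ensembl-style annotation containing divergent gene pairs with
  controlled TSS distances, transcripts spans and biotypes (plus deliberate
  rule-violating decoy pairs so catalog filters have negative tests),
* isoform-level single-cell TPM tables with four planted transcription-state
  archetypes (BLE, BWD, BSD, BND), per-cell low/high flipping, a shared
  per-cell factor controlling L-H correlation, and Bernoulli dropout,
* coverage tracks (7 histone marks, DNaseI, Input, 5 TFs) whose amplitude
  depends on the planted state,
* a chromatin-state segmentation whose label composition depends on state,
* a histone-feature regression dataset with planted stability outliers.

Everything is a deterministic function of ``SimConfig.seed``; each stage
draws from its own spawned substream so stages can be rerun independently.
Truth tables carry everything needed to score downstream recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from .annotation import GeneModel, TranscriptModel, write_gtf
from .genomic import Coverage

STATES = ("BLE", "BWD", "BSD", "BND")
HM_TRACKS = ("H3K4me1", "H3K4me3", "H3K36me3", "H3K27me3", "H3K9me3", "H3K27ac", "H3K122ac")
TF_TRACKS = ("GABPA", "MYC", "YY1", "NRF1", "E2F1")
ACTIVE_MARKS = ("H3K4me1", "H3K4me3", "H3K36me3", "H3K27ac", "H3K122ac")
REPRESSIVE_MARKS = ("H3K27me3", "H3K9me3")
SEG_LABELS = ("TSS", "Enhancer", "Repressed", "Others")
CATEGORIES = ("NC->NC", "NC->PC", "PC->NC", "PC->PC")


@dataclass
class StateArchetype:
    """Planted expression behaviour of one transcription state.

    Means are in log2-TPM units; ``cell_corr`` is the fraction of log-scale
    variance shared between the two genes of a pair within a cell (drives
    the per-state L-H single-cell correlation).
    """

    name: str
    mu_L: float
    mu_H: float
    sigma: float
    flip_prob: float
    dropout_prob: float
    cell_corr: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_L > self.mu_H:
            raise ValueError(f"{self.name}: mu_L must be <= mu_H")
        if not 0 <= self.flip_prob <= 0.5:
            raise ValueError(f"{self.name}: flip_prob must be in [0, 0.5]")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError(f"{self.name}: dropout_prob must be in [0, 1)")
        if not 0 <= self.cell_corr <= 1:
            raise ValueError(f"{self.name}: cell_corr must be in [0, 1]")


def default_archetypes() -> dict[str, StateArchetype]:
    """The four default archetypes.

    BLE: both genes low; BWD: weak L-H difference; BSD: strong difference
    with the H gene the highest of any state's L side; BND: near-equal
    expression with the strongest per-cell coupling (highest correlation)
    and frequent flips.  Dropout falls with expression level, as in
    full-length scRNA-seq protocols.
    """
    return {
        "BLE": StateArchetype("BLE", 0.8, 1.2, 0.8, 0.30, 0.30, 0.2),
        "BWD": StateArchetype("BWD", 3.5, 5.5, 0.8, 0.10, 0.10, 0.4),
        "BSD": StateArchetype("BSD", 2.5, 8.5, 0.8, 0.00, 0.05, 0.1),
        "BND": StateArchetype("BND", 6.0, 6.3, 0.8, 0.40, 0.05, 0.8),
    }


def _default_track_amplitudes() -> dict[str, dict[str, float]]:
    """Mean counts per 50 bp bin around the promoter, per track and state."""
    amps: dict[str, dict[str, float]] = {}
    for t in ("H3K4me3", "H3K27ac", "H3K122ac", "H3K4me1", "DNaseI"):
        amps[t] = {"BLE": 3, "BWD": 20, "BSD": 20, "BND": 30}
    amps["H3K36me3"] = {"BLE": 2, "BWD": 15, "BSD": 15, "BND": 20}
    for t in REPRESSIVE_MARKS:
        amps[t] = {"BLE": 20, "BWD": 3, "BSD": 3, "BND": 2}
    amps["Input"] = {s: 5 for s in STATES}
    for t in TF_TRACKS:
        amps[t] = {"BLE": 2, "BWD": 12, "BSD": 12, "BND": 25}
    return amps


def _default_segmentation_mix() -> dict[str, dict[str, float]]:
    return {
        "BLE": {"TSS": 0.10, "Enhancer": 0.10, "Repressed": 0.60, "Others": 0.20},
        "BWD": {"TSS": 0.30, "Enhancer": 0.30, "Repressed": 0.05, "Others": 0.35},
        "BSD": {"TSS": 0.25, "Enhancer": 0.40, "Repressed": 0.05, "Others": 0.30},
        "BND": {"TSS": 0.30, "Enhancer": 0.45, "Repressed": 0.03, "Others": 0.22},
    }


def _default_biotype_mix() -> dict[str, dict[str, float]]:
    # categories are L-gene -> H-gene; PC->PC excess planted in BWD/BND,
    # NC-containing pairs in BLE
    return {
        "BLE": {"NC->NC": 0.35, "NC->PC": 0.10, "PC->NC": 0.35, "PC->PC": 0.20},
        "BWD": {"NC->NC": 0.05, "NC->PC": 0.10, "PC->NC": 0.10, "PC->PC": 0.75},
        "BSD": {"NC->NC": 0.10, "NC->PC": 0.20, "PC->NC": 0.20, "PC->PC": 0.50},
        "BND": {"NC->NC": 0.05, "NC->PC": 0.07, "PC->NC": 0.08, "PC->PC": 0.80},
    }


#: planted regression weights for the stability dataset (12 features)
DEFAULT_STABILITY_BETA = (0.6, -0.4, 0.5, 0.3, -0.2, 0.7, 0.2, -0.5, 0.4, -0.3, 0.6, -0.1)


@dataclass
class SimConfig:
    """Full parameterization of one synthetic study."""

    n_bp_per_state: int = 50
    n_cells: int = 60
    seed: int = 0
    states: dict[str, StateArchetype] = field(default_factory=default_archetypes)
    tss_distance_range: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "BLE": (250, 500),
            "BWD": (100, 300),
            "BSD": (100, 300),
            "BND": (20, 120),
        }
    )
    # transcripts-span ranges per state: in BWD/BSD the H gene is shorter
    span_l_range: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "BLE": (5000, 25000),
            "BWD": (8000, 25000),
            "BSD": (8000, 25000),
            "BND": (3000, 15000),
        }
    )
    span_h_range: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "BLE": (5000, 25000),
            "BWD": (1500, 6000),
            "BSD": (1500, 6000),
            "BND": (3000, 15000),
        }
    )
    biotype_mix: dict[str, dict[str, float]] = field(default_factory=_default_biotype_mix)
    track_amplitudes: dict[str, dict[str, float]] = field(default_factory=_default_track_amplitudes)
    segmentation_mix: dict[str, dict[str, float]] = field(default_factory=_default_segmentation_mix)
    n_decoys: int = 2
    chrom: str = "chr1"
    bp_spacing: int = 70000
    stability_tracks: tuple[str, ...] = HM_TRACKS[:6]
    stability_beta: tuple[float, ...] = DEFAULT_STABILITY_BETA
    stability_intercept: float = 3.0
    stability_noise_sd: float = 0.5
    stability_outlier_frac: float = 0.1
    stability_delta: float | None = None  # defaults to 5 * noise sd

    def __post_init__(self) -> None:
        if self.n_bp_per_state < 1 or self.n_cells < 1:
            raise ValueError("counts must be positive")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for st, mix in self.biotype_mix.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"biotype_mix for {st} must sum to 1")
        for st, mix in self.segmentation_mix.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"segmentation_mix for {st} must sum to 1")
        if len(self.stability_beta) != 2 * len(self.stability_tracks):
            raise ValueError("stability_beta must have 2 weights per stability track")

    @property
    def state_names(self) -> list[str]:
        return list(self.states)

    @property
    def delta(self) -> float:
        return 5 * self.stability_noise_sd if self.stability_delta is None else self.stability_delta

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))


@dataclass
class SyntheticAnnotation:
    """Generated gene models plus the pair-level truth table."""

    genes: list[GeneModel]
    truth: pd.DataFrame  # one row per generated pair, incl. decoys

    @property
    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    @property
    def real_truth(self) -> pd.DataFrame:
        return self.truth[~self.truth["decoy"]].reset_index(drop=True)


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    strand: str,
    tss: int,
    span: int,
    biotype: str,
    n_extra_tx: int,
) -> GeneModel:
    """Build a gene whose transcripts-span is exactly ``span``.

    The primary transcript covers [0, span) in TSS-relative coordinates;
    extra transcripts start within the 2 kb qualification window and end
    inside the primary extent, so they never change the span.
    """
    direction = 1 if strand == "+" else -1

    def to_genomic(rel_iv: tuple[int, int]) -> tuple[int, int]:
        a, b = rel_iv
        if direction == 1:
            return (tss + a, tss + b)
        return (tss - b, tss - a)

    transcripts = []
    # primary transcript: 2-3 exons tiling [0, span)
    n_ex = int(rng.integers(2, 4))
    cuts = np.sort(rng.integers(200, span - 200, size=2 * (n_ex - 1)))
    rel_exons, pos = [], 0
    for i in range(n_ex - 1):
        rel_exons.append((pos, int(cuts[2 * i])))
        pos = int(cuts[2 * i + 1])
    rel_exons.append((pos, span))
    rel_exons = [(a, b) for a, b in rel_exons if b > a] or [(0, span)]
    if rel_exons[0][0] != 0:
        rel_exons[0] = (0, rel_exons[0][1])
    if rel_exons[-1][1] != span:
        rel_exons[-1] = (rel_exons[-1][0], span)
    transcripts.append(
        TranscriptModel(f"{gene_id}.t1", gene_id, chrom, strand,
                        sorted(to_genomic(iv) for iv in rel_exons))
    )
    for k in range(n_extra_tx):
        off = int(rng.integers(0, min(2000, span // 3)))
        end = int(rng.integers(off + 300, span + 1))
        transcripts.append(
            TranscriptModel(f"{gene_id}.t{k + 2}", gene_id, chrom, strand,
                            [to_genomic((off, end))])
        )
    return GeneModel(gene_id, chrom, strand, transcripts, biotype)


def generate_annotation(config: SimConfig) -> SyntheticAnnotation:
    """Lay out divergent pairs (plus decoys) on one chromosome.

    Pairs are spaced ``bp_spacing`` apart so that no unintended gene enters
    another pair's exclusion flank.  The truth table records the planted
    state, H-gene role, biotype category (L->H), TSS distance and spans.
    """
    rng = config.rng(0)
    genes: list[GeneModel] = []
    rows = []
    idx = 0
    margin = 50000

    def add_pair(state: str, decoy_reason: str | None) -> None:
        nonlocal idx
        arch = config.states[state]
        p = margin + idx * config.bp_spacing
        if decoy_reason == "tss_distance":
            d = 501
        else:
            lo, hi = config.tss_distance_range[state]
            d = int(rng.integers(lo, hi + 1))
        h_gene = "watson" if rng.random() < 0.5 else "crick"
        category = str(rng.choice(CATEGORIES, p=[config.biotype_mix[state][c] for c in CATEGORIES]))
        bt_l, bt_h = category.split("->")
        bt = {"PC": "protein_coding", "NC": "lincRNA"}
        roles = {"watson": "H" if h_gene == "watson" else "L",
                 "crick": "H" if h_gene == "crick" else "L"}
        spans, biotypes = {}, {}
        for side in ("watson", "crick"):
            rng_range = config.span_h_range if roles[side] == "H" else config.span_l_range
            lo, hi = rng_range[state]
            spans[side] = int(rng.integers(lo, hi + 1))
            biotypes[side] = bt[bt_h] if roles[side] == "H" else bt[bt_l]
        wid, cid = f"G{idx:04d}W", f"G{idx:04d}C"
        gw = _make_gene(rng, wid, config.chrom, "+", p + d, spans["watson"],
                        biotypes["watson"], int(rng.integers(0, 3)))
        gc = _make_gene(rng, cid, config.chrom, "-", p, spans["crick"],
                        biotypes["crick"], int(rng.integers(0, 3)))
        genes.extend([gw, gc])
        if decoy_reason == "third_gene":
            xid = f"G{idx:04d}X"
            genes.append(_make_gene(rng, xid, config.chrom, "+", p + d + 1500, 800,
                                    "protein_coding", 0))
        rows.append({
            "bp_id": f"BP_{wid}_{cid}",
            "state": state,
            "watson_gene": wid,
            "crick_gene": cid,
            "h_gene": h_gene,
            "tss_distance": d,
            "watson_span": spans["watson"],
            "crick_span": spans["crick"],
            "category": category,
            "mu_watson": arch.mu_H if h_gene == "watson" else arch.mu_L,
            "mu_crick": arch.mu_H if h_gene == "crick" else arch.mu_L,
            "decoy": decoy_reason is not None,
            "decoy_reason": decoy_reason or "",
        })
        idx += 1

    for state in config.state_names:
        for _ in range(config.n_bp_per_state):
            add_pair(state, None)
    for k in range(config.n_decoys):
        reason = ("tss_distance", "third_gene")[k % 2]
        add_pair(config.state_names[k % len(config.state_names)], reason)

    return SyntheticAnnotation(genes, pd.DataFrame(rows))


def generate_sc_expression(
    config: SimConfig, annotation: SyntheticAnnotation
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the isoform x cell TPM table and the per-gene expression truth.

    Per pair and cell: log2 expression of the planted L and H genes is
    normal around the archetype means with a shared factor of variance
    fraction ``cell_corr``; with probability ``flip_prob`` the two values
    swap within the cell; nonzero values are then zeroed with probability
    ``dropout_prob``.  Gene TPM is split among the gene's transcripts with
    fixed Dirichlet weights.
    """
    rng = config.rng(1)
    genes_by_id = annotation.genes_by_id
    cells = [f"cell_{c + 1:03d}" for c in range(config.n_cells)]
    gene_rows: dict[str, np.ndarray] = {}
    truth_rows = []
    for row in annotation.truth.itertuples():
        arch = config.states[row.state]
        if row.watson_gene not in genes_by_id or row.crick_gene not in genes_by_id:
            raise KeyError(f"unknown gene id in truth table for {row.bp_id}")
        n = config.n_cells
        z = rng.standard_normal(n)
        c = arch.cell_corr
        log_l = arch.mu_L + arch.sigma * (np.sqrt(c) * z + np.sqrt(1 - c) * rng.standard_normal(n))
        log_h = arch.mu_H + arch.sigma * (np.sqrt(c) * z + np.sqrt(1 - c) * rng.standard_normal(n))
        flip = rng.random(n) < arch.flip_prob
        l_val, h_val = np.exp2(log_l), np.exp2(log_h)
        l_val[flip], h_val[flip] = h_val[flip], l_val[flip].copy()
        l_val[rng.random(n) < arch.dropout_prob] = 0.0
        h_val[rng.random(n) < arch.dropout_prob] = 0.0
        by_role = {"H": h_val, "L": l_val}
        for side, gid in (("watson", row.watson_gene), ("crick", row.crick_gene)):
            role = "H" if row.h_gene == side else "L"
            gene_rows[gid] = by_role[role]
            truth_rows.append({
                "gene_id": gid,
                "bp_id": row.bp_id,
                "state": row.state,
                "role": role,
                "mu": arch.mu_H if role == "H" else arch.mu_L,
            })
    # split gene TPM among isoforms with fixed weights
    iso_index, iso_values = [], []
    for gid, vals in gene_rows.items():
        txs = genes_by_id[gid].transcripts
        w = rng.dirichlet(np.full(len(txs), 5.0)) if len(txs) > 1 else np.ones(1)
        for t, wt in zip(txs, w):
            iso_index.append(t.transcript_id)
            iso_values.append(vals * wt)
    iso = pd.DataFrame(np.array(iso_values), index=iso_index, columns=cells)
    iso.index.name = "transcript_id"
    return iso, pd.DataFrame(truth_rows)


def _gene_window(gene: GeneModel, length: int) -> tuple[int, int]:
    """[tss, tss+length) along the gene's direction, as genomic half-open."""
    tss = gene.anchor_tss
    if gene.strand == "+":
        return tss, tss + length
    return tss - length, tss


def generate_tracks(
    config: SimConfig, annotation: SyntheticAnnotation
) -> tuple[dict[str, Coverage], pd.DataFrame]:
    """Poisson coverage tracks and a state-dependent segmentation.

    Each gene deposits counts in 50 bp bins over 2 kb downstream of its TSS
    (plus the inter-TSS region) at the state's amplitude; the elongation
    mark H3K36me3 additionally covers up to 4 kb of gene body.  The
    segmentation tiles each gene's span window with label lengths exactly
    proportional to the state's configured composition; the rest of the
    chromosome is "Others".
    """
    rng = config.rng(2)
    genes_by_id = annotation.genes_by_id
    binsize = 50

    def bins(start: int, end: int, amp: float, out: list) -> None:
        for s in range(start, end, binsize):
            e = min(s + binsize, end)
            v = float(rng.poisson(amp * (e - s) / binsize))
            if v > 0:
                out.append((s, e, v))

    coverages: dict[str, Coverage] = {}
    track_list = list(dict.fromkeys(list(config.track_amplitudes)))
    for track in track_list:
        pieces: list[tuple[int, int, float]] = []
        for row in annotation.truth.itertuples():
            amp = config.track_amplitudes[track][row.state]
            gw = genes_by_id[row.watson_gene]
            gc = genes_by_id[row.crick_gene]
            for g in (gw, gc):
                body = 4000 if track == "H3K36me3" else 2000
                s, e = _gene_window(g, body)
                bins(s, e, amp, pieces)
            # inter-TSS region
            bins(gc.anchor_tss, gw.anchor_tss, amp, pieces)
        coverages[track] = Coverage.from_contributions({config.chrom: pieces})

    seg_rows: list[tuple[int, int, str]] = []
    for row in annotation.truth.itertuples():
        mix = config.segmentation_mix[row.state]
        for gid, span in ((row.watson_gene, row.watson_span), (row.crick_gene, row.crick_span)):
            g = genes_by_id[gid]
            w_start, w_end = _gene_window(g, span)
            labels = list(rng.permutation(SEG_LABELS))
            lengths = [int(round(mix[lab] * span)) for lab in labels]
            lengths[-1] = span - sum(lengths[:-1])
            pos = w_start
            for lab, ln in zip(labels, lengths):
                if ln > 0:
                    seg_rows.append((pos, pos + ln, lab))
                    pos += ln
    seg_rows.sort()
    # fill gaps with Others over the chromosome
    chrom_len = max(g.end for g in annotation.genes) + 50000
    filled, pos = [], 0
    for s, e, lab in seg_rows:
        if s > pos:
            filled.append((pos, s, "Others"))
        filled.append((s, e, lab))
        pos = e
    if pos < chrom_len:
        filled.append((pos, chrom_len, "Others"))
    seg = pd.DataFrame(filled, columns=["start", "end", "label"])
    seg.insert(0, "chrom", config.chrom)
    return coverages, seg


@dataclass
class StabilityDataset:
    """HM feature tracks plus expression with planted stability outliers."""

    coverages: dict[str, Coverage]
    expression: pd.DataFrame  # gene x cell TPM
    truth: pd.DataFrame  # gene_id, response, offset, is_outlier
    beta: np.ndarray
    intercept: float


def generate_stability_dataset(
    config: SimConfig, annotation: SyntheticAnnotation
) -> StabilityDataset:
    """Expression = planted linear combination of 12 HM flank features + noise.

    Coverage is piecewise constant over each gene's 2 kb up/downstream
    flanks; the realized feature matrix is extracted with the same routine
    the analysis uses (flank overlaps between the two genes of a pair add),
    so the planted linear model holds exactly for the realized features.
    A ``stability_outlier_frac`` of genes get a +/-delta response offset.
    """
    from .stability import build_features

    rng = config.rng(3)
    gene_ids = [gid for row in annotation.truth.itertuples()
                for gid in (row.watson_gene, row.crick_gene)
                if not row.decoy]
    genes = [annotation.genes_by_id[g] for g in gene_ids]
    coverages: dict[str, Coverage] = {}
    for track in config.stability_tracks:
        pieces = []
        for g in genes:
            for flank in ("up", "down"):
                level = float(np.exp2(max(0.0, rng.normal(2.0, 1.0))) - 1.0)
                tss, d = g.anchor_tss, g.direction
                if flank == "up":
                    s, e = (tss - 2000, tss) if d == 1 else (tss, tss + 2000)
                else:
                    s, e = (tss, tss + 2000) if d == 1 else (tss - 2000, tss)
                pieces.append((s, e, level))
        coverages[track] = Coverage.from_contributions({config.chrom: pieces})

    X = build_features(genes, coverages).to_numpy()
    beta = np.asarray(config.stability_beta, dtype=float)
    n = len(genes)
    noise = rng.normal(0.0, config.stability_noise_sd, size=n)
    offsets = np.zeros(n)
    n_out = int(round(config.stability_outlier_frac * n))
    if n_out:
        out_idx = rng.choice(n, size=n_out, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_out)
        offsets[out_idx] = signs * config.delta
    y = config.stability_intercept + X @ beta + noise + offsets
    y = np.maximum(y, 0.05)
    cells = [f"cell_{c + 1:03d}" for c in range(config.n_cells)]
    tpm = np.exp2(y) - 1.0
    expr = pd.DataFrame(np.tile(tpm[:, None], (1, len(cells))), index=gene_ids, columns=cells)
    expr.index.name = "gene_id"
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "response": y,
        "offset": offsets,
        "is_outlier": offsets != 0,
    })
    return StabilityDataset(coverages, expr, truth, beta, config.stability_intercept)


def simulate_to_dir(config: SimConfig, outdir) -> dict[str, str]:
    """Run every generator stage and write plain-text outputs to ``outdir``.

    Returns a name -> path map.  Outputs are byte-identical across runs
    with the same config (the determinism contract).
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)
    (outdir / "stability_tracks").mkdir(exist_ok=True)
    ann = generate_annotation(config)
    iso, gene_truth = generate_sc_expression(config, ann)
    coverages, seg = generate_tracks(config, ann)
    stab = generate_stability_dataset(config, ann)

    paths = {}
    paths["annotation"] = str(outdir / "annotation.gtf")
    write_gtf(ann.genes, paths["annotation"])
    paths["bp_truth"] = str(outdir / "bp_truth.tsv")
    ann.truth.to_csv(paths["bp_truth"], sep="\t", index=False)
    paths["isoform_tpm"] = str(outdir / "isoform_tpm.tsv")
    iso.round(6).to_csv(paths["isoform_tpm"], sep="\t")
    paths["gene_truth"] = str(outdir / "gene_truth.tsv")
    gene_truth.to_csv(paths["gene_truth"], sep="\t", index=False)
    for name, cov in coverages.items():
        p = outdir / "tracks" / f"{name}.bedGraph"
        cov.to_bedgraph(p)
        paths[f"track:{name}"] = str(p)
    paths["segmentation"] = str(outdir / "segmentation.bed")
    seg.to_csv(paths["segmentation"], sep="\t", index=False, header=False)
    for name, cov in stab.coverages.items():
        p = outdir / "stability_tracks" / f"{name}.bedGraph"
        cov.to_bedgraph(p)
        paths[f"stability_track:{name}"] = str(p)
    paths["stability_expression"] = str(outdir / "stability_expression.tsv")
    stab.expression.round(6).to_csv(paths["stability_expression"], sep="\t")
    paths["stability_truth"] = str(outdir / "stability_truth.tsv")
    stab.truth.round(6).to_csv(paths["stability_truth"], sep="\t", index=False)
    return paths


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a (YAML-loaded) plain dict; unknown keys error."""
    d = dict(d)
    if "states" in d:
        d["states"] = {k: StateArchetype(name=k, **v) for k, v in d["states"].items()}
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimConfig(**d)
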