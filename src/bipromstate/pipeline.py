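"""End-to-end orchestration: synthetic demo or user-supplied inputs.

Every stage is a pure function of its inputs and the run configuration;
``run_all`` wires them together, writes TSV outputs, and records a summary
JSON with parameters, input digests and headline numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import clustering, concordance, expression, signal, stability
from .genomic import Coverage
from .simulate import HM_TRACKS, TF_TRACKS, SimConfig, config_from_dict, simulate_to_dir

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All paths and parameters for one run; defaults are the standard
    analysis settings (TSS distance cap 500 bp, 2 kb windows, k = 4,
    pseudocount 1, alpha 0.05, 100 bp bins)."""

    annotation: str | None = None
    isoform_tpm: str | None = None
    imputed_tpm: str | None = None
    coverage_dir: str | None = None
    segmentation: str | None = None
    stability_coverage_dir: str | None = None
    stability_expression: str | None = None
    simulate: bool = False
    sim: SimConfig = field(default_factory=SimConfig)
    max_tss_distance: int = 500
    exclusion_flank: int = 2000
    window: int = 2000
    k: int = 4
    pseudocount: float = 1.0
    alpha: float = 0.05
    stability_threshold: float = 1.0
    strict_divergent: bool = False
    hm_tracks: tuple[str, ...] = HM_TRACKS
    tf_tracks: tuple[str, ...] = TF_TRACKS
    input_track: str = "Input"
    dnase_track: str = "DNaseI"
    collapse_map: dict[str, str] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw:
            raw["sim"] = config_from_dict(raw["sim"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(value, stage: str):
    if value is None:
        raise FileNotFoundError(f"stage '{stage}': required input missing")
    return value


def run_all(config: RunConfig, outdir) -> dict:
    """Run catalog -> scBP -> clustering -> concordance -> enrichment ->
    ChromScore -> stability; returns the summary dict (also written as
    summary.json in ``outdir``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config
    if cfg.simulate:
        logger.info("simulating synthetic inputs (seed=%d)", cfg.sim.seed)
        sim_dir = outdir / "sim"
        paths = simulate_to_dir(cfg.sim, sim_dir)
        cfg = dataclasses.replace(
            cfg,
            annotation=paths["annotation"],
            isoform_tpm=paths["isoform_tpm"],
            coverage_dir=str(sim_dir / "tracks"),
            segmentation=paths["segmentation"],
            stability_coverage_dir=str(sim_dir / "stability_tracks"),
            stability_expression=paths["stability_expression"],
        )

    summary: dict = {
        "bipromstate_version": version("bipromstate"),
        "seed": cfg.seed,
        "parameters": {
            "max_tss_distance": cfg.max_tss_distance,
            "exclusion_flank": cfg.exclusion_flank,
            "window": cfg.window,
            "k": cfg.k,
            "pseudocount": cfg.pseudocount,
            "alpha": cfg.alpha,
            "stability_threshold": cfg.stability_threshold,
        },
        "inputs": {},
    }
    for key in ("annotation", "isoform_tpm", "segmentation"):
        p = getattr(cfg, key)
        if p:
            summary["inputs"][key] = {"path": str(p), "sha256": _digest(p)}

    # --- catalog ---------------------------------------------------------
    logger.info("stage: catalog")
    genes = ann.parse_annotation(_require(cfg.annotation, "catalog"))
    bps = ann.find_bps(genes, cfg.max_tss_distance, cfg.exclusion_flank, cfg.strict_divergent)
    catalog = ann.catalog_table(bps, cfg.window)
    catalog.to_csv(outdir / "catalog.tsv", sep="\t", index=False)
    summary["n_genes"] = len(genes)
    summary["n_bps"] = len(bps)

    # --- scBP matrix ------------------------------------------------------
    logger.info("stage: matrix")
    iso = pd.read_csv(_require(cfg.isoform_tpm, "matrix"), sep="\t", index_col="transcript_id")
    gene_mat = expression.gene_expression(iso, genes, cfg.window)
    gene_mat, provenance = expression.impute_hook(gene_mat, cfg.imputed_tpm)
    summary["imputation"] = provenance
    scbp = expression.build_scbp(bps, gene_mat)
    scbp.to_tsv(outdir / "scbp.tsv")

    # --- clustering -------------------------------------------------------
    logger.info("stage: cluster")
    assignment = clustering.cluster_states(scbp, cfg.k, cfg.pseudocount)
    assignment.to_frame().to_csv(outdir / "assignment.tsv", sep="\t")
    pd.DataFrame(
        assignment.linkage, columns=["left", "right", "height", "size"]
    ).to_csv(outdir / "linkage.tsv", sep="\t", index=False)
    corr = clustering.correlation_table(scbp)
    corr.to_csv(outdir / "bp_correlation.tsv", sep="\t")
    states = assignment.to_frame()["state"]
    summary["state_counts"] = states.value_counts().to_dict()

    # --- concordance ------------------------------------------------------
    logger.info("stage: concordance")
    calls = concordance.call_concordance(scbp, cfg.alpha)
    calls.to_csv(outdir / "concordance.tsv", sep="\t")
    ratios = concordance.concordant_ratio(calls, assignment)
    ratios.to_csv(outdir / "concordant_ratio.tsv", sep="\t")
    summary["concordant_ratio"] = ratios.round(4).to_dict()

    gene_class = {g.gene_id: g.biotype_class for g in genes}
    categories = pd.Series(
        {
            bp_id: f"{gene_class[l]}->{gene_class[h]}"
            for bp_id, l, h in zip(scbp.bp_ids, scbp.l_gene_ids, scbp.h_gene_ids)
        },
        name="category",
    )
    gp = concordance.gene_product_enrichment(assignment, categories, cfg.alpha)
    gp.counts.to_csv(outdir / "gene_product_counts.tsv", sep="\t")
    gp.pvalues.to_csv(outdir / "gene_product_pvalues.tsv", sep="\t")

    # --- TF enrichment and HM profiles -----------------------------------
    h_gene_of = {
        bp_id: ("watson" if h == bp.gene_watson.gene_id else "crick")
        for bp_id, h, bp in zip(scbp.bp_ids, scbp.h_gene_ids, bps)
    }
    if cfg.coverage_dir:
        logger.info("stage: enrich")
        covdir = Path(cfg.coverage_dir)

        def load(track: str) -> Coverage:
            p = covdir / f"{track}.bedGraph"
            if not p.exists():
                raise FileNotFoundError(f"stage 'enrich': missing coverage track {p}")
            return Coverage.from_bedgraph(p)

        tf_covs = {t: load(t) for t in cfg.tf_tracks}
        scores = signal.enrichment_table(tf_covs, bps, h_gene_of)
        scores.to_csv(outdir / "tf_enrichment.tsv", sep="\t")
        pct = signal.percent_positive_tfs(scores)
        pct.rename("percent_positive").to_csv(outdir / "percent_positive_tfs.tsv", sep="\t")
        summary["mean_percent_positive_tfs"] = (
            pct.groupby(states.reindex(pct.index)).mean().round(2).to_dict()
        )

        input_cov = load(cfg.input_track)
        medians = {}
        for track in (*cfg.hm_tracks, cfg.dnase_track):
            prof = signal.profile_matrix(load(track), input_cov, bps, h_gene_of)
            medians[track] = signal.median_profiles(prof, states)
            np.log2(prof).round(4).to_csv(outdir / f"profile_{track}.tsv", sep="\t")
        med = pd.concat(medians, names=["track", "state"])
        med.round(4).to_csv(outdir / "median_profiles.tsv", sep="\t")

    # --- ChromScore -------------------------------------------------------
    if cfg.segmentation:
        logger.info("stage: chromscore")
        seg = pd.read_csv(
            cfg.segmentation, sep="\t", header=None,
            names=["chrom", "start", "end", "label"], dtype={"chrom": str},
        )
        bp_genes = [g for bp in bps for g in (bp.gene_watson, bp.gene_crick)]
        cs = signal.chromscore_table(bp_genes, seg, cfg.collapse_map, cfg.window)
        cs.round(6).to_csv(outdir / "chromscore.tsv", sep="\t")
        gene_states = pd.Series(
            {g.gene_id: states.loc[bp.bp_id] for bp in bps
             for g in (bp.gene_watson, bp.gene_crick)}
        )
        pct_cs = signal.chromscore_state_percent(cs, gene_states)
        pct_cs.round(3).to_csv(outdir / "chromscore_percent.tsv", sep="\t")
        summary["chromscore_percent"] = {
            s: row.round(2).to_dict() for s, row in pct_cs.iterrows()
        }

    # --- stability --------------------------------------------------------
    if cfg.stability_coverage_dir and cfg.stability_expression:
        logger.info("stage: stability")
        sdir = Path(cfg.stability_coverage_dir)
        hm_covs = {
            p.stem: Coverage.from_bedgraph(p) for p in sorted(sdir.glob("*.bedGraph"))
        }
        expr = pd.read_csv(cfg.stability_expression, sep="\t", index_col="gene_id")
        gene_index = {g.gene_id: g for g in genes}
        model_genes = [gene_index[g] for g in expr.index if g in gene_index]
        feats = stability.build_features(model_genes, hm_covs, cfg.window)
        response = stability.mean_expression_response(expr.loc[feats.index])
        model, stab_calls = stability.fit_stability(feats, response, cfg.stability_threshold)
        feats.round(6).to_csv(outdir / "stability_features.tsv", sep="\t")
        stab_calls.round(6).to_csv(outdir / "stability_calls.tsv", sep="\t")
        pd.Series(
            np.r_[model.intercept_, model.coef_],
            index=["intercept", *feats.columns],
            name="coefficient",
        ).round(6).to_csv(outdir / "stability_coefficients.tsv", sep="\t")
        gene_states = pd.Series(
            {g.gene_id: states.loc[bp.bp_id] for bp in bps
             for g in (bp.gene_watson, bp.gene_crick)}
        )
        in_catalog = stab_calls.index.intersection(gene_states.index)
        if len(in_catalog):
            enr = stability.stability_enrichment(
                stab_calls.loc[in_catalog], gene_states, cfg.alpha
            )
            enr.to_csv(outdir / "stability_enrichment.tsv", sep="\t")
            summary["stability_category_counts"] = (
                stab_calls.loc[in_catalog, "category"].value_counts().to_dict()
            )

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("run complete: %s", outdir)
    return summary
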