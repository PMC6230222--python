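import dataclasses
import filecmp

import numpy as np
import pandas as pd
import pytest

from bipromstate.expression import gene_expression
from bipromstate.simulate import (
    SimConfig,
    StateArchetype,
    default_archetypes,
    generate_annotation,
    generate_sc_expression,
    generate_stability_dataset,
    generate_tracks,
    simulate_to_dir,
)


def quiet_states(**overrides):
    """Default archetypes with noise switched off where requested."""
    states = default_archetypes()
    return {
        name: dataclasses.replace(arch, **overrides) for name, arch in states.items()
    }


class TestArchetypeValidation:
    def test_mu_ordering_enforced(self):
        with pytest.raises(ValueError):
            StateArchetype("X", mu_L=5, mu_H=2, sigma=1, flip_prob=0, dropout_prob=0)

    def test_flip_prob_bounded(self):
        with pytest.raises(ValueError):
            StateArchetype("X", 1, 2, 1, flip_prob=0.6, dropout_prob=0)

    def test_config_rejects_bad_mix(self):
        mix = SimConfig().biotype_mix
        mix["BLE"]["PC->PC"] = 0.9
        with pytest.raises(ValueError):
            SimConfig(biotype_mix=mix)


class TestDeterminism:
    def test_full_output_byte_identical_under_fixed_seed(self, tmp_path):
        cfg = SimConfig(n_bp_per_state=3, n_cells=6, seed=11)
        p1 = simulate_to_dir(cfg, tmp_path / "run1")
        p2 = simulate_to_dir(cfg, tmp_path / "run2")
        assert p1.keys() == p2.keys()
        for name in p1:
            assert filecmp.cmp(p1[name], p2[name], shallow=False), name

    def test_different_seed_changes_expression(self, tmp_path):
        a = generate_annotation(SimConfig(n_bp_per_state=2, n_cells=5, seed=1))
        iso1, _ = generate_sc_expression(SimConfig(n_bp_per_state=2, n_cells=5, seed=1), a)
        a2 = generate_annotation(SimConfig(n_bp_per_state=2, n_cells=5, seed=2))
        iso2, _ = generate_sc_expression(SimConfig(n_bp_per_state=2, n_cells=5, seed=2), a2)
        assert not np.allclose(iso1.to_numpy(), iso2.to_numpy())


class TestAnnotationGeneration:
    def test_minimal_config_yields_four_pairs(self):
        annx = generate_annotation(SimConfig(n_bp_per_state=1, n_decoys=0, seed=3))
        assert len(annx.truth) == 4
        assert len(annx.genes) == 8
        assert not annx.truth.decoy.any()

    def test_decoy_pairs_marked_with_reason(self, small_annotation):
        decoys = small_annotation.truth[small_annotation.truth.decoy]
        assert set(decoys.decoy_reason) == {"tss_distance", "third_gene"}
        far = decoys[decoys.decoy_reason == "tss_distance"]
        assert (far.tss_distance == 501).all()

    def test_tss_distances_within_configured_ranges(self, small_config, small_annotation):
        for row in small_annotation.real_truth.itertuples():
            lo, hi = small_config.tss_distance_range[row.state]
            assert lo <= row.tss_distance <= hi

    def test_planted_spans_match_gene_models(self, small_annotation):
        from bipromstate.annotation import transcripts_span_length

        by_id = small_annotation.genes_by_id
        for row in small_annotation.real_truth.head(20).itertuples():
            assert transcripts_span_length(by_id[row.watson_gene]) == row.watson_span
            assert transcripts_span_length(by_id[row.crick_gene]) == row.crick_span


class TestExpressionGeneration:
    def test_degenerate_noise_reproduces_archetype_means_exactly(self):
        cfg = SimConfig(n_bp_per_state=2, n_cells=4, seed=5, n_decoys=0,
                        states=quiet_states(sigma=0.0, flip_prob=0.0, dropout_prob=0.0))
        annx = generate_annotation(cfg)
        iso, truth = generate_sc_expression(cfg, annx)
        gene_mat = gene_expression(iso, annx.genes)
        for row in truth.itertuples():
            np.testing.assert_allclose(
                gene_mat.loc[row.gene_id].to_numpy(), 2.0 ** row.mu, rtol=1e-9)

    def test_bsd_without_flips_keeps_h_above_l_in_every_cell(self):
        cfg = SimConfig(n_bp_per_state=5, n_cells=30, seed=5, n_decoys=0,
                        states={"BSD": default_archetypes()["BSD"]},
                        )
        annx = generate_annotation(cfg)
        iso, truth = generate_sc_expression(cfg, annx)
        gene_mat = gene_expression(iso, annx.genes)
        for bp_id, sub in truth.groupby("bp_id"):
            h = gene_mat.loc[sub.loc[sub.role == "H", "gene_id"].iloc[0]]
            l = gene_mat.loc[sub.loc[sub.role == "L", "gene_id"].iloc[0]]
            nz = (h > 0) & (l > 0)  # dropout may zero either side
            assert (h[nz] > l[nz]).all()

    def test_empirical_means_match_planted_within_sampling_error(self):
        cfg = SimConfig(n_bp_per_state=25, n_cells=50, seed=9, n_decoys=0,
                        states=quiet_states(dropout_prob=0.0, flip_prob=0.0))
        annx = generate_annotation(cfg)
        iso, truth = generate_sc_expression(cfg, annx)
        gene_mat = gene_expression(iso, annx.genes)
        log_mat = np.log2(gene_mat)
        for (state, role), sub in truth.groupby(["state", "role"]):
            arch = cfg.states[state]
            mu = arch.mu_H if role == "H" else arch.mu_L
            vals = log_mat.loc[sub.gene_id].to_numpy()
            tol = 3 * arch.sigma / np.sqrt(vals.size)
            assert abs(vals.mean() - mu) < tol, (state, role)

    def test_unknown_gene_in_truth_raises(self, small_config, small_annotation):
        broken = dataclasses.replace(
            small_annotation, truth=small_annotation.truth.assign(watson_gene="nope"))
        with pytest.raises(KeyError):
            generate_sc_expression(small_config, broken)


class TestTrackGeneration:
    def test_planted_repressive_amplitude_ordering(self, small_config, small_annotation):
        covs, _ = generate_tracks(small_config, small_annotation)
        by_id = small_annotation.genes_by_id

        def mean_promoter_cov(track, state):
            vals = []
            for row in small_annotation.real_truth.itertuples():
                if row.state != state:
                    continue
                g = by_id[row.watson_gene]
                vals.append(covs[track].interval_mean(g.chrom, g.anchor_tss, g.anchor_tss + 2000))
            return np.mean(vals)

        assert mean_promoter_cov("H3K27me3", "BLE") > mean_promoter_cov("H3K27me3", "BND")
        assert mean_promoter_cov("H3K4me3", "BND") > mean_promoter_cov("H3K4me3", "BLE")

    def test_zero_amplitude_track_is_empty(self, small_annotation):
        cfg = SimConfig(n_bp_per_state=12, n_cells=20, seed=7)
        cfg.track_amplitudes["GABPA"] = {s: 0 for s in cfg.track_amplitudes["GABPA"]}
        covs, _ = generate_tracks(cfg, small_annotation)
        assert covs["GABPA"].total() == 0.0

    def test_segmentation_tiles_contiguously_with_planted_composition(
            self, small_config, small_annotation):
        _, seg = generate_tracks(small_config, small_annotation)
        assert (seg["start"].iloc[1:].to_numpy() == seg["end"].iloc[:-1].to_numpy()).all()
        assert seg["start"].iloc[0] == 0
        # composition over one gene's window ~ configured mix
        row = small_annotation.real_truth.iloc[0]
        g = small_annotation.genes_by_id[row.watson_gene]
        lo = min(g.anchor_tss, g.anchor_tss + g.direction * row.watson_span)
        hi = max(g.anchor_tss, g.anchor_tss + g.direction * row.watson_span)
        sub = seg[(seg.end > lo) & (seg.start < hi)]
        got = {}
        for r in sub.itertuples():
            got[r.label] = got.get(r.label, 0) + min(r.end, hi) - max(r.start, lo)
        mix = small_config.segmentation_mix[row.state]
        for label, frac in mix.items():
            assert got.get(label, 0) / row.watson_span == pytest.approx(frac, abs=0.01)


class TestStabilityGeneration:
    def test_null_noise_free_dataset_has_exact_linear_response(self, small_annotation):
        cfg = SimConfig(n_bp_per_state=12, n_cells=5, seed=7,
                        stability_noise_sd=0.0, stability_outlier_frac=0.0)
        ds = generate_stability_dataset(cfg, small_annotation)
        from bipromstate.stability import build_features, mean_expression_response

        genes = [small_annotation.genes_by_id[g] for g in ds.truth.gene_id]
        X = build_features(genes, ds.coverages).to_numpy()
        y = mean_expression_response(ds.expression).to_numpy()
        np.testing.assert_allclose(y, cfg.stability_intercept + X @ ds.beta, atol=1e-6)

    def test_outlier_fraction_and_signs(self, small_annotation):
        cfg = SimConfig(n_bp_per_state=12, n_cells=5, seed=7, stability_outlier_frac=0.1)
        ds = generate_stability_dataset(cfg, small_annotation)
        n = len(ds.truth)
        assert ds.truth.is_outlier.sum() == round(0.1 * n)
        assert set(np.sign(ds.truth.loc[ds.truth.is_outlier, "offset"])) <= {-1.0, 1.0}
        assert (ds.truth.loc[ds.truth.is_outlier, "offset"].abs() == cfg.delta).all()
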