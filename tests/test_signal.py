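import numpy as np
import pandas as pd
import pytest

from bipromstate.annotation import BidirectionalPromoter, find_bps
from bipromstate.genomic import Coverage
from bipromstate.signal import (
    DEFAULT_COLLAPSE_MAP,
    bin_all_bps,
    bin_bp,
    chromscore,
    chromscore_state_percent,
    chromscore_table,
    downstream_bins,
    enrichment_table,
    median_profiles,
    percent_positive_tfs,
    profile_matrix,
    tf_enrichment,
)
from conftest import make_gene
from oracles import per_base_chromscore


def make_bp(tss_distance=300, crick_tss=50000):
    crick = make_gene("c", "-", [[(crick_tss - 10000, crick_tss)]])
    watson = make_gene("w", "+", [[(crick_tss + tss_distance,
                                    crick_tss + tss_distance + 10000)]])
    return BidirectionalPromoter("bp", watson, crick)


def uniform_cov(value, start=0, end=200000):
    return Coverage.from_contributions({"chr1": [(start, end, value)]})


class TestBinning:
    def test_vector_has_41_entries_with_middle_width_tss_distance(self):
        bp = make_bp(tss_distance=137)
        v = bin_bp(uniform_cov(1.0), bp, "watson")
        assert len(v) == 41
        assert v[20] == 137  # middle bin integrates 1.0 over the inter-TSS gap

    def test_uniform_field_gives_constant_gene_bins(self):
        bp = make_bp(tss_distance=250)
        v = bin_bp(uniform_cov(2.5), bp, "crick")
        np.testing.assert_allclose(v[:20], 250.0)
        np.testing.assert_allclose(v[21:], 250.0)
        assert v[20] == pytest.approx(250 * 2.5)

    def test_zero_coverage_gives_zero_vector(self):
        bp = make_bp()
        np.testing.assert_array_equal(bin_bp(Coverage({}), bp, "watson"), np.zeros(41))

    def test_spike_downstream_of_h_tss_lands_in_correct_h_bin(self):
        bp = make_bp(tss_distance=300)
        h_tss = bp.gene_watson.anchor_tss
        # unit spike covering bases 250-260 downstream of the H TSS:
        # inside the third 100-bp bin (offsets 200-300)
        cov = Coverage.from_contributions({"chr1": [(h_tss + 250, h_tss + 260, 1.0)]})
        v = bin_bp(cov, bp, "watson")
        assert v[21 + 2] == pytest.approx(10.0)
        assert v.sum() == pytest.approx(10.0)

    def test_l_half_reads_distal_to_tss(self):
        bp = make_bp(tss_distance=300, crick_tss=50000)
        # spike just downstream of the L (crick) TSS -> last L bin (index 19)
        cov = Coverage.from_contributions({"chr1": [(50000 - 50, 50000 - 40, 1.0)]})
        v = bin_bp(cov, bp, "watson")
        assert v[19] == pytest.approx(10.0)
        # spike 1950-1960 downstream of the crick TSS -> first vector entry
        cov2 = Coverage.from_contributions({"chr1": [(50000 - 1960, 50000 - 1950, 1.0)]})
        assert bin_bp(cov2, bp, "watson")[0] == pytest.approx(10.0)

    def test_zero_tss_distance_gives_empty_middle_bin(self):
        bp = make_bp(tss_distance=0)
        v = bin_bp(uniform_cov(1.0), bp, "watson")
        assert v[20] == 0.0

    def test_total_conserves_coverage_over_locus(self):
        bp = make_bp(tss_distance=300)
        rng = np.random.default_rng(0)
        pieces = [(int(s), int(s) + 50, float(v))
                  for s, v in zip(rng.integers(48000, 52000, 60), rng.random(60) * 5)]
        cov = Coverage.from_contributions({"chr1": pieces})
        v = bin_bp(cov, bp, "watson")
        lo = bp.gene_crick.anchor_tss - 2000
        hi = bp.gene_watson.anchor_tss + 2000
        assert v.sum() == pytest.approx(cov.interval_sum("chr1", lo, hi))


class TestEnrichment:
    def test_identical_vectors_score_zero(self):
        binned = np.tile(np.arange(41.0), (5, 1))
        np.testing.assert_allclose(tf_enrichment(binned), 0.0)

    def test_three_bp_direct_formula(self):
        binned = np.vstack([np.full(41, 0.0), np.full(41, 1.0), np.full(41, 3.0)])
        np.testing.assert_allclose(tf_enrichment(binned), [-41.0, 0.0, 41.0])

    def test_single_bin_change_only_affects_that_bp_with_odd_count(self):
        rng = np.random.default_rng(1)
        binned = rng.random((5, 41))
        binned[2, 7] = binned[:, 7].max() + 1.0  # already above the median
        bumped = binned.copy()
        bumped[2, 7] += 10.0  # moves further up: the median is unchanged
        s0, s1 = tf_enrichment(binned), tf_enrichment(bumped)
        assert s1[2] > s0[2]
        np.testing.assert_allclose(np.delete(s1, 2), np.delete(s0, 2))

    def test_score_additive_and_increasing_per_bin(self):
        rng = np.random.default_rng(2)
        binned = rng.integers(0, 20, (7, 41)).astype(float)
        bg = np.median(binned, axis=0)
        manual = sum(np.log2((binned[:, j] + 1) / (bg[j] + 1)) for j in range(41))
        np.testing.assert_allclose(tf_enrichment(binned), manual)

    def test_percent_positive(self):
        scores = pd.DataFrame({"tf1": [1.0, -1.0], "tf2": [2.0, -0.5],
                               "tf3": [-0.1, -2.0], "tf4": [0.5, 0.0]})
        np.testing.assert_allclose(percent_positive_tfs(scores), [75.0, 0.0])

    def test_synthetic_bnd_has_highest_percent_positive(self, small_config,
                                                        small_annotation):
        from bipromstate.simulate import TF_TRACKS, generate_tracks

        covs, _ = generate_tracks(small_config, small_annotation)
        bps = find_bps(small_annotation.genes)
        truth = small_annotation.real_truth.set_index("bp_id")
        h_of = truth["h_gene"].to_dict()
        scores = enrichment_table({t: covs[t] for t in TF_TRACKS}, bps, h_of)
        pct = percent_positive_tfs(scores)
        means = pct.groupby(truth["state"].reindex(pct.index)).mean()
        assert means.idxmax() == "BND"


class TestProfiles:
    def test_chip_equal_input_gives_unit_ratio(self):
        bp = make_bp()
        cov = uniform_cov(2.0)
        prof = profile_matrix(cov, cov, [bp], {"bp": "watson"})
        np.testing.assert_allclose(prof.to_numpy(), 1.0)

    def test_zero_input_falls_back_to_pseudocount(self):
        bp = make_bp(tss_distance=100)
        chip = uniform_cov(3.0)
        prof = profile_matrix(chip, Coverage({}), [bp], {"bp": "watson"},
                              depth_normalize=False)
        np.testing.assert_allclose(prof.to_numpy()[0, :20], 301.0)

    def test_median_profiles_by_state(self):
        profs = pd.DataFrame(np.arange(8.0).reshape(4, 2),
                             index=pd.Index(list("abcd"), name="bp_id"))
        states = pd.Series(["BLE", "BLE", "BND", "BND"], index=list("abcd"))
        med = median_profiles(profs, states)
        np.testing.assert_allclose(med.loc["BLE"], [1.0, 2.0])

    def test_synthetic_active_mark_higher_in_bnd_than_ble(self, small_config,
                                                          small_annotation):
        from bipromstate.simulate import generate_tracks

        covs, _ = generate_tracks(small_config, small_annotation)
        bps = find_bps(small_annotation.genes)
        truth = small_annotation.real_truth.set_index("bp_id")
        prof = profile_matrix(covs["H3K4me3"], covs["Input"], bps,
                              truth["h_gene"].to_dict())
        med = median_profiles(prof, truth["state"])
        assert med.loc["BND"].median() > med.loc["BLE"].median()


class TestChromScore:
    def _seg(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])

    def test_single_label_window(self):
        g = make_gene("g", "+", [[(1000, 4000)]])
        seg = self._seg([("chr1", 0, 10000, "Enhancer")])
        cs = chromscore(g, seg)
        assert cs.tolist() == [0.0, 1.0, 0.0, 0.0]

    def test_repressed_only_segmentation(self):
        g = make_gene("g", "+", [[(1000, 4000)]])
        seg = self._seg([("chr1", 0, 10000, "Repressed")])
        assert chromscore(g, seg).tolist() == [0.0, 0.0, 1.0, 0.0]

    def test_half_tss_half_repressed(self):
        g = make_gene("g", "+", [[(1000, 3000)]])
        seg = self._seg([("chr1", 0, 2000, "TSS"), ("chr1", 2000, 9000, "Repressed")])
        assert chromscore(g, seg).tolist() == [0.5, 0.0, 0.5, 0.0]

    def test_minus_strand_window_extends_upstream_in_genomic_terms(self):
        g = make_gene("g", "-", [[(7000, 10000)]])  # TSS at 10000, span 3000
        seg = self._seg([("chr1", 0, 8500, "TSS"), ("chr1", 8500, 12000, "Enhancer")])
        cs = chromscore(g, seg)
        assert cs["TSS"] == pytest.approx(1500 / 3000)
        assert cs["Enhancer"] == pytest.approx(1500 / 3000)

    def test_gap_counts_as_others_with_warning(self):
        g = make_gene("g", "+", [[(1000, 3000)]])
        seg = self._seg([("chr1", 1000, 2000, "TSS")])
        with pytest.warns(UserWarning, match="gap"):
            cs = chromscore(g, seg)
        assert cs.tolist() == [0.5, 0.0, 0.0, 0.5]

    def test_18_state_labels_collapse(self):
        g = make_gene("g", "+", [[(1000, 2000)]])
        seg = self._seg([("chr1", 1000, 1300, "TssA"), ("chr1", 1300, 1600, "EnhA1"),
                         ("chr1", 1600, 1800, "ReprPCWk"), ("chr1", 1800, 2100, "Quies")])
        cs = chromscore(g, seg)
        assert cs.tolist() == [0.3, 0.3, 0.2, 0.2]

    def test_unknown_label_raises(self):
        g = make_gene("g", "+", [[(1000, 2000)]])
        seg = self._seg([("chr1", 0, 5000, "Wat")])
        with pytest.raises(KeyError):
            chromscore(g, seg)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_random_segmentation_matches_per_base_oracle(self, strand):
        rng = np.random.default_rng(11)
        for _ in range(5):
            span = int(rng.integers(500, 3000))
            exons = [(5000, 5000 + span)] if strand == "+" else [(5000 - span, 5000)]
            g = make_gene("g", strand, [exons])
            cuts = np.sort(rng.integers(0, 12000, 6))
            edges = [0, *cuts.tolist(), 12000]
            labels = rng.choice(["TssA", "EnhG1", "Het", "Quies", "Tx"], len(edges) - 1)
            rows = [("chr1", s, e, lab) for s, e, lab in zip(edges[:-1], edges[1:], labels)
                    if e > s]
            cs = chromscore(g, pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))
            w = (5000, 5000 + span) if strand == "+" else (5000 - span, 5000)
            expected = per_base_chromscore([(s, e, lab) for _, s, e, lab in rows],
                                           *w, DEFAULT_COLLAPSE_MAP)
            for state in cs.index:
                assert cs[state] == pytest.approx(expected[state], abs=1e-12)
            assert cs.sum() == pytest.approx(1.0)

    def test_state_percentages_sum_to_100(self, small_config, small_annotation):
        from bipromstate.simulate import generate_tracks

        _, seg = generate_tracks(small_config, small_annotation)
        truth = small_annotation.real_truth
        genes = [small_annotation.genes_by_id[g]
                 for row in truth.head(20).itertuples()
                 for g in (row.watson_gene, row.crick_gene)]
        scores = chromscore_table(genes, seg)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0)
        gene_states = pd.Series(
            {g: row.state for row in truth.head(20).itertuples()
             for g in (row.watson_gene, row.crick_gene)})
        pct = chromscore_state_percent(scores, gene_states)
        np.testing.assert_allclose(pct.sum(axis=1), 100.0)
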