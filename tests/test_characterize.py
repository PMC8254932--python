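"""Aggregate heatmaps, CTCF convergence, coverage, expression and
subcompartment overlap — exact identities and oracle checks."""

import numpy as np
import pandas as pd
import pytest

from tadclique import characterize, cliques, genomic_io
from tadclique import simulate as sim
from tadclique.core import BinnedContactMap, GenomicInterval, TadPairTest, TadSegment, TadSegmentation

from conftest import random_map


def motif_df(rows):
    return pd.DataFrame(rows, columns=genomic_io.BED_COLUMNS)


@pytest.fixture(scope="module")
def truth_run():
    """Truth segmentation with the planted graph treated as significant:
    isolates the characterization operations from the caller. Six cliques
    (sizes 3..8) give enough clique TADs for the enrichment contrasts."""
    cfg = sim.SimulationConfig(seed=17, planted_cliques=[
        sim.PlantedClique(s, 8.0) for s in range(3, 9)])
    cmap, truth = sim.simulate_contact_map(cfg)
    planted_pairs = [
        TadPairTest(tad_a=a, tad_b=b, distance_bp=1, observed=1, n_a=1,
                    n_b=1, total_n=1, expected=0.1, odds=1.0, p_value=0.0,
                    significant=True)
        for a, b in (sorted(e) for e in truth.clique_edges)
    ]
    graph = cliques.build_tad_graph(
        planted_pairs,
        nodes=[s.id for s in truth.segmentation.called_domains()])
    stats = cliques.assign_clique_stats(graph)
    return cmap, truth, stats


class TestHeatmap:
    def test_constant_matrix_resizes_to_constant(self):
        assert np.all(characterize.resize_nearest(np.full((7, 7), 3.5)) == 3.5)

    def test_25_bin_source_is_identity(self):
        rng = np.random.default_rng(0)
        m = rng.random((25, 25))
        assert np.array_equal(characterize.resize_nearest(m), m)

    def test_aggregate_is_mean_of_resized_matrices(self):
        rng = np.random.default_rng(1)
        cmap = random_map(rng, 30, resolution=1000)
        tads = [
            TadSegment(GenomicInterval("chrT", 0, 10_000), "A"),
            TadSegment(GenomicInterval("chrT", 10_000, 24_000), "B"),
        ]
        hm = characterize.aggregate_intra_tad_heatmap(cmap, tads)
        want = (characterize.resize_nearest(characterize.intra_tad_matrix(cmap, tads[0]))
                + characterize.resize_nearest(characterize.intra_tad_matrix(cmap, tads[1]))) / 2
        assert np.array_equal(hm.matrix, want)
        assert hm.n_tads == 2

    def test_empty_category_rejected(self):
        cmap = random_map(np.random.default_rng(0), 5)
        with pytest.raises(ValueError, match="no TADs"):
            characterize.aggregate_intra_tad_heatmap(cmap, [], "clique_3")


class TestConvergence:
    tad = TadSegment(GenomicInterval("chr1", 100_000, 400_000), "T1")

    def test_plus_at_start_minus_at_end_is_convergent(self):
        motifs = motif_df([("chr1", 99_990, 100_010, "m", 5.0, "+"),
                           ("chr1", 399_990, 400_010, "m", 5.0, "-")])
        assert characterize.tad_is_convergent(self.tad, motifs, 10_000)

    def test_divergent_orientation_is_not_convergent(self):
        motifs = motif_df([("chr1", 99_990, 100_010, "m", 5.0, "-"),
                           ("chr1", 399_990, 400_010, "m", 5.0, "+")])
        assert not characterize.tad_is_convergent(self.tad, motifs, 10_000)

    def test_no_motifs_near_boundaries_is_not_convergent(self):
        motifs = motif_df([("chr1", 250_000, 250_020, "m", 5.0, "+")])
        assert not characterize.tad_is_convergent(self.tad, motifs, 10_000)

    def test_highest_score_motif_decides_boundary(self):
        motifs = motif_df([
            ("chr1", 100_500, 100_520, "weak", 1.0, "-"),
            ("chr1", 101_000, 101_020, "strong", 9.0, "+"),
            ("chr1", 399_990, 400_010, "m", 5.0, "-")])
        assert characterize.tad_is_convergent(self.tad, motifs, 10_000)
        motifs.loc[0, "score"] = 99.0  # now the '-' motif wins the 5' boundary
        assert not characterize.tad_is_convergent(self.tad, motifs, 10_000)

    def test_binomial_two_sided_closed_forms(self):
        assert characterize.binomial_two_sided(0, 20, 0.5) == \
            pytest.approx(2 * 0.5 ** 20)
        assert characterize.binomial_two_sided(10, 20, 0.5) == 1.0

    def test_clique_categories_depleted_on_synthetic_fixture(self, truth_run):
        cmap, truth, stats = truth_run
        motifs = sim.simulate_ctcf_motifs(
            truth, p_convergent_nonclique=0.6, p_convergent_clique=0.1, seed=3)
        summary = characterize.convergence_enrichment(
            truth.segmentation, stats, motifs, window_bp=50_000)
        clique_cats = [c for c in summary.index if c.startswith("clique")]
        for cat in clique_cats:
            assert summary.loc[cat, "percent"] < summary.loc[cat, "p0_percent"]
        # pooled over all clique TADs the depletion is significant
        n = int(summary.loc[clique_cats, "n_tads"].sum())
        x = int(summary.loc[clique_cats, "n_convergent"].sum())
        p0 = summary["p0_percent"].iloc[0] / 100
        assert characterize.binomial_two_sided(x, n, p0) < 0.05

    def test_category_weighted_percentages_average_to_p0(self, truth_run):
        cmap, truth, stats = truth_run
        motifs = sim.simulate_ctcf_motifs(truth, seed=5)
        summary = characterize.convergence_enrichment(
            truth.segmentation, stats, motifs)
        weighted = (summary["percent"] * summary["n_tads"]).sum() \
            / summary["n_tads"].sum()
        assert weighted == pytest.approx(summary["p0_percent"].iloc[0], abs=1e-9)


def bitmap_coverage(tad, annotation_rows):
    bits = np.zeros(tad.interval.length, dtype=bool)
    for _, s, e in annotation_rows:
        lo = max(s, tad.interval.start) - tad.interval.start
        hi = min(e, tad.interval.end) - tad.interval.start
        if hi > lo:
            bits[lo:hi] = True
    return bits.mean()


class TestCoverage:
    def test_full_cover_is_one(self):
        tad = TadSegment(GenomicInterval("chr1", 100, 200), "T")
        ann = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500]})
        assert characterize.interval_coverage([tad], ann)["T"] == 1.0

    def test_overlapping_annotation_counted_once(self):
        tad = TadSegment(GenomicInterval("chr1", 0, 100), "T")
        ann = pd.DataFrame({"chrom": ["chr1", "chr1"],
                            "start": [10, 30], "end": [50, 60]})
        assert characterize.interval_coverage([tad], ann)["T"] == \
            pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bitmap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tad = TadSegment(GenomicInterval("chr1", 0, 1_000_000), "T")
        rows = [("chr1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 990_000, 40),
                                rng.integers(1, 50_000, 40))]
        ann = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        got = characterize.interval_coverage([tad], ann)["T"]
        assert got == pytest.approx(bitmap_coverage(tad, rows), abs=1e-12)

    def test_line_enrichment_direction_reproduced(self):
        """Planted LINE enrichment in clique TADs shows up in the
        measured coverage in at least 9 of 10 seeds."""
        wins = 0
        for seed in range(10):
            cfg = sim.SimulationConfig(chrom_length_bp=15_000_000, seed=40 + seed,
                                       planted_cliques=[sim.PlantedClique(3, 8.0)])
            _, truth = sim.simulate_contact_map(cfg)
            repeats, _, _ = sim.simulate_annotations(truth, seed=seed)
            cov = characterize.interval_coverage(
                truth.segmentation.called_domains(),
                repeats[repeats["name"] == "LINE"])
            in_cl = pd.Series(truth.in_planted_clique)
            wins += cov[in_cl[cov.index]].mean() > cov[~in_cl[cov.index]].mean()
        assert wins >= 9


class TestExpression:
    def seg_and_stats(self):
        seg = TadSegmentation([
            TadSegment(GenomicInterval("chr1", 0, 1000), "A"),
            TadSegment(GenomicInterval("chr1", 1000, 2000), "B"),
        ])
        stats = pd.DataFrame({"max_clique_size": [5, 1],
                              "category": ["clique_5", "singleton"]},
                             index=pd.Index(["A", "B"], name="tad_id"))
        return seg, stats

    def expr(self, vals_a, vals_b):
        rows = [("g%da" % i, "chr1", 10 + i, v) for i, v in enumerate(vals_a)]
        rows += [("g%db" % i, "chr1", 1010 + i, v) for i, v in enumerate(vals_b)]
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss_pos", "value"])

    def test_identical_samples_give_zero_statistic(self):
        seg, stats = self.seg_and_stats()
        vals = [1.0, 2.0, 3.0, 4.0]
        ks, p, _ = characterize.expression_compare(self.expr(vals, vals), seg, stats)
        assert ks == 0.0 and p == 1.0

    def test_disjoint_supports_give_statistic_one(self):
        seg, stats = self.seg_and_stats()
        ks, _, _ = characterize.expression_compare(
            self.expr([1, 2, 3], [10, 11, 12]), seg, stats)
        assert ks == 1.0

    def test_class_with_fewer_than_two_genes_rejected(self):
        seg, stats = self.seg_and_stats()
        with pytest.raises(ValueError, match="fewer than 2"):
            characterize.expression_compare(self.expr([1.0], [1, 2, 3]), seg, stats)

    def test_planted_expression_shift_detected(self, truth_run):
        cmap, truth, stats = truth_run
        _, expr, _ = sim.simulate_annotations(truth, expr_shift=1.0, seed=9)
        ks, p, summary = characterize.expression_compare(
            expr, truth.segmentation, stats)
        assert summary.loc["clique", "median"] < summary.loc["non_clique", "median"]
        assert p < 0.01


class TestSubcompartments:
    def seg(self):
        return TadSegmentation([
            TadSegment(GenomicInterval("chr1", 0, 1000), "A"),
            TadSegment(GenomicInterval("chr1", 1000, 2000), "B"),
        ])

    def test_identical_segment_scores_one(self):
        sub = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000],
                            "name": ["B2"]})
        df = characterize.subcompartment_overlap(self.seg(), sub)
        assert df.loc["A", "jaccard"] == 1.0
        assert df.loc["A", "label"] == "B2"

    def test_no_overlap_scores_zero(self):
        sub = pd.DataFrame({"chrom": ["chr1"], "start": [5000], "end": [6000],
                            "name": ["A1"]})
        df = characterize.subcompartment_overlap(self.seg(), sub)
        assert df.loc["A", "jaccard"] == 0.0
        assert df.loc["A", "label"] is None

    def test_half_offset_equal_length_gives_one_third(self):
        sub = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [1500],
                            "name": ["B3"]})
        df = characterize.subcompartment_overlap(self.seg(), sub)
        assert df.loc["A", "jaccard"] == pytest.approx(1 / 3)

    def test_per_label_union_mode(self):
        sub = pd.DataFrame({"chrom": ["chr1", "chr1"],
                            "start": [0, 500], "end": [500, 1000],
                            "name": ["B2", "B2"]})
        per_seg = characterize.subcompartment_overlap(self.seg(), sub)
        union = characterize.subcompartment_overlap(
            self.seg(), sub, per_label_union=True)
        assert per_seg.loc["A", "jaccard"] == pytest.approx(0.5)
        assert union.loc["A", "jaccard"] == 1.0

    def test_b_restricted_rerun_equals_post_hoc_filter(self, truth_run):
        """Restricting to B-compartment TADs then characterizing equals
        characterizing everything and filtering afterwards."""
        cmap, truth, stats = truth_run
        repeats, _, sub = sim.simulate_annotations(truth, seed=21)
        overlap = characterize.subcompartment_overlap(truth.segmentation, sub)
        b_ids = characterize.b_compartment_tads(overlap)
        all_cov = characterize.interval_coverage(
            truth.segmentation.called_domains(),
            repeats[repeats["name"] == "LINE"])
        b_tads = [s for s in truth.segmentation.called_domains() if s.id in b_ids]
        b_cov = characterize.interval_coverage(
            b_tads, repeats[repeats["name"] == "LINE"])
        pd.testing.assert_series_equal(b_cov, all_cov[b_cov.index])
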