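"""Feature annotation, sequence predictors, expression mapping."""
import numpy as np
import pandas as pd
import pytest

import nucgraph as ng
from nucgraph.neighbourhood import NeighbourhoodGraph
from nucgraph.omics_map import (
    DeTable,
    Pwm,
    annotate_edges,
    call_isochores,
    default_ctcf_pwm,
    edge_annotation_summary,
    map_expression,
    predict_ctcf,
    predict_rss,
    simple_de,
)
from nucgraph.types import FeatureTrack, Gene

from conftest import brute_force_overlaps


def _two_gene_graph():
    g = NeighbourhoodGraph()
    g.add_vertex(Gene("A", "chr1", 0, 10_000), 0, "seed")
    g.add_vertex(Gene("B", "chr1", 50_000, 60_000), 1, "contact")
    g.add_edge("A", "B", None, ("chr1", 0, 5_000), ("chr1", 50_000, 55_000), 1)
    g.add_edge("A", "B", None, ("chr1", 5_000, 10_000), ("chr1", 55_000, 60_000), 1)
    return g


class TestAnnotateEdges:
    def test_track_covering_one_fragment(self):
        g = _two_gene_graph()
        track = FeatureTrack("t", [("chr1", 1_000, 2_000, 1.0)])
        annotate_edges(g, track)
        values = sorted(d["features"]["t"] for *_, d in g.g.edges(data=True))
        assert values == [0.0, 1.0]
        # per-contact mean across the two supporting pairs
        assert edge_annotation_summary(g, "t")[("A", "B")] == 0.5

    def test_vertex_density_per_kb(self):
        g = _two_gene_graph()
        track = FeatureTrack("t", [("chr1", i * 100, i * 100 + 50, 1.0)
                                   for i in range(5)])  # 5 hits inside A
        annotate_edges(g, track)
        assert g.g.nodes["A"]["cov_t"] == pytest.approx(0.5)  # 5 per 10 kb
        assert g.g.nodes["B"]["cov_t"] == 0.0

    def test_agg_variants(self):
        g = _two_gene_graph()
        track = FeatureTrack("t", [("chr1", 1_000, 2_000, 1.0)])
        annotate_edges(g, track)
        assert edge_annotation_summary(g, "t", "sum")[("A", "B")] == 1.0
        assert edge_annotation_summary(g, "t", "max")[("A", "B")] == 1.0

    def test_empty_track_all_zero(self):
        g = _two_gene_graph()
        annotate_edges(g, FeatureTrack("none", []))
        assert all(d["features"]["none"] == 0.0
                   for *_, d in g.g.edges(data=True))

    def test_matches_quadratic_oracle(self, planted_world):
        genome, fragments, genes, spec, pairs = planted_world
        graph = ng.build_neighbourhood(["G0001"], pairs, fragments, genes,
                                       levels=2)
        rng = np.random.default_rng(42)
        ivs = []
        for _ in range(50):
            chrom = rng.choice(["chr1", "chr2"])
            s = int(rng.integers(0, 390_000))
            ivs.append((chrom, s, s + int(rng.integers(100, 10_000)), 1.0))
        track = FeatureTrack("rnd", ivs)
        annotate_edges(graph, track)
        for *_, d in graph.g.edges(data=True):
            expected = (brute_force_overlaps(track.intervals, *d["frag1"])
                        + brute_force_overlaps(track.intervals, *d["frag2"]))
            assert d["features"]["rnd"] == expected


class TestPredictCtcf:
    def test_planted_consensus_found_at_position(self):
        pwm = default_ctcf_pwm()
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("AT"), size=500))  # AT background
        seq = seq[:100] + pwm.consensus + seq[100 + pwm.length:]
        track = predict_ctcf(seq, pwm)
        assert ("seq", 100, 100 + pwm.length) in [
            (c, s, e) for c, s, e, _ in track.intervals]

    def test_strand_symmetric_hit_count(self):
        pwm = default_ctcf_pwm()
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        seq = seq[:300] + pwm.consensus + seq[300 + pwm.length:]
        comp = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert len(predict_ctcf(seq, pwm)) == len(predict_ctcf(comp, pwm))

    def test_all_n_sequence_empty(self):
        assert len(predict_ctcf("N" * 200, default_ctcf_pwm())) == 0

    def test_short_sequence_empty(self):
        assert len(predict_ctcf("ACGT", default_ctcf_pwm())) == 0

    def test_pwm_validation(self):
        with pytest.raises(ValueError):
            Pwm("bad", np.zeros((2, 4)), 0.0)


class TestPredictRss:
    def test_perfect_12_spacer_detected_with_value_0(self):
        site = "CACAGTG" + "T" * 12 + "ACAAAAACC"
        seq = "G" * 50 + site + "G" * 50
        hits = [(s, e, v) for _, s, e, v in predict_rss(seq).intervals]
        assert (50, 50 + len(site), 0.0) in hits

    def test_17bp_spacer_rejected(self):
        site = "CACAGTG" + "T" * 17 + "ACAAAAACC"
        seq = "G" * 50 + site + "G" * 50
        assert len(predict_rss(seq, 0, 0)) == 0

    def test_matches_brute_force_scanner(self):
        """Random sequences vs an exhaustive position-by-position oracle."""
        from nucgraph.omics_map import RSS_HEPTAMER, RSS_NONAMER

        def oracle(seq, mh, mn):
            def rc(s):
                return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
            found = set()
            n = len(seq)
            for strand_seq, fwd in ((seq, True), (rc(seq), False)):
                for i in range(n - 6):
                    h = strand_seq[i:i + 7]
                    if len(h) < 7:
                        continue
                    mmh = sum(a != b for a, b in zip(h, RSS_HEPTAMER))
                    if mmh > mh:
                        continue
                    for spacer in (11, 12, 13, 22, 23, 24):
                        j = i + 7 + spacer
                        nn = strand_seq[j:j + 9]
                        if len(nn) < 9:
                            continue
                        mmn = sum(a != b for a, b in zip(nn, RSS_NONAMER))
                        if mmn <= mn:
                            if fwd:
                                found.add((i, j + 9, mmh + mmn))
                            else:
                                found.add((n - j - 9, n - i, mmh + mmn))
            return found

        rng = np.random.default_rng(17)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            # plant one site to keep the comparison non-vacuous
            pos = int(rng.integers(0, 250))
            seq = seq[:pos] + "CACAGTG" + seq[pos + 7:]
            got = {(s, e, v) for _, s, e, v in predict_rss(seq, 1, 2).intervals}
            assert got == oracle(seq, 1, 2)


class TestIsochores:
    def test_two_segment_construction(self):
        genome, truth = ng.plant_features(
            {"chr1": "A" * 800_000},
            isochore_layout={"chr1": [(0, 400_000, 0.30),
                                      (400_000, 800_000, 0.60)]},
            seed=4)
        track = call_isochores(genome, window_bp=100_000)
        assert len(track) == 2
        (c1, s1, e1, v1), (c2, s2, e2, v2) = track.intervals
        assert (v1, v2) == (1.0, 5.0)  # L1 then H3
        assert abs(e1 - 400_000) <= 100_000  # boundary within one window
        assert abs(s2 - 400_000) <= 100_000

    def test_homogeneous_350kb_single_segment(self):
        genome, _ = ng.plant_features(
            {"chr1": "A" * 350_000},
            isochore_layout={"chr1": [(0, 350_000, 0.50)]}, seed=5)
        track = call_isochores(genome, window_bp=50_000)
        assert len(track) == 1
        assert track.intervals[0][3] == 4.0  # 50% GC -> H2

    def test_below_min_len_discarded(self):
        genome, _ = ng.plant_features(
            {"chr1": "A" * 200_000},
            isochore_layout={"chr1": [(0, 200_000, 0.50)]}, seed=6)
        assert len(call_isochores(genome, window_bp=50_000)) == 0

    def test_segments_disjoint_and_classes_recomputable(self):
        genome, _ = ng.plant_features(
            {"chr1": "A" * 1_200_000},
            isochore_layout={"chr1": [(0, 400_000, 0.35),
                                      (400_000, 700_000, 0.44),
                                      (700_000, 1_200_000, 0.50)]},
            seed=7)
        track = call_isochores(genome, window_bp=100_000)
        bounds = (37.0, 41.0, 46.0, 53.0)
        prev_end = 0
        for chrom, start, end, value in track.intervals:
            assert start >= prev_end
            assert end - start >= 300_000
            prev_end = end
            seq = genome[chrom][start:end]
            pct = 100 * (seq.count("G") + seq.count("C")) / len(seq)
            assert value == 1 + int(np.searchsorted(bounds, pct))

    def test_window_larger_than_min_len_rejected(self):
        with pytest.raises(ValueError):
            call_isochores("A" * 1000, window_bp=500_000, min_len_bp=300_000)


class TestExpression:
    def test_colour_rules(self):
        g = _two_gene_graph()
        de = DeTable(pd.DataFrame({"logFC": [2.0, -0.5], "p": [0.01, 0.2]},
                                  index=["A", "B"]))
        map_expression(g, de)
        assert g.g.nodes["A"]["weight"] == 2.0
        assert g.g.nodes["A"]["colour"] == "red"
        assert g.g.nodes["B"]["weight"] == 0.5
        assert g.g.nodes["B"]["colour"] == "green"

    def test_missing_gene_neutral_grey(self):
        g = _two_gene_graph()
        de = DeTable(pd.DataFrame({"logFC": [1.0], "p": [0.5]}, index=["A"]))
        map_expression(g, de)
        assert g.g.nodes["B"]["weight"] == 0.0
        assert g.g.nodes["B"]["colour"] == "grey"

    def test_simple_de_exact_ratio(self):
        expr = pd.DataFrame({"A1": [1.0], "A2": [2.0],
                             "B1": [4.0], "B2": [8.0]}, index=["g"])
        de = simple_de(expr, ["A", "A", "B", "B"])
        assert de.table.loc["g", "logFC"] == pytest.approx(2.0)

    def test_identical_groups_zero_logfc(self):
        expr = pd.DataFrame({"A1": [3.0, 5.0], "B1": [3.0, 5.0]},
                            index=["g1", "g2"])
        de = simple_de(expr, ["A", "B"])
        assert (de.table["logFC"] == 0).all()
        assert (de.table["p"] == 1.0).all()  # n=1 per group

    def test_shifted_gene_significant(self):
        rng = np.random.default_rng(8)
        base = rng.normal(5, 0.1, (1, 10))
        data = 2.0 ** base
        data[0, 5:] *= 2.0  # one log2 unit shift in group B
        expr = pd.DataFrame(data, index=["g"],
                            columns=[f"s{i}" for i in range(10)])
        de = simple_de(expr, ["A"] * 5 + ["B"] * 5)
        assert de.table.loc["g", "p"] < 0.01
        assert de.table.loc["g", "logFC"] == pytest.approx(1.0, abs=0.2)

    def test_wrong_label_count_rejected(self):
        expr = pd.DataFrame({"s1": [1.0], "s2": [1.0], "s3": [1.0]},
                            index=["g"])
        with pytest.raises(ValueError):
            simple_de(expr, ["A", "B", "C"])
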