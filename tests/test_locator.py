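"""ce-scoring, threshold estimation and subpathway extraction."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from cernapath.cerna import CeRNAPair
from cernapath.diffexpr import load_external_de
from cernapath.kgml import PathwayGraph, path_distance_and_union
from cernapath.locator import (
    CeScore,
    annotate_key_nodes,
    all_ce_scores,
    build_node_sets,
    ce_score,
    estimate_threshold,
    extract_subpathways,
)

import pandas as pd


def make_graph(pathway_id, nodes, edges, genes=None):
    pg = PathwayGraph(pathway_id=pathway_id)
    for n in nodes:
        pg.graph.add_node(n, genes=frozenset(genes[n] if genes else {n}))
    pg.graph.add_edges_from(edges)
    return pg


def score_record(graph_id, u, v, score, d=1):
    return CeScore(pathway_id=graph_id, node_i=u, node_j=v, P_DE=0.01,
                   P_cor=1.0, P=0.01, z=2.33, d=d, score=score)


class TestCeScore:
    def test_non_key_pair_has_minus_inf_score(self):
        P_DE, P, z, score = ce_score(1.0, 1.0, 1.0, d=3)
        assert P == 1.0 and z == float("-inf") and score == float("-inf")

    def test_median_probability_gives_zero(self):
        _, _, z, score = ce_score(0.5, 0.9, 1.0, d=4)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_inverse_normal_oracle(self):
        # P = 0.0013499 maps to z = 3.000 (standard-normal upper tail)
        P_DE, P, z, score = ce_score(0.0013499, 1.0, 1.0, d=2)
        assert P_DE == pytest.approx(0.0013499)
        assert z == pytest.approx(3.0, abs=1e-4)
        assert score == pytest.approx(3.0 * math.exp(-2.0), abs=1e-4)

    def test_p_de_is_min_of_node_pvalues(self):
        P_DE, P, _, _ = ce_score(0.04, 0.002, 0.5, d=1)
        assert P_DE == 0.002 and P == pytest.approx(0.001)

    def test_tiny_p_clamped_to_finite_z(self):
        _, _, z, score = ce_score(0.0, 1e-310, 1.0, d=1)
        assert np.isfinite(z) and np.isfinite(score)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            ce_score(0.5, 0.5, 0.5, d=0)
        with pytest.raises(ValueError):
            ce_score(1.5, 0.5, 0.5, d=1)
        with pytest.raises(ValueError):
            ce_score(0.5, 0.5, 0.5, d=1, score_form="nope")

    def test_score_monotone_in_p_and_d(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p1, p2 = sorted(rng.uniform(1e-12, 0.49, size=2))
            d = int(rng.integers(1, 8))
            s_small_p = ce_score(p1, 1.0, 1.0, d)[3]
            s_large_p = ce_score(p2, 1.0, 1.0, d)[3]
            assert s_small_p > s_large_p
            s_far = ce_score(p1, 1.0, 1.0, d + 1)[3]
            assert s_far < s_small_p

    def test_literal_form_available(self):
        _, _, z, score = ce_score(0.0013499, 1.0, 1.0, d=2,
                                  score_form="exp_neg_dz")
        assert score == pytest.approx(math.exp(-2 * z))


def annotation_inputs():
    graph = make_graph("p", "ABCDE",
                       [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
    de = load_external_de(
        pd.DataFrame({"gene": ["A", "C"], "p_fdr": [0.001, 0.004]}),
        alpha=0.01,
    )
    pairs = [CeRNAPair("A", "C", 5, 1e-4, 1e-3, 0.9, 1e-6)]
    return graph, de, pairs


class TestAnnotation:
    def test_key_nodes_are_de_or_cerna(self):
        graph, de, pairs = annotation_inputs()
        ann = annotate_key_nodes(graph, de, pairs)
        assert ann.key_nodes == {"A", "C"}
        assert ann.de_p("A") == pytest.approx(0.001)
        assert ann.de_p("B") == 1.0
        assert ann.p_cor("A", "C") == pytest.approx(1e-6)
        assert ann.p_cor("A", "B") == 1.0

    def test_multi_gene_node_takes_min_over_members(self):
        graph = make_graph("p", ["n1", "n2"], [("n1", "n2")],
                           genes={"n1": {"A", "B"}, "n2": {"C"}})
        de = load_external_de(
            pd.DataFrame({"gene": ["A", "B", "C"],
                          "p_fdr": [0.005, 0.0001, 0.002]}),
            alpha=0.01,
        )
        ann = annotate_key_nodes(graph, de, [])
        assert ann.de_p("n1") == pytest.approx(0.0001)


class TestAllScores:
    def test_three_connected_key_nodes_give_three_scores(self):
        graph, de, pairs = annotation_inputs()
        de = load_external_de(
            pd.DataFrame({"gene": ["A", "C", "E"],
                          "p_fdr": [0.001, 0.004, 0.002]}),
            alpha=0.01,
        )
        ann = {"p": annotate_key_nodes(graph, de, pairs)}
        scores = all_ce_scores([graph], ann)
        assert len(scores) == 3
        by_pair = {(s.node_i, s.node_j): s for s in scores}
        assert by_pair[("A", "C")].d == 2
        assert by_pair[("A", "E")].d == 4

    def test_cross_component_pairs_absent(self):
        graph = make_graph("p", "ABCD", [("A", "B"), ("C", "D")])
        de = load_external_de(
            pd.DataFrame({"gene": ["A", "C"], "p_fdr": [0.001, 0.001]}),
            alpha=0.01,
        )
        ann = {"p": annotate_key_nodes(graph, de, [])}
        scores = all_ce_scores([graph], ann)
        assert scores == []

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(3)
        nodes = [str(i) for i in range(10)]
        edges = [(a, b) for a, b in itertools.combinations(nodes, 2)
                 if rng.random() < 0.3]
        graph = make_graph("p", nodes, edges)
        de = load_external_de(
            pd.DataFrame({"gene": nodes[:5],
                          "p_fdr": rng.uniform(1e-5, 0.009, 5)}),
            alpha=0.01,
        )
        pairs = [CeRNAPair(*sorted(("0", "3")), 5, 1e-4, 1e-3, 0.8, 1e-5)]
        ann = {"p": annotate_key_nodes(graph, de, pairs)}
        scores = all_ce_scores([graph], ann)
        expected = {}
        for u, v in itertools.combinations(sorted(ann["p"].key_nodes), 2):
            d, _ = path_distance_and_union(graph, u, v)
            if d:
                _, _, _, s = ce_score(ann["p"].de_p(u), ann["p"].de_p(v),
                                      ann["p"].p_cor(u, v), d)
                expected[(u, v)] = (d, s)
        got = {(s.node_i, s.node_j): (s.d, s.score) for s in scores}
        assert got == expected


class TestThreshold:
    def test_linear_interpolation_quantile(self):
        assert estimate_threshold([1.0, 2.0, 3.0, 4.0]) == pytest.approx(3.25)

    def test_constant_scores(self):
        assert estimate_threshold([2.5, 2.5, 2.5]) == 2.5

    def test_q_zero_gives_min(self):
        assert estimate_threshold([3.0, 1.0, 2.0], q=0.0) == 1.0

    def test_non_finite_scores_excluded(self):
        assert estimate_threshold([1.0, float("-inf"), 3.0],
                                  q=1.0) == 3.0

    def test_no_finite_scores_raises(self):
        with pytest.raises(ValueError, match="no scorable"):
            estimate_threshold([float("-inf")])


class TestNodeSets:
    def test_overlapping_pairs_merge(self):
        graph = make_graph("p", "ABCD", [("A", "C"), ("C", "B"), ("B", "D")])
        scores = [score_record("p", "A", "B", 5.0, d=2),
                  score_record("p", "B", "D", 5.0, d=1)]
        sets = build_node_sets(graph, scores, omega=1.0)
        assert sets == [{"A", "B", "C", "D"}]

    def test_disjoint_regions_stay_separate(self):
        graph = make_graph("p", "ABCDEF",
                           [("A", "B"), ("C", "D"), ("E", "F"), ("B", "C")])
        scores = [score_record("p", "A", "B", 5.0),
                  score_record("p", "E", "F", 5.0)]
        sets = build_node_sets(graph, scores, omega=1.0)
        assert sorted(map(sorted, sets)) == [["A", "B"], ["E", "F"]]

    def test_threshold_is_strict(self):
        graph = make_graph("p", "AB", [("A", "B")])
        scores = [score_record("p", "A", "B", 1.0)]
        assert build_node_sets(graph, scores, omega=1.0) == []

    def test_merging_order_independent(self):
        rng = np.random.default_rng(8)
        for trial in range(30):
            n = int(rng.integers(5, 15))
            nodes = [str(i) for i in range(n)]
            edges = [(a, b) for a, b in itertools.combinations(nodes, 2)
                     if rng.random() < 0.3]
            graph = make_graph("p", nodes, edges)
            keys = list(rng.choice(nodes, size=min(n, 6), replace=False))
            scores = []
            for u, v in itertools.combinations(sorted(keys), 2):
                d, _ = path_distance_and_union(graph, u, v)
                if d:
                    scores.append(score_record("p", u, v,
                                               float(rng.uniform(0, 2)), d))
            omega = 1.0
            expected_sets = brute_force_sets(graph, scores, omega)
            got = build_node_sets(graph, scores, omega)
            assert sorted(map(sorted, got)) == sorted(map(sorted,
                                                          expected_sets))
            rng.shuffle(scores)
            got_shuffled = build_node_sets(graph, scores, omega)
            assert sorted(map(sorted, got)) == sorted(
                map(sorted, got_shuffled)
            )

    def test_lowering_omega_never_shrinks_sets(self):
        rng = np.random.default_rng(9)
        nodes = [str(i) for i in range(12)]
        edges = [(a, b) for a, b in itertools.combinations(nodes, 2)
                 if rng.random() < 0.25]
        graph = make_graph("p", nodes, edges)
        scores = []
        for u, v in itertools.combinations(nodes[:6], 2):
            d, _ = path_distance_and_union(graph, u, v)
            if d:
                scores.append(score_record("p", u, v,
                                           float(rng.uniform(0, 2)), d))
        hi = build_node_sets(graph, scores, omega=1.2)
        lo = build_node_sets(graph, scores, omega=0.4)
        for s_hi in hi:
            assert any(s_hi <= s_lo for s_lo in lo)


def brute_force_sets(graph, scores, omega):
    """Independent oracle: repeated pairwise merging to a fixed point."""
    sets = []
    for sc in scores:
        if sc.score > omega:
            _, members = path_distance_and_union(graph, sc.node_i, sc.node_j)
            sets.append(set(members))
    changed = True
    while changed:
        changed = False
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] and sets[j] and sets[i] & sets[j]:
                    sets[i] |= sets[j]
                    sets[j] = set()
                    changed = True
    return [s for s in sets if s]


class TestExtract:
    def graph(self):
        nodes = [str(i) for i in range(8)]
        edges = [(str(i), str(i + 1)) for i in range(7)]
        return make_graph("path:77777", nodes, edges)

    def test_small_sets_dropped(self):
        subs = extract_subpathways(self.graph(), [{"0", "1", "2", "3"}])
        assert subs == []

    def test_five_node_set_kept_with_induced_edges(self):
        subs = extract_subpathways(self.graph(), [{"0", "1", "2", "3", "4"}])
        assert len(subs) == 1
        sp = subs[0]
        assert sp.subpathway_id == "path:77777_1"
        assert sp.subgraph.number_of_edges() == 4
        assert sp.genes == frozenset({"0", "1", "2", "3", "4"})

    def test_empty_input_gives_empty_output(self):
        assert extract_subpathways(self.graph(), []) == []

    def test_ids_ordered_by_size_then_nodes(self):
        sets = [{"0", "1", "2", "3", "4"}, {"2", "3", "4", "5", "6", "7"}]
        subs = extract_subpathways(self.graph(), sets)
        assert [sp.subpathway_id for sp in subs] == ["path:77777_1",
                                                     "path:77777_2"]
        assert len(subs[0].nodes) == 6  # larger set numbered first

    def test_unknown_nodes_raise(self):
        with pytest.raises(ValueError, match="unknown"):
            extract_subpathways(self.graph(), [{"0", "zz", "1", "2", "3"}])
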