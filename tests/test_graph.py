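"""Graph/ranking data model and the agony score itself."""

import numpy as np
import pytest

from agony import (DirectedGraph, PenaltySpec, Ranking, agony, canonicalize,
                   classify_edges, hierarchy, penalty)


@pytest.mark.parametrize("d,x,expected", [
    (1, 0, 1),       # same-class edge costs one unit
    (1, -3, 0),      # forward links are free
    (2, 2, 9),
    (0, 7, 1),       # d=0 counts backward edges
    (0, -1, 0),
    (1.5, 3, 8.0),   # real exponents are allowed
])
def test_penalty_values(d, x, expected):
    assert penalty(PenaltySpec(d), x) == pytest.approx(expected)


def test_penalty_rejects_negative_exponent():
    with pytest.raises(ValueError):
        PenaltySpec(-0.5)


class TestDirectedGraph:
    def test_rejects_self_loops(self):
        with pytest.raises(ValueError, match="self-loop"):
            DirectedGraph([("a", "a")])

    def test_deduplicates_edges(self):
        g = DirectedGraph([("a", "b"), ("a", "b")])
        assert g.n_edges == 1

    def test_isolated_nodes_kept(self):
        g = DirectedGraph([("a", "b")], nodes=["a", "b", "z"])
        assert g.n_nodes == 3

    def test_subgraph(self, small_dag):
        sub = small_dag.subgraph(["a", "b", "d"])
        assert sub.edges == frozenset({("a", "b"), ("b", "d")})


class TestRanking:
    def test_rejects_nonpositive_ranks(self):
        with pytest.raises(ValueError):
            Ranking({"a": 0})

    def test_class_sizes(self):
        r = Ranking({"a": 1, "b": 1, "c": 3})
        assert r.n_classes == 2
        assert r.class_sizes == [2, 1]

    def test_invert(self):
        r = Ranking({"a": 1, "b": 2, "c": 3})
        assert r.invert().rank == {"a": 3, "b": 2, "c": 1}


class TestAgony:
    def test_trivial_ranking_costs_m(self, rng):
        # the one-class ranking pays f_d(0)=1 per edge, i.e. exactly m
        from conftest import random_graph
        for _ in range(20):
            g = random_graph(rng)
            r = Ranking.trivial(g.nodes)
            for d in (0, 0.5, 1, 2):
                assert agony(g, r, PenaltySpec(d)) == g.n_edges

    def test_dag_with_topological_ranking_is_zero(self, small_dag):
        order = ["a", "b", "c", "d"]
        r = Ranking({v: i + 1 for i, v in enumerate(order)})
        for d in (0, 1, 2, 3):
            assert agony(small_dag, r, PenaltySpec(d)) == 0
        assert hierarchy(small_dag, r) == 1.0

    def test_three_cycle_minimum_is_three(self, triangle):
        # brute-force over all ordered partitions of 3 nodes
        from agony import minimize_agony_bruteforce
        res = minimize_agony_bruteforce(triangle, PenaltySpec(1))
        assert res.agony == 3

    def test_missing_rank_names_node(self, triangle):
        with pytest.raises(KeyError, match="c"):
            agony(triangle, Ranking({"a": 1, "b": 2}), PenaltySpec(1))

    def test_two_cycle_two_classes_has_zero_hierarchy(self):
        g = DirectedGraph([("a", "b"), ("b", "a")])
        r = Ranking({"a": 1, "b": 2})
        assert hierarchy(g, r, PenaltySpec(1)) == 0.0

    def test_hierarchy_undefined_without_edges(self):
        g = DirectedGraph(nodes=["a", "b"])
        with pytest.raises(ValueError, match="undefined"):
            hierarchy(g, Ranking.trivial(g.nodes))

    def test_hierarchy_can_be_negative_without_minimisation(self):
        g = DirectedGraph([("a", "b")])
        r = Ranking({"a": 5, "b": 1})  # strongly violated ranking
        assert hierarchy(g, r, PenaltySpec(1)) < 0

    def test_d0_agony_counts_backward_edges(self, rng):
        from conftest import random_graph
        for _ in range(10):
            g = random_graph(rng)
            ranks = {v: int(rng.integers(1, 4)) for v in g.nodes}
            r = Ranking(ranks)
            backward = sum(1 for lbl in classify_edges(g, r).values()
                           if lbl == "backward")
            assert agony(g, r, PenaltySpec(0)) == backward

    def test_invariant_under_difference_preserving_relabelling(self, rng):
        from conftest import random_graph
        for _ in range(10):
            g = random_graph(rng)
            ranks = {v: int(rng.integers(1, 5)) for v in g.nodes}
            shifted = Ranking({v: r + 7 for v, r in ranks.items()})
            for d in (0, 1, 2):
                assert agony(g, Ranking(ranks), PenaltySpec(d)) == \
                    agony(g, shifted, PenaltySpec(d))

    def test_hierarchy_complements_agony(self, rng):
        from conftest import random_graph
        for _ in range(10):
            g = random_graph(rng)
            if g.n_edges == 0:
                continue
            r = Ranking({v: int(rng.integers(1, 4)) for v in g.nodes})
            a = agony(g, r, PenaltySpec(1))
            h = hierarchy(g, r, PenaltySpec(1))
            assert h + a / g.n_edges == pytest.approx(1.0, abs=1e-12)


class TestClassifyEdges:
    def test_labels(self):
        g = DirectedGraph([("a", "b"), ("b", "a"), ("a", "c"), ("c", "a")])
        r = Ranking({"a": 1, "b": 1, "c": 3})
        labels = classify_edges(g, r)
        assert labels[("a", "b")] == "backward"   # same class
        assert labels[("a", "c")] == "forward"    # up two classes
        assert labels[("c", "a")] == "backward"   # down-rank


class TestCanonicalize:
    def test_gap_removal(self):
        r = canonicalize(Ranking({"a": 2, "b": 5, "c": 5}))
        assert r.rank == {"a": 1, "b": 2, "c": 2}

    def test_identity_on_contiguous(self):
        r = Ranking({"a": 1, "b": 2})
        assert canonicalize(r) == r

    def test_never_increases_agony(self, rng):
        from conftest import random_graph
        g = DirectedGraph([("a", "b")])
        r = Ranking({"a": 4, "b": 1})
        assert agony(g, r, PenaltySpec(1)) == 4
        assert agony(g, canonicalize(r), PenaltySpec(1)) == 2
        for _ in range(15):
            g = random_graph(rng)
            ranks = {v: int(rng.integers(1, 10)) for v in g.nodes}
            r = Ranking(ranks)
            for d in (0, 1, 2):
                assert agony(g, canonicalize(r), PenaltySpec(d)) <= \
                    agony(g, r, PenaltySpec(d))
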