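"""Redundancy graph construction, ranking and dominating-set reduction."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prm import (
    ComparisonRecord,
    ProteomeMetadata,
    RankVector,
    brute_force_dominating_set,
    build_graph,
    compare_rank,
    export_graph,
    graph_from_edges,
    import_graph,
    is_dominating_set,
    rank_vector,
    reduce,
    removable,
    remove_node,
    select_weakest,
)
from prm.graph import ReductionState


def fresh_state(graph, protected=(), seed=0):
    return ReductionState(surviving=set(graph.nodes),
                          protected=set(protected), rng_seed=seed)


class TestBuildGraph:
    def test_threshold_cut(self):
        meta = {p: ProteomeMetadata() for p in "ABC"}
        comparisons = [
            ComparisonRecord("A", "B", 0.95, True),   # B redundant to A
            ComparisonRecord("A", "C", 0.89, True),   # below threshold
            ComparisonRecord("C", "B", None, False),  # skipped
        ]
        graph = build_graph(comparisons, meta)
        assert set(graph.digraph.edges) == {("B", "A")}
        assert graph.similarity("B", "A") == 0.95

    def test_mutual_pair_gives_two_cycle(self):
        meta = {p: ProteomeMetadata() for p in "AB"}
        comparisons = [ComparisonRecord("A", "B", 0.99, True),
                       ComparisonRecord("B", "A", 0.99, True)]
        graph = build_graph(comparisons, meta)
        assert set(graph.digraph.edges) == {("A", "B"), ("B", "A")}

    def test_no_comparisons_gives_isolated_nodes(self):
        meta = {p: ProteomeMetadata() for p in "ABC"}
        graph = build_graph([], meta)
        assert graph.nodes == {"A", "B", "C"}
        assert not graph.digraph.edges

    def test_exact_threshold_value_kept(self):
        # a similarity of exactly 0.9 arriving via float arithmetic can
        # sit a few ulp below the threshold; the tolerance must keep it
        meta = {p: ProteomeMetadata() for p in "AB"}
        sim = 0.3 * 3  # 0.8999999999999999...
        assert sim < 0.9
        graph = build_graph([ComparisonRecord("A", "B", sim, True)], meta)
        assert set(graph.digraph.edges) == {("B", "A")}

    def test_unknown_proteome_errors(self):
        with pytest.raises(KeyError):
            build_graph([ComparisonRecord("A", "Z", 0.95, True)],
                        {"A": ProteomeMetadata()})


class TestRankVector:
    def test_isolated_reference_node(self, reference_metadata):
        graph = graph_from_edges([], nodes=["X"],
                                 metadata={"X": reference_metadata})
        state = fresh_state(graph)
        assert rank_vector(graph, state, "X") == RankVector(0, 0, 2, 100, 1)

    def test_degrees_counted_on_surviving_subgraph(self):
        # three leaves point at both X and Y; removing X must not change
        # Y's indegree, but removing a leaf must.
        edges = [(leaf, hub) for leaf in ("L1", "L2", "L3")
                 for hub in ("X", "Y")]
        graph = graph_from_edges(edges)
        state = fresh_state(graph)
        assert rank_vector(graph, state, "Y").indegree == 3
        remove_node(graph, state, "L1")
        assert rank_vector(graph, state, "Y").indegree == 2

    def test_plain_node_vector(self):
        edges = [(f"i{k}", "X") for k in range(4)]
        edges += [("X", f"o{k}") for k in range(5)]
        # give every out-neighbour a back-edge so degrees are as stated
        graph = graph_from_edges(edges)
        state = fresh_state(graph)
        assert rank_vector(graph, state, "X") == RankVector(4, 5, 1, 0, 1)

    def test_removed_node_errors(self):
        graph = graph_from_edges([("A", "B")])
        state = fresh_state(graph)
        remove_node(graph, state, "A")
        with pytest.raises(KeyError):
            rank_vector(graph, state, "A")


class TestCompareRank:
    @pytest.mark.parametrize("a,b", [
        ((4, 5, 1, 0, 1), (5, 4, 1, 0, 1)),
        ((0, 5, 1, 0, 1), (0, 3, 1, 0, 1)),
        ((5, 2, 1, 0, 1), (6, 1, 1, 0, 1)),
        ((5, 2, 1, 0, 1), (5, 2, 2, 0, 1)),
        ((5, 2, 1, 105, 1), (5, 2, 2, 200, 1)),
    ])
    def test_printed_ranking_pairs_favour_b(self, a, b):
        assert compare_rank(RankVector(*a), RankVector(*b)) == -1
        assert compare_rank(RankVector(*b), RankVector(*a)) == 1

    def test_identical_vectors_tie(self):
        v = RankVector(5, 2, 1, 105, 1)
        assert compare_rank(v, v) == 0

    def test_previous_state_breaks_final_tie(self):
        a = RankVector(2, 2, 1, 10, 0)
        b = RankVector(2, 2, 1, 10, 1)
        assert compare_rank(a, b) == -1

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(*[st.integers(0, 6)] * 5),
           st.tuples(*[st.integers(0, 6)] * 5),
           st.tuples(*[st.integers(0, 6)] * 5))
    def test_total_preorder(self, ta, tb, tc):
        a, b, c = (RankVector(*t) for t in (ta, tb, tc))
        assert compare_rank(a, b) == -compare_rank(b, a)  # completeness
        if compare_rank(a, b) >= 0 and compare_rank(b, c) >= 0:
            assert compare_rank(a, c) >= 0  # transitivity


class TestRemovable:
    def test_protected_node_not_removable(self):
        graph = graph_from_edges([("A", "B"), ("B", "A")])
        state = fresh_state(graph, protected={"A"})
        assert not removable(graph, state, "A")
        assert removable(graph, state, "B")

    def test_node_without_out_edges_not_removable(self):
        graph = graph_from_edges([("A", "B")])
        state = fresh_state(graph)
        assert not removable(graph, state, "B")

    def test_last_representative_not_removable(self):
        graph = graph_from_edges([("A", "B")])
        state = fresh_state(graph)
        remove_node(graph, state, "A")
        assert not removable(graph, state, "B")


class TestRemoveNode:
    def test_representation_transferred_to_out_neighbours(self):
        graph = graph_from_edges([("A", "B"), ("A", "C"),
                                  ("B", "A"), ("C", "A")])
        state = fresh_state(graph)
        remove_node(graph, state, "A")
        assert state.surviving_neighbours["A"] == {"B", "C"}
        assert state.represented["B"] == {"A"}
        assert state.represented["C"] == {"A"}

    def test_chain_preserves_domination(self):
        graph = graph_from_edges([("A", "B"), ("B", "C"), ("C", "B")])
        state = fresh_state(graph)
        remove_node(graph, state, "A")
        assert state.surviving_neighbours["A"] == {"B"}
        assert not removable(graph, state, "B")
        # C is removable: B stays as its own representative chain allows
        assert removable(graph, state, "C")

    def test_representation_uses_original_direct_edges_only(self):
        # D -> C -> B, with back-edges so removals are legal; removing C
        # after D must not re-route D's representation to B.
        graph = graph_from_edges([("D", "C"), ("C", "D"), ("C", "B"),
                                  ("B", "C"), ("D", "B"), ("B", "D")])
        state = fresh_state(graph)
        remove_node(graph, state, "D")
        assert state.surviving_neighbours["D"] == {"C", "B"}
        remove_node(graph, state, "C")
        # D keeps its own surviving-neighbour entry, now shrunk to B
        assert state.surviving_neighbours["D"] == {"B"}
        assert state.surviving_neighbours["C"] == {"B"}
        assert state.represented["B"] == {"D", "C"}

    def test_removing_unremovable_node_errors(self):
        graph = graph_from_edges([("A", "B")])
        state = fresh_state(graph)
        with pytest.raises(ValueError):
            remove_node(graph, state, "B")


class TestSelectWeakest:
    def test_lower_annotation_selected(self):
        meta = {"A": ProteomeMetadata(annotation_level=105),
                "B": ProteomeMetadata(annotation_level=200)}
        graph = graph_from_edges([("A", "B"), ("B", "A")], metadata=meta)
        state = fresh_state(graph)
        assert select_weakest(graph, state) == "A"

    def test_all_protected_returns_none(self):
        graph = graph_from_edges([("A", "B"), ("B", "A")])
        state = fresh_state(graph, protected={"A", "B"})
        assert select_weakest(graph, state) is None

    def test_tie_broken_by_smaller_represented_set(self):
        # After removing R1 and R2, X and Y are fully rank-tied (in=1,
        # out=1 on the surviving subgraph) but X represents {R1, R2} and Y
        # only {R1}: the less comprehensive representative Y is removed.
        edges = [("R1", "X"), ("R1", "Y"), ("R2", "X"), ("R2", "Z"),
                 ("X", "Y"), ("Y", "X")]
        graph = graph_from_edges(edges)
        state = fresh_state(graph)
        remove_node(graph, state, "R1")
        remove_node(graph, state, "R2")
        assert state.represented["X"] == {"R1", "R2"}
        assert state.represented["Y"] == {"R1"}
        assert removable(graph, state, "X") and removable(graph, state, "Y")
        assert select_weakest(graph, state) == "Y"

    def test_seeded_tie_break_is_deterministic(self):
        graph = graph_from_edges([("A", "B"), ("B", "A")])
        choices = {select_weakest(graph, fresh_state(graph, seed=42))
                   for _ in range(5)}
        assert len(choices) == 1


class TestReduce:
    def test_isolated_node_survives(self):
        graph = graph_from_edges([], nodes=["X"])
        state = reduce(graph)
        assert state.surviving == {"X"} and not state.removed

    def test_mutual_pair_keeps_exactly_one(self):
        graph = graph_from_edges([("A", "B"), ("B", "A")])
        state = reduce(graph, seed=0)
        assert len(state.surviving) == 1
        (removed,) = state.removed
        assert state.surviving_neighbours[removed] == state.surviving

    def test_star_collapses_to_hub(self):
        edges = [(f"leaf{i}", "hub") for i in range(6)]
        graph = graph_from_edges(edges)
        state = reduce(graph)
        assert state.surviving == {"hub"}
        assert all(state.surviving_neighbours[r] == {"hub"}
                   for r in state.removed)

    def test_protected_everything_is_identity(self):
        graph = graph_from_edges([("A", "B"), ("B", "A"), ("B", "C"),
                                  ("C", "B")])
        state = reduce(graph, protected={"A", "B", "C"})
        assert state.surviving == {"A", "B", "C"}

    def test_determinism(self):
        rng = np.random.default_rng(5)
        edges = random_digraph_edges(rng, 10, 0.4)
        graph = graph_from_edges(edges, nodes=[f"n{i}" for i in range(10)])
        a = reduce(graph, seed=7)
        graph2 = graph_from_edges(edges, nodes=[f"n{i}" for i in range(10)])
        b = reduce(graph2, seed=7)
        assert a.surviving == b.surviving and a.removed == b.removed

    def test_conservation_and_domination_at_every_step(self):
        rng = np.random.default_rng(17)
        edges = random_digraph_edges(rng, 9, 0.35)
        graph = graph_from_edges(edges, nodes=[f"n{i}" for i in range(9)])
        state = fresh_state(graph)
        n = len(graph.nodes)
        while True:
            weakest = select_weakest(graph, state, random.Random(0))
            if weakest is None:
                break
            remove_node(graph, state, weakest)
            assert len(state.surviving) + len(state.removed) == n
            state.check_invariants(graph.nodes)
            assert is_dominating_set(graph, state.surviving)


class TestBruteForce:
    def test_edgeless_graph_needs_all_nodes(self):
        graph = graph_from_edges([], nodes=list("ABCD"))
        assert brute_force_dominating_set(graph) == 4

    def test_two_cycle_needs_one(self):
        graph = graph_from_edges([("A", "B"), ("B", "A")])
        assert brute_force_dominating_set(graph) == 1

    def test_star_needs_one(self):
        graph = graph_from_edges([(f"leaf{i}", "hub") for i in range(5)])
        assert brute_force_dominating_set(graph) == 1

    def test_large_graph_rejected(self):
        graph = graph_from_edges([], nodes=[f"n{i}" for i in range(16)])
        with pytest.raises(ValueError):
            brute_force_dominating_set(graph)


class TestGraphIO:
    def test_round_trip(self, tmp_path, rng):
        edges = random_digraph_edges(rng, 12, 0.5)
        graph = graph_from_edges(edges, similarity=0.912345678912)
        path = tmp_path / "graph.tsv"
        export_graph(graph, path)
        loaded = import_graph(path)
        assert set(loaded.digraph.edges) == set(graph.digraph.edges)
        for e in graph.digraph.edges:
            assert loaded.similarity(*e) == pytest.approx(
                graph.similarity(*e), abs=1e-12)

    def test_empty_graph_round_trip(self, tmp_path):
        graph = graph_from_edges([])
        path = tmp_path / "empty.tsv"
        export_graph(graph, path)
        assert not import_graph(path).digraph.edges

    def test_out_of_range_similarity_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("source_id\ttarget_id\tsimilarity\nA\tB\t1.2\n")
        with pytest.raises(ValueError, match=":2:"):
            import_graph(path)

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("source_id\ttarget_id\tsimilarity\nA\tB\n")
        with pytest.raises(ValueError, match=":2:"):
            import_graph(path)


def random_digraph_edges(rng, n, density):
    nodes = [f"n{i}" for i in range(n)]
    return [(a, b) for a in nodes for b in nodes
            if a != b and rng.random() < density]


def test_reduce_always_valid_and_never_beats_brute_force():
    """On many small random digraphs the heuristic yields a valid
    dominating set whose size is at least the exact minimum."""
    rng = np.random.default_rng(99)
    for trial in range(60):
        n = int(rng.integers(2, 13))
        density = float(rng.uniform(0.1, 0.5))
        edges = random_digraph_edges(rng, n, density)
        nodes = [f"n{i}" for i in range(n)]
        graph = graph_from_edges(edges, nodes=nodes)
        state = reduce(graph, seed=trial)
        assert is_dominating_set(graph, state.surviving)
        assert len(state.surviving) >= brute_force_dominating_set(graph)
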