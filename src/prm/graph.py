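"""Directed redundancy graph and its dominating-set reduction.

Nodes are proteomes; an edge X -> Y means "X is redundant to Y", i.e. the
similarity S(Y, X) of X to Y reached the threshold (default 0.9).  The
survivors of the reduction form a dominating set of this graph: every
removed proteome keeps at least one of its original out-neighbours in the
surviving set as its representative, so no information is lost outright.

Finding a minimum dominating set is NP-hard, so the reduction is a greedy
heuristic: nodes are ranked, the weakest removable node is eliminated, the
ranking is recomputed on the surviving subgraph, and the loop repeats until
no node can be removed without stranding an already-removed proteome.

The rank of a node is the quintuple (indegree, outdegree, priority score,
annotation level, previous redundancy state), compared lexicographically:
more proteomes redundant to you is better, being redundant to more
proteomes is worse, then reference status, curated-entry count and having
been non-redundant last run break ties.  Degrees are counted on the
surviving subgraph only.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .comparison import ComparisonRecord
from .model import ProteomeMetadata

DEFAULT_SIMILARITY_THRESHOLD = 0.9
#: Absolute tolerance on the edge threshold, guarding against float
#: representation of similarities sitting exactly at the cut-off.
THRESHOLD_TOLERANCE = 1e-12


@dataclass
class RedundancyGraph:
    """Directed graph of above-threshold proteome comparisons."""

    digraph: nx.DiGraph
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD

    @property
    def nodes(self) -> set[str]:
        return set(self.digraph.nodes)

    def metadata(self, node: str) -> ProteomeMetadata:
        return self.digraph.nodes[node]["metadata"]

    def out_neighbours(self, node: str) -> set[str]:
        return set(self.digraph.successors(node))

    def similarity(self, source: str, target: str) -> float:
        return self.digraph.edges[source, target]["similarity"]


@dataclass(frozen=True)
class RankVector:
    """Node rank: (indegree, outdegree, priority, annotation, previous state)."""

    indegree: int
    outdegree: int
    priority_score: int
    annotation_level: int
    previous_state: int

    def __post_init__(self) -> None:
        for name in ("indegree", "outdegree", "priority_score",
                     "annotation_level", "previous_state"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def strength_key(self) -> tuple[int, int, int, int, int]:
        """Sort key: lexicographically larger means higher priority to keep."""
        return (self.indegree, -self.outdegree, self.priority_score,
                self.annotation_level, self.previous_state)


def compare_rank(a: RankVector, b: RankVector) -> int:
    """Lexicographic rank comparison: 1 if a is higher, -1 if b, 0 on tie.

    Higher indegree wins; else lower outdegree; else higher priority score;
    else higher annotation level; else higher previous state.
    """
    ka, kb = a.strength_key(), b.strength_key()
    if ka > kb:
        return 1
    if ka < kb:
        return -1
    return 0


@dataclass
class ReductionState:
    """Bookkeeping of a (possibly partial) reduction.

    ``surviving_neighbours[r]`` holds, for each removed node r, the set of
    its original out-neighbours that are still surviving — r's candidate
    representatives; domination requires it never be emptied.
    ``represented[s]`` is the set of removed nodes that s represents.
    """

    surviving: set[str]
    removed: list[str] = field(default_factory=list)
    surviving_neighbours: dict[str, set[str]] = field(default_factory=dict)
    represented: dict[str, set[str]] = field(default_factory=dict)
    protected: set[str] = field(default_factory=set)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for node in self.surviving:
            self.represented.setdefault(node, set())

    def check_invariants(self, all_nodes: set[str]) -> None:
        removed_set = set(self.removed)
        assert self.surviving | removed_set == all_nodes
        assert not (self.surviving & removed_set)
        assert self.protected <= self.surviving
        for r in self.removed:
            assert self.surviving_neighbours[r], f"removed node {r} stranded"
            assert self.surviving_neighbours[r] <= self.surviving


def build_graph(comparisons: Iterable[ComparisonRecord],
                metadata: Mapping[str, ProteomeMetadata],
                threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
                ) -> RedundancyGraph:
    """Build the redundancy graph from performed comparisons.

    A performed comparison (subject A, query B) with S(A, B) >= threshold
    becomes the edge B -> A ("B is redundant to A").  All proteomes named
    by any comparison, plus all proteomes in ``metadata``, become nodes.
    """
    digraph = nx.DiGraph()
    for pid, meta in metadata.items():
        digraph.add_node(pid, metadata=meta)
    for record in comparisons:
        for pid in (record.subject_id, record.query_id):
            if pid not in digraph:
                raise KeyError(f"comparison references unknown proteome {pid!r}")
        if not record.performed:
            continue
        if record.similarity >= threshold - THRESHOLD_TOLERANCE:
            digraph.add_edge(record.query_id, record.subject_id,
                             similarity=record.similarity)
    return RedundancyGraph(digraph, threshold)


def rank_vector(graph: RedundancyGraph, state: ReductionState,
                node: str) -> RankVector:
    """Rank of a surviving node, with degrees counted among survivors only."""
    if node not in state.surviving:
        raise KeyError(f"node {node!r} is not surviving")
    g = graph.digraph
    indeg = sum(1 for p in g.predecessors(node) if p in state.surviving)
    outdeg = sum(1 for s in g.successors(node) if s in state.surviving)
    meta = graph.metadata(node)
    return RankVector(indeg, outdeg, meta.priority_score,
                      meta.annotation_level, meta.previous_state)


def removable(graph: RedundancyGraph, state: ReductionState,
              node: str) -> bool:
    """Whether a node can be eliminated without breaking domination.

    Requires: not protected; at least one surviving out-neighbour to
    represent it; and it is not the last surviving representative of any
    already-removed node.
    """
    if node not in state.surviving:
        raise KeyError(f"node {node!r} is not surviving")
    if node in state.protected:
        return False
    if not any(s in state.surviving for s in graph.digraph.successors(node)):
        return False
    for neighbours in state.surviving_neighbours.values():
        if node in neighbours and len(neighbours) == 1:
            return False
    return True


def select_weakest(graph: RedundancyGraph, state: ReductionState,
                   rng: random.Random | None = None) -> str | None:
    """Pick the removable node with the lowest rank, or None.

    Rank ties are broken by removing the node with the smaller represented
    set (keeping the node connected to the more comprehensive set of
    removed proteomes); remaining ties fall to the seeded generator.
    """
    candidates = [n for n in sorted(state.surviving)
                  if removable(graph, state, n)]
    if not candidates:
        return None
    keyed = [
        (rank_vector(graph, state, n).strength_key(),
         len(state.represented.get(n, ())), n)
        for n in candidates
    ]
    weakest_key = min(k[:2] for k in keyed)
    tied = [n for key, size, n in keyed if (key, size) == weakest_key]
    if len(tied) == 1:
        return tied[0]
    rng = rng if rng is not None else random.Random(state.rng_seed)
    return rng.choice(tied)


def remove_node(graph: RedundancyGraph, state: ReductionState,
                node: str) -> ReductionState:
    """Eliminate one removable node, transferring its representation.

    The node's surviving out-neighbours become its representatives (they
    gain a reference to it); the node stops being a candidate
    representative for every previously removed proteome.  Representation
    follows original direct edges only — the represented set a node had
    accumulated is not re-routed when the node itself is removed.
    """
    if not removable(graph, state, node):
        raise ValueError(f"node {node!r} is not removable")
    reps = {s for s in graph.digraph.successors(node) if s in state.surviving}
    state.surviving.discard(node)
    state.removed.append(node)
    state.surviving_neighbours[node] = reps
    for rep in reps:
        state.represented.setdefault(rep, set()).add(node)
    for r, neighbours in state.surviving_neighbours.items():
        if r != node:
            neighbours.discard(node)
    return state


def reduce(graph: RedundancyGraph, protected: set[str] | None = None,
           seed: int = 0) -> ReductionState:
    """Iteratively eliminate weakest nodes until none is removable.

    The final surviving set dominates the graph: every removed node has an
    original out-edge to a survivor.  Protected nodes (e.g. reference
    proteomes) always survive.  Deterministic for a given seed.
    """
    protected = set(protected or ())
    missing = protected - graph.nodes
    if missing:
        raise KeyError(f"protected nodes not in graph: {sorted(missing)}")
    state = ReductionState(surviving=set(graph.nodes), protected=protected,
                           rng_seed=seed)
    rng = random.Random(seed)
    while True:
        weakest = select_weakest(graph, state, rng)
        if weakest is None:
            break
        remove_node(graph, state, weakest)
    state.check_invariants(graph.nodes)
    return state


def is_dominating_set(graph: RedundancyGraph, survivors: set[str]) -> bool:
    """Every node outside ``survivors`` has an out-edge into it."""
    return all(
        any(s in survivors for s in graph.digraph.successors(node))
        for node in graph.nodes - survivors
    )


def brute_force_dominating_set(graph: RedundancyGraph,
                               protected: set[str] | None = None) -> int:
    """Exact minimum dominating-set size by exhaustive search (test oracle).

    Only feasible for small graphs (n <= 15).  The protected set is forced
    into every candidate subset.
    """
    nodes = sorted(graph.nodes)
    if len(nodes) > 15:
        raise ValueError("brute force limited to graphs with <= 15 nodes")
    protected = set(protected or ())
    free = [n for n in nodes if n not in protected]
    for extra in range(len(free) + 1):
        for combo in combinations(free, extra):
            candidate = protected | set(combo)
            if is_dominating_set(graph, candidate):
                return len(candidate)
    return len(nodes)  # unreachable: the full set always dominates


def graph_from_edges(edges: Iterable[tuple[str, str]],
                     nodes: Iterable[str] = (),
                     metadata: Mapping[str, ProteomeMetadata] | None = None,
                     threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
                     similarity: float = 1.0) -> RedundancyGraph:
    """Convenience constructor from explicit redundant-to edges."""
    metadata = dict(metadata or {})
    digraph = nx.DiGraph()
    edge_list = list(edges)
    for node in list(nodes) + [n for e in edge_list for n in e]:
        if node not in digraph:
            digraph.add_node(
                node, metadata=metadata.get(node, ProteomeMetadata()))
    for source, target in edge_list:
        if source == target:
            raise ValueError("self-edges are not allowed")
        digraph.add_edge(source, target, similarity=similarity)
    return RedundancyGraph(digraph, threshold)


def export_graph(graph: RedundancyGraph, path: str | Path) -> None:
    """Write the edge list as TSV: source (redundant-to), target, similarity."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source_id\ttarget_id\tsimilarity\n")
        for source, target in sorted(graph.digraph.edges):
            sim = graph.digraph.edges[source, target]["similarity"]
            fh.write(f"{source}\t{target}\t{sim:.12g}\n")


def import_graph(path: str | Path,
                 metadata: Mapping[str, ProteomeMetadata] | None = None,
                 threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
                 ) -> RedundancyGraph:
    """Read a TSV edge list back into a graph (lossless to 12 significant digits)."""
    metadata = dict(metadata or {})
    digraph = nx.DiGraph()
    for pid, meta in metadata.items():
        digraph.add_node(pid, metadata=meta)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != ["source_id", "target_id", "similarity"]:
            raise ValueError(f"{path}:1: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            source, target, sim_text = parts
            try:
                sim = float(sim_text)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: bad similarity {sim_text!r}") from exc
            if not 0.0 <= sim <= 1.0:
                raise ValueError(
                    f"{path}:{lineno}: similarity {sim} outside [0, 1]")
            for node in (source, target):
                if node not in digraph:
                    digraph.add_node(
                        node, metadata=metadata.get(node, ProteomeMetadata()))
            digraph.add_edge(source, target, similarity=sim)
    return RedundancyGraph(digraph, threshold)
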