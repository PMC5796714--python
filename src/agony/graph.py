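"""Directed graphs, rankings, and the generalized agony score.

A *ranking* is an ordered partition of the nodes of a directed graph into
integer-indexed classes.  Given a ranking ``r``, an edge ``(u, v)`` is
*forward* when ``r(v) > r(u)`` and *backward* otherwise (same-class edges
count as backward).  The agony of the ranking charges every backward edge a
penalty ``f_d(r(u) - r(v)) = (r(u) - r(v) + 1) ** d`` that grows with the
rank distance spanned against the hierarchy; forward edges are free.
Minimising agony over all rankings yields the hierarchy of the graph,
``h_d = 1 - A_d / m``, which is 1 for a perfectly layered graph and 0 when
no ordering beats putting every node in a single class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "DirectedGraph",
    "Ranking",
    "PenaltySpec",
    "penalty",
    "agony",
    "hierarchy",
    "classify_edges",
    "canonicalize",
    "sorted_nodes",
]


def sorted_nodes(nodes: Iterable) -> list:
    """Deterministic ordering of (possibly heterogeneous) node identifiers."""
    nodes = list(nodes)
    try:
        return sorted(nodes)
    except TypeError:
        return sorted(nodes, key=lambda v: (type(v).__name__, str(v)))


@dataclass(frozen=True)
class PenaltySpec:
    """Backward-edge penalty ``f_d(x) = (x + 1)**d`` for ``x >= 0``, else 0.

    The ``+1`` makes same-class edges (rank difference 0) cost one unit, so
    the trivial one-class ranking never wins by default.  ``d`` tunes how
    harshly long backward jumps are punished: ``d = 0`` counts backward
    edges (the feedback-arc-set objective), ``d = 1`` is the piecewise
    linear score with a polynomial exact solver, ``d > 1`` privileges only
    very strong hierarchies.  Any real ``d >= 0`` is accepted.
    """

    d: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.d) or self.d < 0:
            raise ValueError(f"penalty exponent d must be a real >= 0, got {self.d}")

    def cost(self, x):
        """Vectorised penalty of integer rank difference(s) ``x``."""
        x = np.asarray(x, dtype=float)
        out = np.where(x >= 0, np.power(x + 1.0, self.d, where=x >= 0, out=np.ones_like(x)), 0.0)
        return out if out.shape else float(out)


def penalty(spec: PenaltySpec, x) -> float:
    """Penalty ``f_d(x)`` of a single rank difference ``x``."""
    return spec.cost(x)


class DirectedGraph:
    """Simple binary directed graph: no self-loops, no parallel edges.

    Parameters
    ----------
    edges : iterable of (u, v) pairs
    nodes : optional iterable of node ids; defaults to the edge endpoints.
        Extra isolated nodes may be supplied here.
    """

    __slots__ = ("_nodes", "_edges", "_node_list")

    def __init__(self, edges: Iterable[Tuple] = (), nodes: Iterable = ()) -> None:
        edge_set = set()
        node_set = set(nodes)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r} is not allowed")
            edge_set.add((u, v))
            node_set.add(u)
            node_set.add(v)
        self._nodes = frozenset(node_set)
        self._edges = frozenset(edge_set)
        self._node_list = sorted_nodes(node_set)

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> frozenset:
        return self._nodes

    @property
    def node_list(self) -> list:
        """Nodes in deterministic sorted order."""
        return list(self._node_list)

    @property
    def edges(self) -> frozenset:
        return self._edges

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, node) -> bool:
        return node in self._nodes

    def __eq__(self, other) -> bool:
        if not isinstance(other, DirectedGraph):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __hash__(self) -> int:
        return hash((self._nodes, self._edges))

    def __repr__(self) -> str:
        return f"DirectedGraph(N={self.n_nodes}, m={self.n_edges})"

    # -- derived views -----------------------------------------------------
    def subgraph(self, nodes: Iterable) -> "DirectedGraph":
        keep = set(nodes)
        missing = keep - self._nodes
        if missing:
            raise KeyError(f"nodes not in graph: {sorted_nodes(missing)}")
        edges = [(u, v) for (u, v) in self._edges if u in keep and v in keep]
        return DirectedGraph(edges, nodes=keep)

    def edge_arrays(self, index: Mapping = None) -> Tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as two integer arrays, using ``index`` (node -> int)
        or the sorted-node positions by default.  Deterministic order."""
        if index is None:
            index = {v: i for i, v in enumerate(self._node_list)}
        es = sorted_nodes(self._edges) if self._edges else []
        if not es:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        src = np.fromiter((index[u] for u, _ in es), dtype=np.int64, count=len(es))
        dst = np.fromiter((index[v] for _, v in es), dtype=np.int64, count=len(es))
        return src, dst

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self._node_list)
        g.add_edges_from(sorted_nodes(self._edges))
        return g


class Ranking:
    """Ordered partition of nodes via a rank map ``node -> class index >= 1``.

    Rank values need not be contiguous; :func:`canonicalize` relabels them to
    ``1..R``.  Agony is well defined for any integer ranks, and removing the
    gaps can only lower it (backward distances shrink, forward edges stay
    forward).
    """

    __slots__ = ("_rank",)

    def __init__(self, rank: Mapping) -> None:
        clean: Dict = {}
        for node, r in rank.items():
            ri = int(r)
            if ri != r or ri < 1:
                raise ValueError(f"rank of node {node!r} must be an integer >= 1, got {r!r}")
            clean[node] = ri
        self._rank = clean

    @classmethod
    def from_classes(cls, classes: Sequence[Iterable]) -> "Ranking":
        """Build from an ordered sequence of node groups (class 1 first)."""
        rank = {}
        for i, group in enumerate(classes, start=1):
            for node in group:
                if node in rank:
                    raise ValueError(f"node {node!r} appears in more than one class")
                rank[node] = i
        return cls(rank)

    @classmethod
    def trivial(cls, nodes: Iterable) -> "Ranking":
        return cls({v: 1 for v in nodes})

    # -- accessors ---------------------------------------------------------
    def __getitem__(self, node) -> int:
        return self._rank[node]

    def __contains__(self, node) -> bool:
        return node in self._rank

    def __len__(self) -> int:
        return len(self._rank)

    def __iter__(self):
        return iter(self._rank)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Ranking):
            return NotImplemented
        return self._rank == other._rank

    def __hash__(self):
        return hash(frozenset(self._rank.items()))

    def __repr__(self) -> str:
        return f"Ranking(N={len(self._rank)}, R={self.n_classes})"

    @property
    def rank(self) -> Dict:
        return dict(self._rank)

    @property
    def nodes(self) -> frozenset:
        return frozenset(self._rank)

    @property
    def n_classes(self) -> int:
        """Number of distinct (occupied) rank values."""
        return len(set(self._rank.values()))

    @property
    def class_sizes(self) -> list:
        """Sizes of the occupied classes, in increasing rank order."""
        counts: Dict[int, int] = {}
        for r in self._rank.values():
            counts[r] = counts.get(r, 0) + 1
        return [counts[r] for r in sorted(counts)]

    def classes(self) -> Dict[int, list]:
        """Map rank value -> sorted list of member nodes."""
        out: Dict[int, list] = {}
        for node, r in self._rank.items():
            out.setdefault(r, []).append(node)
        return {r: sorted_nodes(members) for r, members in sorted(out.items())}

    @property
    def is_canonical(self) -> bool:
        vals = set(self._rank.values())
        return vals == set(range(1, len(vals) + 1)) if vals else True

    def canonicalize(self) -> "Ranking":
        return canonicalize(self)

    def invert(self) -> "Ranking":
        """Reverse the class order: ``r -> R - r + 1`` (canonicalises first)."""
        can = self.canonicalize()
        R = can.n_classes
        return Ranking({v: R - r + 1 for v, r in can._rank.items()})

    def labels(self, order: Sequence) -> np.ndarray:
        """Rank values aligned to the given node order."""
        return np.fromiter((self._rank[v] for v in order), dtype=np.int64, count=len(order))

    def restrict(self, nodes: Iterable) -> "Ranking":
        keep = set(nodes)
        return Ranking({v: r for v, r in self._rank.items() if v in keep})


def canonicalize(r: Ranking) -> Ranking:
    """Relabel classes to consecutive integers ``1..R`` preserving order."""
    values = sorted(set(r.rank.values()))
    remap = {old: new for new, old in enumerate(values, start=1)}
    return Ranking({v: remap[old] for v, old in r.rank.items()})


@dataclass(frozen=True)
class AgonyResult:
    """A ranking together with its agony and hierarchy for exponent ``d``."""

    ranking: Ranking
    agony: float
    hierarchy: float
    d: float
    method: str = ""
    optimal: bool = False
    info: dict = field(default_factory=dict, compare=False)


def _require_ranked(G: DirectedGraph, r: Ranking) -> None:
    for u, v in G.edges:
        if u not in r:
            raise KeyError(f"node {u!r} has no rank")
        if v not in r:
            raise KeyError(f"node {v!r} has no rank")


def agony(G: DirectedGraph, r: Ranking, spec: PenaltySpec = PenaltySpec(1.0)) -> float:
    """Agony of ranking ``r`` on ``G``: sum of ``f_d(r(u) - r(v))`` over edges."""
    if G.n_edges == 0:
        for v in G.nodes:
            if v not in r:
                raise KeyError(f"node {v!r} has no rank")
        return 0.0
    _require_ranked(G, r)
    order = G.node_list
    index = {v: i for i, v in enumerate(order)}
    src, dst = G.edge_arrays(index)
    labels = r.labels(order)
    diffs = labels[src] - labels[dst]
    return float(np.sum(spec.cost(diffs)))


def hierarchy(G: DirectedGraph, r: Ranking, spec: PenaltySpec = PenaltySpec(1.0)) -> float:
    """Hierarchy ``1 - A_d(G, r)/m``.  Undefined (error) on edgeless graphs.

    Without minimisation this may be negative: a strongly violated ranking
    can be worse than the trivial single-class one.
    """
    if G.n_edges == 0:
        raise ValueError("hierarchy is undefined for a graph with no edges")
    return 1.0 - agony(G, r, spec) / G.n_edges


def classify_edges(G: DirectedGraph, r: Ranking) -> Dict[Tuple, str]:
    """Label every edge ``forward`` (strictly up-rank) or ``backward``."""
    _require_ranked(G, r)
    return {(u, v): ("forward" if r[v] > r[u] else "backward") for (u, v) in G.edges}
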