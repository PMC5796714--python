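"""Agony minimisation over rankings.

Four routes are provided:

``brute``
    Exhaustive enumeration of every ordered partition of the node set
    (the ordered Bell number of candidates), exact for any penalty
    exponent ``d``.  Only feasible for small graphs; it is the oracle the
    other solvers are validated against.
``flow_d1``
    Exact polynomial solver for ``d = 1``.  Minimising
    ``sum_e max(r(u) - r(v) + 1, 0)`` over integer rank labels is the dual
    of a minimum-cost circulation; we solve it as a linear program whose
    constraint matrix is a network (totally unimodular) matrix, so the LP
    optimum is attained at integral ranks.  The graph is first split into
    strongly connected components: edges between components can always be
    oriented forward at zero cost, so only non-trivial components need the
    LP and a DAG costs nothing.
``ilp``
    Mixed-integer formulation for any ``d >= 1`` (the penalty restricted
    to integer rank differences is convex there, so it linearises as a
    maximum of secant segments).  Exact but only practical for modest N.
``greedy_fas``
    Deterministic linear-arrangement heuristic for ``d = 0`` (minimum
    feedback arc set, NP-hard): repeatedly peel sinks/sources and
    otherwise the node with maximal out-degree minus in-degree.  The
    returned order (or its reversal, whichever is better) leaves at most
    ``m/2`` backward edges.

Ties among co-optimal rankings are broken toward fewer classes by a
greedy adjacent-class merge pass, then deterministically by the solver
construction; for a DAG the minimum-class perfect ranking (longest-path
layering) is returned directly.
"""

from __future__ import annotations

from itertools import permutations
from typing import Iterator, List, Optional

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .graph import (
    AgonyResult,
    DirectedGraph,
    PenaltySpec,
    Ranking,
    agony,
    canonicalize,
    sorted_nodes,
)

__all__ = ["minimize_agony", "minimize_agony_bruteforce", "SolverError"]

DEFAULT_BRUTE_CAP = 8


class SolverError(RuntimeError):
    """Raised for infeasible method/exponent combinations or solver failures."""

    def __init__(self, message: str, incumbent: Optional[AgonyResult] = None):
        super().__init__(message)
        self.incumbent = incumbent


def _result(G: DirectedGraph, ranking: Ranking, spec: PenaltySpec, method: str,
            optimal: bool, **info) -> AgonyResult:
    a = agony(G, ranking, spec)
    h = 1.0 - a / G.n_edges if G.n_edges else 1.0
    return AgonyResult(ranking=ranking, agony=a, hierarchy=h, d=spec.d,
                       method=method, optimal=optimal, info=info)


# ---------------------------------------------------------------------------
# brute force
# ---------------------------------------------------------------------------

def _set_partitions(n: int) -> Iterator[List[List[int]]]:
    """All partitions of range(n) into unordered blocks (restricted growth)."""

    def rec(i: int, blocks: List[List[int]]):
        if i == n:
            yield [list(b) for b in blocks]
            return
        for b in blocks:
            b.append(i)
            yield from rec(i + 1, blocks)
            b.pop()
        blocks.append([i])
        yield from rec(i + 1, blocks)
        blocks.pop()

    yield from rec(0, [])


def minimize_agony_bruteforce(G: DirectedGraph, spec: PenaltySpec = PenaltySpec(1.0),
                              max_nodes: int = DEFAULT_BRUTE_CAP) -> AgonyResult:
    """Exact minimum agony by enumerating every ordered partition.

    Ties are broken toward the fewest classes, then the lexicographically
    smallest rank vector in sorted-node order.
    """
    N = G.n_nodes
    if N > max_nodes:
        raise SolverError(
            f"brute force caps at {max_nodes} nodes (got {N}); "
            "use the flow_d1 or ilp solver instead, or raise max_nodes")
    order = sorted_nodes(G.nodes)
    index = {v: i for i, v in enumerate(order)}
    src, dst = G.edge_arrays(index)
    if N == 0:
        return AgonyResult(Ranking({}), 0.0, 1.0, spec.d, "brute", True)

    best_key = None
    best_ranks: Optional[np.ndarray] = None
    ranks = np.empty(N, dtype=np.int64)
    for blocks in _set_partitions(N):
        k = len(blocks)
        for perm in permutations(range(k)):
            for pos, bi in enumerate(perm, start=1):
                for node in blocks[bi]:
                    ranks[node] = pos
            diffs = ranks[src] - ranks[dst]
            a = float(np.sum(spec.cost(diffs)))
            key = (a, k, tuple(ranks))
            if best_key is None or key < best_key:
                best_key = key
                best_ranks = ranks.copy()

    ranking = canonicalize(Ranking({order[i]: int(best_ranks[i]) for i in range(N)}))
    return _result(G, ranking, spec, "brute", optimal=True)


# ---------------------------------------------------------------------------
# exact d = 1 (LP dual of min-cost circulation)
# ---------------------------------------------------------------------------

def _solve_d1_lp(src: np.ndarray, dst: np.ndarray, n: int) -> np.ndarray:
    """Integral optimal rank labels (0-based) for d=1 on one strongly
    connected component, via the totally unimodular LP relaxation."""
    m = len(src)
    rows = np.repeat(np.arange(m), 3)
    cols = np.concatenate([np.stack([src, dst, n + np.arange(m)], axis=1).ravel()])
    vals = np.tile(np.array([1.0, -1.0, -1.0]), m)
    A = sparse.csc_matrix((vals, (rows, cols)), shape=(m, n + m))
    c = np.concatenate([np.zeros(n), np.ones(m)])
    bounds = [(0, n)] * n + [(0, None)] * m
    res = linprog(c, A_ub=A, b_ub=-np.ones(m), bounds=bounds, method="highs-ds")
    if res.status != 0:
        raise SolverError(f"d=1 LP failed with status {res.status}: {res.message}")
    ranks = np.round(res.x[:n]).astype(np.int64)
    # TU matrix => vertex optimum is integral; guard against drift anyway.
    drift = np.max(np.abs(res.x[:n] - ranks)) if n else 0.0
    if drift > 1e-6:
        raise SolverError(f"non-integral LP vertex (drift {drift:.2e})")
    return ranks - ranks.min()


def _dag_layering(g: "nx.DiGraph") -> dict:
    """Longest-path layering: minimum-class ranking with zero agony on a DAG."""
    level = {}
    for v in nx.topological_sort(g):
        preds = [level[u] for u in g.predecessors(v)]
        level[v] = 1 + max(preds, default=0)
    return level


def _minimize_flow_d1(G: DirectedGraph, spec: PenaltySpec) -> AgonyResult:
    if G.n_edges == 0:
        return _result(G, Ranking.trivial(G.nodes), spec, "flow_d1", True)
    g = G.to_networkx()
    if nx.is_directed_acyclic_graph(g):
        ranking = canonicalize(Ranking(_dag_layering(g)))
        return _result(G, ranking, spec, "flow_d1", True, dag=True)

    # Solve each strongly connected component separately; inter-component
    # edges follow the condensation's topological order at zero cost.
    comps = list(nx.strongly_connected_components(g))
    cond = nx.condensation(g, scc=comps)
    rank = {}
    width = {}
    offset = {}
    for ci in nx.topological_sort(cond):
        members = sorted_nodes(cond.nodes[ci]["members"])
        off = max((offset[p] + width[p] for p in cond.predecessors(ci)), default=0)
        offset[ci] = off
        if len(members) == 1:
            rank[members[0]] = off + 1
            width[ci] = 1
            continue
        sub = g.subgraph(members)
        index = {v: i for i, v in enumerate(members)}
        es = sorted_nodes(sub.edges())
        src = np.fromiter((index[u] for u, _ in es), dtype=np.int64, count=len(es))
        dst = np.fromiter((index[v] for _, v in es), dtype=np.int64, count=len(es))
        local = _solve_d1_lp(src, dst, len(members))
        for v, r in zip(members, local):
            rank[v] = off + 1 + int(r)
        width[ci] = int(local.max()) + 1

    ranking = canonicalize(Ranking(rank))
    ranking = _merge_pass(G, ranking, spec)
    return _result(G, ranking, spec, "flow_d1", True, components=len(comps))


def _merge_pass(G: DirectedGraph, ranking: Ranking, spec: PenaltySpec) -> Ranking:
    """Greedily merge adjacent classes while the agony is unchanged.

    A cheap stand-in for the minimal-class selection among co-optimal
    rankings; it never changes the agony value.
    """
    order = G.node_list
    index = {v: i for i, v in enumerate(order)}
    src, dst = G.edge_arrays(index)
    labels = ranking.canonicalize().labels(order).astype(np.int64)

    def cost(lab: np.ndarray) -> float:
        return float(np.sum(spec.cost(lab[src] - lab[dst])))

    base = cost(labels)
    changed = True
    while changed:
        changed = False
        R = labels.max() if len(labels) else 0
        k = 1
        while k < R:
            trial = np.where(labels > k, labels - 1, labels)
            if cost(trial) <= base + 1e-9:
                labels = trial
                R -= 1
                changed = True
            else:
                k += 1
    return Ranking({order[i]: int(labels[i]) for i in range(len(order))})


# ---------------------------------------------------------------------------
# general d >= 1 mixed-integer program
# ---------------------------------------------------------------------------

def _minimize_ilp(G: DirectedGraph, spec: PenaltySpec,
                  time_limit: Optional[float] = None) -> AgonyResult:
    if spec.d < 1:
        raise SolverError(
            "the integer program linearises the penalty as a maximum of "
            "secants, which requires a convex integer profile (d >= 1); "
            "use brute force for 0 <= d < 1")
    if G.n_edges == 0:
        return _result(G, Ranking.trivial(G.nodes), spec, "ilp", True)
    order = G.node_list
    n = len(order)
    index = {v: i for i, v in enumerate(order)}
    src, dst = G.edge_arrays(index)
    m = len(src)

    # variables: ranks r_0..r_{n-1} (integer, 0..n-1), slacks z_e >= 0
    xs = np.arange(-1, n - 1)                       # breakpoints
    f = np.where(xs + 1 >= 0, (np.abs(xs + 1) + 1.0) ** spec.d, 0.0)
    f = np.concatenate([[0.0], f])                  # f at xs and xs+1
    slopes = f[1:] - f[:-1]
    inter = f[1:] - slopes * (xs + 1)               # line value at 0

    rows, cols, vals, rhs = [], [], [], []
    row = 0
    for e in range(m):
        for k in range(len(xs)):
            # z_e - slope*(r_u - r_v) >= inter_k
            rows += [row, row, row]
            cols += [n + e, int(src[e]), int(dst[e])]
            vals += [1.0, -slopes[k], slopes[k]]
            rhs.append(inter[k])
            row += 1
    A = sparse.csc_matrix((vals, (rows, cols)), shape=(row, n + m))
    c = np.concatenate([np.zeros(n), np.ones(m)])
    integrality = np.concatenate([np.ones(n), np.zeros(m)])
    lb = np.concatenate([np.zeros(n), np.zeros(m)])
    ub = np.concatenate([np.full(n, n - 1.0), np.full(m, np.inf)])
    options = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(c, constraints=LinearConstraint(A, np.asarray(rhs), np.inf),
               integrality=integrality, bounds=Bounds(lb, ub), options=options)
    if res.status != 0:
        incumbent = None
        if res.x is not None:
            ranks = np.round(res.x[:n]).astype(np.int64)
            rk = canonicalize(Ranking({order[i]: int(ranks[i]) + 1 for i in range(n)}))
            incumbent = _result(G, rk, spec, "ilp", optimal=False, status=res.status)
        raise SolverError(f"MILP did not reach optimality (status {res.status}: "
                          f"{res.message})", incumbent=incumbent)
    ranks = np.round(res.x[:n]).astype(np.int64)
    ranking = canonicalize(Ranking({order[i]: int(ranks[i]) + 1 for i in range(n)}))
    ranking = _merge_pass(G, ranking, spec)
    return _result(G, ranking, spec, "ilp", optimal=True)


# ---------------------------------------------------------------------------
# d = 0 greedy feedback-arc-set heuristic
# ---------------------------------------------------------------------------

def _minimize_greedy_fas(G: DirectedGraph, spec: PenaltySpec) -> AgonyResult:
    """Eades-Lin-Smyth style greedy linear arrangement, one node per class."""
    g = G.to_networkx()
    left: List = []
    right: List = []
    g = g.copy()
    while g.number_of_nodes():
        sinks = sorted_nodes([v for v in g if g.out_degree(v) == 0])
        if sinks:
            right.append(sinks[0])
            g.remove_node(sinks[0])
            continue
        sources = sorted_nodes([v for v in g if g.in_degree(v) == 0])
        if sources:
            left.append(sources[0])
            g.remove_node(sources[0])
            continue
        v = max(sorted_nodes(g.nodes),
                key=lambda u: g.out_degree(u) - g.in_degree(u))
        left.append(v)
        g.remove_node(v)
    order = left + right[::-1]

    def backward(seq: List) -> int:
        pos = {v: i for i, v in enumerate(seq)}
        return sum(1 for (u, v) in G.edges if pos[u] >= pos[v])

    if backward(order[::-1]) < backward(order):
        order = order[::-1]
    ranking = Ranking({v: i + 1 for i, v in enumerate(order)})
    return _result(G, ranking, spec, "greedy_fas", optimal=False)


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def minimize_agony(G: DirectedGraph, spec: PenaltySpec = PenaltySpec(1.0),
                   method: str = "auto", brute_cap: int = DEFAULT_BRUTE_CAP,
                   time_limit: Optional[float] = None) -> AgonyResult:
    """Find a ranking minimising the generalized agony ``A_d``.

    ``method`` is one of ``auto``, ``flow_d1`` (exact, d=1 only), ``ilp``
    (exact, d>=1), ``brute`` (exact, any d, small N), ``greedy_fas``
    (heuristic, d=0 only).  ``auto`` picks the exact solver for the given
    exponent, falling back to brute force below ``brute_cap`` nodes and to
    the FAS heuristic at ``d=0``.
    """
    d = spec.d
    if method == "auto":
        if d == 1:
            method = "flow_d1"
        elif G.n_nodes <= brute_cap:
            method = "brute"
        elif d == 0:
            method = "greedy_fas"
        elif d > 1:
            method = "ilp"
        else:
            raise SolverError(
                f"no scalable exact solver for 0 < d < 1 (d={d}); "
                f"N={G.n_nodes} exceeds the brute-force cap {brute_cap}")
    if method == "flow_d1":
        if d != 1:
            raise SolverError(f"flow_d1 requires d=1, got d={d}")
        return _minimize_flow_d1(G, spec)
    if method == "brute":
        return minimize_agony_bruteforce(G, spec, max_nodes=brute_cap)
    if method == "ilp":
        return _minimize_ilp(G, spec, time_limit=time_limit)
    if method == "greedy_fas":
        if d != 0:
            raise SolverError(f"greedy_fas requires d=0, got d={d}")
        return _minimize_greedy_fas(G, spec)
    raise SolverError(f"unknown method {method!r}")
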