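"""Ranked Stochastic Block Model (RSBM).

A directed stochastic block model whose ``R x R`` affinity matrix encodes a
planted ranking hierarchy: class ``i`` sends edges to the next class up
(``j = i + 1``) with probability ``p``, to more distant higher classes
(``j > i + 1``) with probability ``q``, and every other ordered pair —
same-class and down-rank — carries a "noise" backward edge with
probability ``s``.  The planted ranking assigns class ``C_i`` rank ``i``.

Two named parameter regimes recur throughout:

* *twitter-like*: ``p >= q > s`` — forward links may reach any higher class;
* *military-like*: ``q = 0`` — forward links only reach the direct superior
  class.

A parameter set is a *valid hierarchy* when the expected number of backward
edges does not exceed the expected number of forward edges, which for
uniform class sizes reduces to ``s <= s_max`` with::

    s_max = 2(R-1)/(R(R+1)) * p + (R-2)(R-1)/(R(R+1)) * q

This module is also the synthetic-fixture generator for the whole package:
samplers are seeded and bit-reproducible.

A bookkeeping subtlety: the pair-count vector ``b_k = sum_i n_i n_{i+k}``
counts ``n_i ** 2`` ordered same-class pairs at ``k = 0``, slightly
overcounting the ``n_i (n_i - 1)`` ordered pairs of *distinct* nodes.  The
closed-form theory (see :mod:`agony.theory`) keeps the ``n_i ** 2``
ensemble convention; the sampler and the exact expected-edge-count matrix
here use ``n_i (n_i - 1)``.  The difference is ``O(1/n_i)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .graph import DirectedGraph, Ranking

__all__ = ["RSBMParams", "BlockCounts", "affinity_matrix", "s_max", "sample",
           "block_counts", "HierarchyConstraintWarning"]


class HierarchyConstraintWarning(UserWarning):
    """The backward-link probability exceeds the valid-hierarchy bound."""


@dataclass(frozen=True)
class RSBMParams:
    """RSBM(p, q, s, R, {n_i}) parameter set.

    Parameters
    ----------
    p, q, s : float
        Forward-to-adjacent, forward-to-distant and backward link
        probabilities, each in [0, 1].
    R : int
        Number of planted classes (>= 1).
    n : int, optional
        Uniform class size; shortcut for ``class_sizes = [n] * R``.
    class_sizes : sequence of int, optional
        Explicit class sizes (overrides ``n``).
    """

    p: float
    q: float
    s: float
    R: int
    n: Optional[int] = None
    class_sizes: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        for name in ("p", "q", "s"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {val}")
        if self.R < 1 or int(self.R) != self.R:
            raise ValueError(f"R must be an integer >= 1, got {self.R}")
        if self.class_sizes is not None:
            sizes = tuple(int(x) for x in self.class_sizes)
        elif self.n is not None:
            sizes = (int(self.n),) * self.R
        else:
            raise ValueError("provide either n (uniform class size) or class_sizes")
        if len(sizes) != self.R:
            raise ValueError(f"class_sizes has {len(sizes)} entries for R={self.R}")
        if any(x < 1 for x in sizes):
            raise ValueError("all class sizes must be >= 1")
        object.__setattr__(self, "class_sizes", sizes)
        object.__setattr__(self, "n", sizes[0] if len(set(sizes)) == 1 else None)
        if self.R >= 2 and not self.is_valid_hierarchy:
            warnings.warn(
                f"s={self.s} exceeds the valid-hierarchy bound s_max="
                f"{s_max(self):.6g}: expected backward edges outnumber forward ones",
                HierarchyConstraintWarning, stacklevel=2)

    # -- derived quantities ------------------------------------------------
    @property
    def N(self) -> int:
        return int(sum(self.class_sizes))

    @property
    def uniform(self) -> bool:
        return len(set(self.class_sizes)) == 1

    @property
    def a(self) -> Optional[int]:
        """``log2 R`` when ``R`` is a power of two, else ``None``."""
        a = self.R.bit_length() - 1
        return a if (1 << a) == self.R else None

    @property
    def is_valid_hierarchy(self) -> bool:
        """Expected forward edges >= expected backward edges (pair-count
        convention ``b_0 = sum n_i^2``)."""
        b = _b_vector(self.class_sizes)
        backward = self.s * b.sum()
        forward = self.p * b[1] + self.q * b[2:].sum() if self.R >= 2 else 0.0
        return bool(backward <= forward + 1e-12)

    @property
    def regime(self) -> str:
        """``military`` (q = 0), ``twitter`` (p >= q > s), or ``other``."""
        if self.q == 0:
            return "military"
        if self.p >= self.q > self.s:
            return "twitter"
        return "other"


def _b_vector(sizes: Sequence[int]) -> np.ndarray:
    """Pair-count vector ``b_k = sum_{i} n_i n_{i+k}``, ``k = 0..R-1``."""
    n = np.asarray(sizes, dtype=float)
    R = len(n)
    return np.array([np.dot(n[: R - k], n[k:]) for k in range(R)])


def affinity_matrix(params: RSBMParams) -> np.ndarray:
    """The R x R matrix C: p on the first superdiagonal, q above it, s
    on and below the diagonal."""
    R = params.R
    C = np.full((R, R), params.s)
    iu = np.triu_indices(R, k=2)
    C[iu] = params.q
    idx = np.arange(R - 1)
    C[idx, idx + 1] = params.p
    return C


def s_max(params: RSBMParams) -> float:
    """Largest backward-link probability compatible with a valid hierarchy.

    Uniform class sizes admit the closed form
    ``2(R-1)p/(R(R+1)) + (R-2)(R-1)q/(R(R+1))``; general sizes solve the
    pair-count inequality ``s * sum_k b_k <= p b_1 + q sum_{k>=2} b_k``.
    """
    R = params.R
    if R < 2:
        raise ValueError("s_max requires at least two classes")
    if params.uniform:
        return (2 * (R - 1) * params.p + (R - 2) * (R - 1) * params.q) / (R * (R + 1))
    b = _b_vector(params.class_sizes)
    return float((params.p * b[1] + params.q * b[2:].sum()) / b.sum())


@dataclass(frozen=True)
class BlockCounts:
    """Pair counts and expected per-block edge counts.

    ``b[k]`` uses the ensemble convention (``b_0 = sum n_i^2``);
    ``expected_m[i, j]`` is the exact expectation ``n_i n_j c_ij`` off the
    diagonal and ``n_i (n_i - 1) s`` on it.
    """

    b: np.ndarray = field(repr=False)
    expected_m: np.ndarray = field(repr=False)

    @property
    def expected_total(self) -> float:
        return float(self.expected_m.sum())


def block_counts(params: RSBMParams) -> BlockCounts:
    sizes = np.asarray(params.class_sizes, dtype=float)
    C = affinity_matrix(params)
    em = np.outer(sizes, sizes) * C
    np.fill_diagonal(em, sizes * (sizes - 1) * params.s)
    return BlockCounts(b=_b_vector(params.class_sizes), expected_m=em)


def planted_ranking(params: RSBMParams) -> Ranking:
    """The planted ranking on nodes ``0..N-1`` laid out class by class."""
    rank = {}
    node = 0
    for i, size in enumerate(params.class_sizes, start=1):
        for _ in range(size):
            rank[node] = i
            node += 1
    return Ranking(rank)


def sample(params: RSBMParams, seed) -> Tuple[DirectedGraph, Ranking]:
    """Draw one RSBM realisation; returns the graph and its planted ranking.

    Each ordered pair of distinct nodes carries an edge independently with
    the probability given by the affinity matrix (no self-loops).  For
    speed a binomial edge count is drawn per block pair and the edges are
    then placed uniformly without replacement within the block, which is
    distributionally identical to per-pair Bernoulli sampling.  The same
    ``seed`` reproduces the same graph bit for bit.
    """
    rng = np.random.default_rng(seed)
    sizes = list(params.class_sizes)
    starts = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
    C = affinity_matrix(params)
    edges: List[Tuple[int, int]] = []
    for i in range(params.R):
        ni = sizes[i]
        for j in range(params.R):
            nj = sizes[j]
            prob = C[i, j]
            if i == j:
                pairs = ni * (ni - 1)
            else:
                pairs = ni * nj
            if prob == 0.0 or pairs == 0:
                continue
            count = rng.binomial(pairs, prob)
            if count == 0:
                continue
            idx = rng.choice(pairs, size=count, replace=False)
            if i == j:
                u = idx // (ni - 1)
                off = idx % (ni - 1)
                v = off + (off >= u)
            else:
                u = idx // nj
                v = idx % nj
            src = starts[i] + u
            dst = starts[j] + v
            edges.extend(zip(src.tolist(), dst.tolist()))
    G = DirectedGraph(edges, nodes=range(params.N))
    return G, planted_ranking(params)
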