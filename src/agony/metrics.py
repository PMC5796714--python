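"""Partition-comparison metrics for planted-vs-inferred rankings.

The adjusted Rand index is insensitive to class order, so a ranking and
its inversion score 1; :func:`rank_alignment` (a Kendall correlation of
the class labels) disambiguates: values near -1 flag an inverted
recovery.
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
from scipy.stats import kendalltau

from .graph import Ranking, sorted_nodes

__all__ = ["adjusted_rand_index", "rank_alignment", "contingency_counts"]


def _aligned_labels(r1: Ranking, r2: Ranking) -> Tuple[np.ndarray, np.ndarray]:
    if r1.nodes != r2.nodes:
        only1 = sorted_nodes(r1.nodes - r2.nodes)[:5]
        only2 = sorted_nodes(r2.nodes - r1.nodes)[:5]
        raise ValueError(
            f"rankings cover different node sets (e.g. only in first: {only1}, "
            f"only in second: {only2})")
    order = sorted_nodes(r1.nodes)
    return r1.canonicalize().labels(order), r2.canonicalize().labels(order)


def contingency_counts(planted: Ranking, inferred: Ranking) -> np.ndarray:
    """Heat-map matrix: entry ``(i, j)`` counts nodes in planted class
    ``i+1`` and inferred class ``j+1``.  Row sums are the planted class
    sizes, column sums the inferred ones."""
    l1, l2 = _aligned_labels(planted, inferred)
    R1, R2 = l1.max(initial=0), l2.max(initial=0)
    table = np.zeros((R1, R2), dtype=np.int64)
    np.add.at(table, (l1 - 1, l2 - 1), 1)
    return table


def adjusted_rand_index(r1: Ranking, r2: Ranking) -> float:
    """Hubert-Arabie adjusted Rand index between two ordered partitions.

    Chance-corrected under the permutation model; 1 for identical
    partitions (up to relabelling), ~0 for independent ones.
    """
    table = contingency_counts(r1, r2)
    n = table.sum()
    if n < 2:
        return 1.0

    def comb2(x):
        x = np.asarray(x, dtype=float)
        return x * (x - 1.0) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0  # both partitions trivial in the same way
    return float((sum_ij - expected) / (max_index - expected))


def rank_alignment(r1: Ranking, r2: Ranking) -> float:
    """Kendall rank correlation of the two class-label vectors, in [-1, 1].

    +1 for order-preserving agreement, -1 for an exact inversion.  If
    either ranking is constant (a single class) the correlation is
    undefined; 0 is returned with a warning.
    """
    l1, l2 = _aligned_labels(r1, r2)
    if len(set(l1)) < 2 or len(set(l2)) < 2:
        warnings.warn("rank alignment undefined for a constant ranking; returning 0",
                      stacklevel=2)
        return 0.0
    tau = kendalltau(l1, l2).statistic
    return float(tau) if np.isfinite(tau) else 0.0
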