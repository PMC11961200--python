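"""Node-level comparison of two attractor sets.

Given the attractor sets ``A`` (original network) and ``A*`` (modified
network), the destroyed attractors are ``cD = A \\ A*`` and the created
ones ``cC = A* \\ A``.  Matching each member of a complement to its
Hamming-nearest attractors in the other set and summing the element-wise
differences row-by-row yields three length-N arrays:

* ``D``: destroyed vs. nearest members of ``A*``,
* ``C``: nearest members of ``A`` vs. created,
* ``B``: destroyed vs. nearest created.

Taking absolute values of each difference row before summing gives
``|D|, |C|, |B|`` and their total ``|E|``; sorting nodes by descending
``|E|`` produces the sorted-nodes vector SN, whose leading entries
concentrate on the nodes whose edges differ between the two networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .dynamics import AttractorSet

__all__ = [
    "AttractorComplements",
    "NodeScoreArray",
    "SortedNodes",
    "hamming",
    "nearest_attractors",
    "complements",
    "difference_arrays",
    "abs_difference_arrays",
    "sorted_nodes",
    "attractor_jaccard",
    "write_score_arrays",
]


@dataclass(frozen=True)
class AttractorComplements:
    """Destroyed (``A \\ A*``) and created (``A* \\ A``) attractor states."""

    destroyed: frozenset
    created: frozenset


@dataclass(frozen=True)
class NodeScoreArray:
    """A length-N per-node integer summary array with its label."""

    values: tuple
    label: str

    def as_array(self) -> np.ndarray:
        return np.array(self.values, dtype=np.int64)


@dataclass(frozen=True)
class SortedNodes:
    """Node indices in descending |E| order; ties by ascending index.

    ``degenerate`` is set when the two attractor sets are identical, in
    which case the order is simply ``0..N-1``.
    """

    order: tuple
    e_abs: tuple
    degenerate: bool = False


def hamming(a, b) -> int:
    """Number of positions where two equal-length 0/1 vectors differ."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


def _bits(states: np.ndarray, n: int) -> np.ndarray:
    return ((np.asarray(states, dtype=np.int64)[:, None] >> np.arange(n)) & 1).astype(
        np.int64
    )


def _popcount(x: np.ndarray) -> np.ndarray:
    return np.bitwise_count(np.asarray(x, dtype=np.uint64)).astype(np.int64)


def nearest_attractors(target: int, pool: Iterable[int]) -> frozenset:
    """All members of ``pool`` at minimal Hamming distance from ``target``.

    States are integer-encoded; ties are kept, not broken — every minimizer
    contributes a row to the difference matrices downstream.
    """
    pool = np.array(sorted(set(int(p) for p in pool)), dtype=np.int64)
    if pool.size == 0:
        raise ValueError("nearest_attractors: empty pool")
    d = _popcount(np.bitwise_xor(pool, np.int64(target)))
    return frozenset(int(s) for s in pool[d == d.min()])


def complements(A: AttractorSet, A_star: AttractorSet) -> AttractorComplements:
    if A.n_nodes != A_star.n_nodes:
        raise ValueError("attractor sets live on different node counts")
    sa, sb = A.all_states, A_star.all_states
    return AttractorComplements(destroyed=sa - sb, created=sb - sa)


def _summed_rows(
    sources: frozenset, pool: frozenset, n: int, sign: int, absolute: bool
) -> np.ndarray:
    """Sum (or abs-sum) of difference rows source - nearest(pool) over all
    sources and all their nearest-pool minimizers.

    ``sign=+1`` accumulates source - nearest, ``sign=-1`` nearest - source.
    """
    out = np.zeros(n, dtype=np.int64)
    if not sources or not pool:
        return out
    pool_arr = np.array(sorted(pool), dtype=np.int64)
    pool_bits = _bits(pool_arr, n)
    for s in sorted(sources):
        d = _popcount(np.bitwise_xor(pool_arr, np.int64(s)))
        near = pool_bits[d == d.min()]
        diff = sign * (_bits(np.array([s]), n) - near)
        out += np.abs(diff).sum(axis=0) if absolute else diff.sum(axis=0)
    return out


def difference_arrays(
    A: AttractorSet, A_star: AttractorSet
) -> tuple[NodeScoreArray, NodeScoreArray, NodeScoreArray]:
    """The signed summed arrays D, C and B.

    ``D`` matches destroyed attractors against all of ``A*``; ``C`` matches
    created attractors against all of ``A`` (difference taken as original
    minus created); ``B`` matches destroyed against created.  Empty
    complements give all-zero arrays.
    """
    comp = complements(A, A_star)
    n = A.n_nodes
    d = _summed_rows(comp.destroyed, A_star.all_states, n, +1, absolute=False)
    c = _summed_rows(comp.created, A.all_states, n, -1, absolute=False)
    b = _summed_rows(comp.destroyed, comp.created, n, +1, absolute=False)
    return (
        NodeScoreArray(tuple(int(v) for v in d), "D"),
        NodeScoreArray(tuple(int(v) for v in c), "C"),
        NodeScoreArray(tuple(int(v) for v in b), "B"),
    )


def abs_difference_arrays(
    A: AttractorSet, A_star: AttractorSet
) -> tuple[NodeScoreArray, NodeScoreArray, NodeScoreArray, NodeScoreArray]:
    """|D|, |C|, |B| (absolute values taken per difference row, before the
    sum over rows) and their total |E|."""
    comp = complements(A, A_star)
    n = A.n_nodes
    d = _summed_rows(comp.destroyed, A_star.all_states, n, +1, absolute=True)
    c = _summed_rows(comp.created, A.all_states, n, -1, absolute=True)
    b = _summed_rows(comp.destroyed, comp.created, n, +1, absolute=True)
    e = d + c + b
    return (
        NodeScoreArray(tuple(int(v) for v in d), "D_abs"),
        NodeScoreArray(tuple(int(v) for v in c), "C_abs"),
        NodeScoreArray(tuple(int(v) for v in b), "B_abs"),
        NodeScoreArray(tuple(int(v) for v in e), "E_abs"),
    )


def sorted_nodes(A: AttractorSet, A_star: AttractorSet) -> SortedNodes:
    """Sorted-nodes vector SN: nodes by descending |E| peak height.

    Equal |E| values are ordered by ascending node index.  If the two
    attractor sets are identical SN is undefined; the index order
    ``0..N-1`` is returned with the ``degenerate`` flag set and a warning.
    """
    if A.n_nodes != A_star.n_nodes:
        raise ValueError("attractor sets live on different node counts")
    n = A.n_nodes
    if A.all_states == A_star.all_states:
        warnings.warn(
            "identical attractor sets: SN is degenerate, returning index order",
            stacklevel=2,
        )
        return SortedNodes(tuple(range(n)), (0,) * n, degenerate=True)
    e = abs_difference_arrays(A, A_star)[3].as_array()
    order = sorted(range(n), key=lambda i: (-e[i], i))
    return SortedNodes(tuple(order), tuple(int(v) for v in e), degenerate=False)


def write_score_arrays(arrays: Iterable[NodeScoreArray], path) -> None:
    """Diagnostic dump: one labelled row per array, tab-separated."""
    with open(path, "w") as fh:
        for arr in arrays:
            fh.write(arr.label + "\t" + "\t".join(str(v) for v in arr.values))
            fh.write("\n")


def attractor_jaccard(A: AttractorSet, B: AttractorSet) -> float:
    """Jaccard overlap of the two attractor-state sets (both empty -> 1.0)."""
    if A.n_nodes != B.n_nodes:
        raise ValueError("attractor sets live on different node counts")
    sa, sb = A.all_states, B.all_states
    union = len(sa | sb)
    return 1.0 if union == 0 else len(sa & sb) / union
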