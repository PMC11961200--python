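"""Synchronous Boolean threshold ("majority vote") dynamics and attractors.

Each node ``i`` carries a binary state ``s_i`` (presence/absence of a
taxon).  All nodes update synchronously from the signed input field
``h_i = sum_j I_ij s_j``:

* ``h_i > 0``  -> ``s_i`` becomes 1,
* ``h_i < 0``  -> ``s_i`` becomes 0,
* ``h_i = 0``  -> ``s_i`` keeps its value.

Updating each of the ``2^N`` states exactly once yields a functional graph
``s -> update(s)``; its fixed points and cycles are the attractor set of
the network.  States are canonically encoded as integers with node 0 as the
least-significant bit, which makes exhaustive enumeration a handful of
vectorized array operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .network import SignedNetwork

__all__ = [
    "AttractorSet",
    "update_state",
    "compute_attractors",
    "basin_sizes",
    "state_to_bits",
    "bits_to_state",
    "successor_table",
    "write_attractor_matrix",
    "read_attractor_matrix",
]

#: Default cap on n_nodes for exhaustive 2^N enumeration.
DEFAULT_NODE_CAP = 20


def bits_to_state(bits: Sequence[int]) -> int:
    """Encode a 0/1 vector as an integer (node 0 = least significant bit)."""
    state = 0
    for k, b in enumerate(bits):
        if b not in (0, 1):
            raise ValueError("state bits must be 0 or 1")
        state |= int(b) << k
    return state


def state_to_bits(state: int, n_nodes: int) -> np.ndarray:
    """Decode an integer state to a length-``n_nodes`` 0/1 vector."""
    if not 0 <= state < (1 << n_nodes):
        raise ValueError(f"state {state} outside 0..2^{n_nodes}-1")
    return (state >> np.arange(n_nodes)) & 1


@lru_cache(maxsize=8)
def _all_states_bits(n_nodes: int) -> np.ndarray:
    """(2^N, N) matrix of all states' bits, row index == integer encoding."""
    states = np.arange(1 << n_nodes, dtype=np.int64)
    return ((states[:, None] >> np.arange(n_nodes)) & 1).astype(np.int16)


def update_state(net: SignedNetwork, bits: Sequence[int]) -> np.ndarray:
    """Apply one synchronous threshold update to a state vector."""
    s = np.asarray(bits, dtype=np.int16)
    if s.shape != (net.n_nodes,):
        raise ValueError(
            f"state length {s.shape} does not match n_nodes={net.n_nodes}"
        )
    if np.any((s != 0) & (s != 1)):
        raise ValueError("state bits must be 0 or 1")
    h = net.interaction_matrix().astype(np.int16) @ s
    return np.where(h > 0, 1, np.where(h < 0, 0, s)).astype(np.int8)


def successor_table(net: SignedNetwork, cap: int = DEFAULT_NODE_CAP) -> np.ndarray:
    """Integer successor ``f`` over all ``2^N`` states: ``f[s] = update(s)``."""
    n = net.n_nodes
    if n > cap:
        raise ValueError(
            f"n_nodes={n} exceeds the exhaustive-enumeration cap of {cap}"
        )
    return _successor_from_matrix(net.interaction_matrix(), n)


def _successor_from_matrix(imat: np.ndarray, n: int) -> np.ndarray:
    bits = _all_states_bits(n)
    h = bits @ imat.astype(np.int16)
    nxt_bits = np.where(h > 0, 1, np.where(h < 0, 0, bits))
    pow2 = (1 << np.arange(n, dtype=np.int64))
    return nxt_bits.astype(np.int64) @ pow2


def _cycle_states(f: np.ndarray, n: int) -> np.ndarray:
    """States lying on cycles of the functional graph ``f`` (sorted)."""
    g = f
    for _ in range(n):  # g = f^(2^n); every tail has length < 2^n
        g = g[g]
    mask = np.zeros(f.shape[0], dtype=bool)
    mask[g] = True
    return np.flatnonzero(mask)


@dataclass(frozen=True)
class AttractorSet:
    """Fixed points and cycles of the synchronous dynamics.

    ``all_states`` is the union of the fixed points and every state on a
    cycle, as integer-encoded states; downstream set comparisons operate on
    this union (cyclic attractors contribute state-by-state).
    """

    n_nodes: int
    fixed_points: frozenset = field(default_factory=frozenset)
    cycles: tuple = ()

    @property
    def all_states(self) -> frozenset:
        states = set(self.fixed_points)
        for cyc in self.cycles:
            states.update(cyc)
        return frozenset(states)

    @property
    def n_attractors(self) -> int:
        return len(self.fixed_points) + len(self.cycles)

    def states_array(self) -> np.ndarray:
        """All attractor states, sorted ascending by integer encoding."""
        return np.array(sorted(self.all_states), dtype=np.int64)

    def bit_matrix(self) -> np.ndarray:
        """(n_states, N) 0/1 matrix, rows in ascending state order."""
        arr = self.states_array()
        return ((arr[:, None] >> np.arange(self.n_nodes)) & 1).astype(np.int8)

    @classmethod
    def from_states(cls, n_nodes: int, states) -> "AttractorSet":
        """Build a fixed-point-only set from integer states (for observed
        pattern collections that are interpreted as attractors)."""
        return cls(n_nodes, frozenset(int(s) for s in states), ())


def compute_attractors(
    net: SignedNetwork, cap: int = DEFAULT_NODE_CAP
) -> AttractorSet:
    """Exhaustively enumerate the attractor set of ``net``.

    Builds the successor table over all ``2^N`` states, finds the states on
    cycles by iterated squaring of the successor map, and splits them into
    fixed points and cyclic orbits.  Each cycle is reported starting at its
    smallest state.
    """
    f = successor_table(net, cap)
    on_cycle = _cycle_states(f, net.n_nodes)
    fixed = frozenset(int(s) for s in on_cycle[f[on_cycle] == on_cycle])
    cycles = []
    seen: set[int] = set()
    for s in on_cycle:
        s = int(s)
        if s in fixed or s in seen:
            continue
        orbit = [s]
        cur = int(f[s])
        while cur != s:
            orbit.append(cur)
            cur = int(f[cur])
        seen.update(orbit)
        k = orbit.index(min(orbit))
        cycles.append(tuple(orbit[k:] + orbit[:k]))
    cycles.sort()
    return AttractorSet(net.n_nodes, fixed, tuple(cycles))


def basin_sizes(
    net: SignedNetwork, cap: int = DEFAULT_NODE_CAP
) -> Mapping[tuple, int]:
    """Number of initial states flowing to each attractor.

    Keys are attractors as state tuples: ``(s,)`` for a fixed point ``s``,
    the canonical orbit tuple for a cycle.  Values sum to ``2^N``.
    """
    f = successor_table(net, cap)
    attrs = compute_attractors(net, cap)
    # map every cycle state to its attractor key
    key_of: dict[int, tuple] = {s: (s,) for s in attrs.fixed_points}
    for cyc in attrs.cycles:
        for s in cyc:
            key_of[s] = cyc
    g = f
    for _ in range(net.n_nodes):
        g = g[g]
    counts: dict[tuple, int] = {}
    landed, n = np.unique(g, return_counts=True)
    for s, c in zip(landed, n):
        key = key_of[int(s)]
        counts[key] = counts.get(key, 0) + int(c)
    return counts


# -- plain-text attractor-matrix I/O --------------------------------------


def write_attractor_matrix(attrs: AttractorSet, path) -> None:
    """One row per attractor state, N whitespace-separated 0/1 columns,
    rows in ascending integer encoding."""
    np.savetxt(path, attrs.bit_matrix(), fmt="%d")


def read_attractor_matrix(path, n_nodes: int | None = None) -> AttractorSet:
    mat = np.atleast_2d(np.loadtxt(path, dtype=np.int64))
    if n_nodes is None:
        n_nodes = mat.shape[1]
    elif mat.shape[1] != n_nodes:
        raise ValueError(f"{path}: expected {n_nodes} columns, got {mat.shape[1]}")
    states = mat @ (1 << np.arange(n_nodes, dtype=np.int64))
    return AttractorSet.from_states(n_nodes, states)
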