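"""Signed undirected interaction networks.

A microbial interaction network is modelled as an undirected graph on
``n_nodes`` taxa whose edges carry a sign: ``+1`` for synergy (co-presence
is favoured) and ``-1`` for competition.  The equivalent algebraic object is
the symmetric interaction matrix ``I`` with entries in ``{-1, 0, +1}`` and a
zero diagonal.

Node labels are 0-based integers ``0..n_nodes-1`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx
import numpy as np

__all__ = [
    "SignedNetwork",
    "RewireRecord",
    "generate_random_network",
    "rewire_edges",
    "edge_jaccard",
    "read_edge_list",
    "write_edge_list",
]


def _canon_edge(i: int, j: int, sign: int) -> tuple[int, int, int]:
    if i == j:
        raise ValueError(f"self-loop ({i},{i}) is not allowed")
    if sign not in (-1, 1):
        raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
    if i > j:
        i, j = j, i
    return (int(i), int(j), int(sign))


@dataclass(frozen=True)
class SignedNetwork:
    """An undirected graph on ``n_nodes`` nodes with edges signed +1/-1.

    ``edges`` is a frozenset of ``(i, j, sign)`` triples with ``i < j``.
    At most one edge per unordered node pair; no self-loops.
    """

    n_nodes: int
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        canon = frozenset(_canon_edge(*e) for e in self.edges)
        object.__setattr__(self, "edges", canon)
        pairs = {(i, j) for i, j, _ in canon}
        if len(pairs) != len(canon):
            raise ValueError("multiple edges between the same node pair")
        for i, j, _ in canon:
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"edge ({i},{j}) outside 0..{self.n_nodes - 1}")

    # -- basic queries -----------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_sign(self, i: int, j: int) -> int:
        """Sign of the edge between ``i`` and ``j``; 0 if absent."""
        if i > j:
            i, j = j, i
        for a, b, s in self.edges:
            if (a, b) == (i, j):
                return s
        return 0

    def interaction_matrix(self) -> np.ndarray:
        """Symmetric ``n_nodes x n_nodes`` matrix with entries in {-1,0,+1}."""
        mat = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        for i, j, s in self.edges:
            mat[i, j] = s
            mat[j, i] = s
        return mat

    @classmethod
    def from_interaction_matrix(cls, mat: np.ndarray) -> "SignedNetwork":
        mat = np.asarray(mat)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError("interaction matrix must be square")
        if not np.array_equal(mat, mat.T):
            raise ValueError("interaction matrix must be symmetric")
        if np.any(np.diag(mat) != 0):
            raise ValueError("interaction matrix must have zero diagonal")
        n = mat.shape[0]
        ii, jj = np.nonzero(np.triu(mat, 1))
        edges = frozenset((int(i), int(j), int(mat[i, j])) for i, j in zip(ii, jj))
        return cls(n, edges)

    def with_edge_state(self, i: int, j: int, state: int) -> "SignedNetwork":
        """Return a copy with the (i, j) pair set to ``state`` in {-1, 0, +1}."""
        if i > j:
            i, j = j, i
        if state not in (-1, 0, 1):
            raise ValueError("edge state must be -1, 0 or +1")
        kept = {e for e in self.edges if (e[0], e[1]) != (i, j)}
        if state != 0:
            kept.add(_canon_edge(i, j, state))
        return SignedNetwork(self.n_nodes, frozenset(kept))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from((i, j, {"sign": s}) for i, j, s in self.edges)
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())

    def __iter__(self) -> Iterator[tuple[int, int, int]]:
        return iter(sorted(self.edges))


@dataclass(frozen=True)
class RewireRecord:
    """One rewiring move: edge (n0, n_minus) replaced by (n0, n_plus).

    The anchor node ``n0`` is the endpoint kept by the rewired edge; the sign
    is preserved, so the positive/negative edge counts are invariant.
    """

    removed: tuple[int, int, int]
    added: tuple[int, int, int]

    @property
    def anchor(self) -> int:
        shared = set(self.removed[:2]) & set(self.added[:2])
        return next(iter(shared))


def generate_random_network(
    n_nodes: int,
    m_pos: int,
    m_neg: int,
    seed: int | np.random.Generator,
    *,
    require_connected: bool = True,
    max_tries: int = 10_000,
) -> SignedNetwork:
    """Draw a random signed network with exact edge counts.

    Edges are a uniform sample of ``m_pos + m_neg`` node pairs; signs are a
    random assignment of ``m_pos`` pluses and ``m_neg`` minuses to those
    pairs.  Connectivity is enforced by rejection sampling: draws are
    repeated until the graph is a single component (adequate at the small
    network sizes this package targets).
    """
    if n_nodes < 1 or m_pos < 0 or m_neg < 0:
        raise ValueError("n_nodes must be >= 1 and edge counts non-negative")
    m = m_pos + m_neg
    max_edges = n_nodes * (n_nodes - 1) // 2
    if m > max_edges:
        raise ValueError(
            f"{m} edges requested but at most {max_edges} fit on {n_nodes} nodes"
        )
    if require_connected and m < n_nodes - 1:
        raise ValueError(
            f"{m} edges cannot connect {n_nodes} nodes (need >= {n_nodes - 1})"
        )
    rng = np.random.default_rng(seed)
    all_pairs = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    signs = np.array([1] * m_pos + [-1] * m_neg, dtype=int)
    for _ in range(max_tries):
        idx = rng.choice(len(all_pairs), size=m, replace=False)
        perm = rng.permutation(m)
        edges = frozenset(
            (all_pairs[int(k)][0], all_pairs[int(k)][1], int(signs[p]))
            for k, p in zip(idx, perm)
        )
        net = SignedNetwork(n_nodes, edges)
        if not require_connected or m == 0 or net.is_connected():
            return net
    raise RuntimeError(
        f"no connected network found in {max_tries} tries for "
        f"N={n_nodes}, M+={m_pos}, M-={m_neg}"
    )


def rewire_edges(
    net: SignedNetwork,
    n_rewires: int,
    seed: int | np.random.Generator,
    *,
    require_connected: bool = True,
    max_tries: int = 10_000,
) -> tuple[SignedNetwork, list[RewireRecord]]:
    """Rewire ``n_rewires`` edges, keeping one endpoint (the anchor) of each.

    Each move removes an existing edge ``(n0, n_minus)`` and adds an absent
    edge ``(n0, n_plus)`` with the same sign.  The result is kept connected
    and free of multi-edges; moves that would undo an earlier move in the
    same call are rejected so the output differs from the input by exactly
    ``n_rewires`` removed and ``n_rewires`` added edges.
    """
    if n_rewires < 1:
        raise ValueError("n_rewires must be >= 1")
    if net.n_edges == 0:
        raise ValueError("cannot rewire a network with no edges")
    rng = np.random.default_rng(seed)

    for _ in range(max_tries):
        cur = net
        records: list[RewireRecord] = []
        removed_pairs: set[tuple[int, int]] = set()
        added_pairs: set[tuple[int, int]] = set()
        ok = True
        for _ in range(n_rewires):
            move = _draw_rewire(
                cur, rng, removed_pairs, added_pairs, require_connected
            )
            if move is None:
                ok = False
                break
            cur, rec = move
            records.append(rec)
            removed_pairs.add(rec.removed[:2])
            added_pairs.add(rec.added[:2])
        if ok:
            return cur, records
    raise RuntimeError(f"no legal sequence of {n_rewires} rewires found")


def _draw_rewire(
    net: SignedNetwork,
    rng: np.random.Generator,
    forbidden_add: set[tuple[int, int]],
    forbidden_remove: set[tuple[int, int]],
    require_connected: bool,
    attempts: int = 200,
) -> tuple[SignedNetwork, RewireRecord] | None:
    edges = sorted(net.edges)
    neighbors: dict[int, set[int]] = {v: set() for v in range(net.n_nodes)}
    for i, j, _ in edges:
        neighbors[i].add(j)
        neighbors[j].add(i)
    for _ in range(attempts):
        i, j, sign = edges[int(rng.integers(len(edges)))]
        if (i, j) in forbidden_remove:
            continue
        n0, n_minus = (i, j) if rng.integers(2) == 0 else (j, i)
        candidates = [
            v
            for v in range(net.n_nodes)
            if v != n0
            and v not in neighbors[n0]
            and tuple(sorted((n0, v))) not in forbidden_add
        ]
        if not candidates:
            continue
        n_plus = candidates[int(rng.integers(len(candidates)))]
        removed = _canon_edge(n0, n_minus, sign)
        added = _canon_edge(n0, n_plus, sign)
        new_edges = (set(net.edges) - {removed}) | {added}
        cand = SignedNetwork(net.n_nodes, frozenset(new_edges))
        if require_connected and not cand.is_connected():
            continue
        return cand, RewireRecord(removed=removed, added=added)
    return None


def edge_jaccard(net_a: SignedNetwork, net_b: SignedNetwork) -> float:
    """Jaccard overlap of signed edge sets.

    A signed edge matches only if both endpoints and the sign agree.  Two
    networks with no edges at all are considered identical (overlap 1.0).
    """
    if net_a.n_nodes != net_b.n_nodes:
        raise ValueError("networks must have the same number of nodes")
    inter = len(net_a.edges & net_b.edges)
    union = len(net_a.edges | net_b.edges)
    return 1.0 if union == 0 else inter / union


# -- plain-text edge-list I/O ---------------------------------------------


def write_edge_list(net: SignedNetwork, path) -> None:
    """Write ``# n_nodes=<N>`` header plus one ``i<TAB>j<TAB>sign`` line per edge."""
    with open(path, "w") as fh:
        fh.write(f"# n_nodes={net.n_nodes}\n")
        for i, j, s in sorted(net.edges):
            fh.write(f"{i}\t{j}\t{'+1' if s > 0 else '-1'}\n")


def read_edge_list(path) -> SignedNetwork:
    n_nodes = None
    edges = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                if key.strip() == "n_nodes":
                    n_nodes = int(val)
                continue
            i, j, s = line.split("\t")
            edges.add((int(i), int(j), int(s)))
    if n_nodes is None:
        raise ValueError(f"{path}: missing '# n_nodes=<N>' header")
    return SignedNetwork(n_nodes, frozenset(edges))
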