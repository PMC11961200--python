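"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written in the most naive way possible
(python loops, explicit trajectory following, exhaustive enumeration) and
shares no code with the package's vectorized paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_update(imat, bits):
    """Threshold update of one state, scalar python arithmetic."""
    n = len(bits)
    out = []
    for i in range(n):
        h = sum(int(imat[i][j]) * int(bits[j]) for j in range(n))
        out.append(1 if h > 0 else 0 if h < 0 else int(bits[i]))
    return tuple(out)


def _int_to_bits(s, n):
    return tuple((s >> k) & 1 for k in range(n))


def _bits_to_int(bits):
    return sum(b << k for k, b in enumerate(bits))


def naive_attractors(net):
    """Trajectory-following oracle: iterate each initial state until a
    state repeats, then classify the loop as fixed point or cycle.

    Returns (fixed_points: set[int], cycles: set[frozenset[int]],
    basin: dict[key, int]) with keys as in `basin_sizes`.
    """
    imat = net.interaction_matrix()
    n = net.n_nodes
    fixed = set()
    cycles = set()
    basin = {}
    for s0 in range(1 << n):
        seen = {}
        s = s0
        while s not in seen:
            seen[s] = len(seen)
            s = _bits_to_int(naive_update(imat, _int_to_bits(s, n)))
        # s is the first repeated state: the loop starts at seen[s]
        loop = [st for st, idx in sorted(seen.items(), key=lambda kv: kv[1])
                if idx >= seen[s]]
        if len(loop) == 1:
            fixed.add(loop[0])
            key = (loop[0],)
        else:
            cycles.add(frozenset(loop))
            k = loop.index(min(loop))
            key = tuple(loop[k:] + loop[:k])
        basin[key] = basin.get(key, 0) + 1
    return fixed, cycles, basin


def brute_difference_arrays(states_a, states_b, n):
    """Independent re-implementation of the D/C/B summed arrays and their
    absolute-value analogues, from integer state sets."""
    a = sorted(states_a)
    b = sorted(states_b)

    def bits(s):
        return [(s >> k) & 1 for k in range(n)]

    def ham(x, y):
        return bin(x ^ y).count("1")

    def rows(sources, pool, flip):
        out = []
        for s in sources:
            dmin = min(ham(s, p) for p in pool)
            for p in pool:
                if ham(s, p) == dmin:
                    r = [bs - bp for bs, bp in zip(bits(s), bits(p))]
                    out.append([-v for v in r] if flip else r)
        return out

    cd = [s for s in a if s not in states_b]
    cc = [s for s in b if s not in states_a]
    arrays = {}
    for name, (src, pool, flip) in {
        "D": (cd, b, False),
        "C": (cc, a, True),
        "B": (cd, cc, False),
    }.items():
        if not src or not pool:
            arrays[name] = [0] * n
            arrays[name + "_abs"] = [0] * n
            continue
        rr = rows(src, pool, flip)
        arrays[name] = [sum(r[i] for r in rr) for i in range(n)]
        arrays[name + "_abs"] = [sum(abs(r[i]) for r in rr) for i in range(n)]
    arrays["E_abs"] = [
        arrays["D_abs"][i] + arrays["C_abs"][i] + arrays["B_abs"][i]
        for i in range(n)
    ]
    return arrays


def exhaustive_and_entropy_null(a, b, n):
    """Exact permutation-null mean/sd of H(AND(x, y)) by enumerating every
    placement of the ``b`` ones of y against a fixed x with ``a`` ones."""
    hs = []
    x = [1] * a + [0] * (n - a)
    for pos in itertools.combinations(range(n), b):
        y = [1 if i in pos else 0 for i in range(n)]
        k = sum(xi & yi for xi, yi in zip(x, y))
        p = k / n
        h = 0.0 if p in (0.0, 1.0) else -(
            p * math.log2(p) + (1 - p) * math.log2(1 - p)
        )
        hs.append(h)
    mu = sum(hs) / len(hs)
    var = sum((h - mu) ** 2 for h in hs) / len(hs)
    return mu, math.sqrt(var)


def random_signed_net(rng, n_max=4, connected=False):
    """A random small SignedNetwork (possibly disconnected) for oracles."""
    from edame import SignedNetwork

    n = int(rng.integers(2, n_max + 1))
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            r = rng.random()
            if r < 1 / 3:
                edges.add((i, j, 1))
            elif r < 2 / 3:
                edges.add((i, j, -1))
    return SignedNetwork(n, frozenset(edges))
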