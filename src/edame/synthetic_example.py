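"""A synthetic worked example of single-edge detection via sorted nodes.

This module freezes one 8-node signed network, found by randomized
search, on which rewiring the negative edge (4, 7) to (4, 6) produces
the sorted-nodes vector ``[6, 7, 4, 3, 2, 5, 1, 0]`` with strictly
decreasing |E| peaks — the rewired-edge endpoints 6, 7 and 4 lead the
ranking.  It is a synthetic stand-in instance (constructed, not
measured) used in the documentation and tests as the canonical
demonstration that attractor mismatches localize an edge change.
"""

from __future__ import annotations

from .network import SignedNetwork

__all__ = ["worked_example_pair", "WORKED_EXAMPLE_SN"]

#: Sorted-nodes vector obtained for the pair below (strict |E| order).
WORKED_EXAMPLE_SN: tuple = (6, 7, 4, 3, 2, 5, 1, 0)

_EDGES = (
    (0, 2, -1),
    (0, 5, 1),
    (0, 7, 1),
    (1, 3, -1),
    (2, 5, -1),
    (2, 6, 1),
    (3, 7, 1),
    (4, 7, -1),
    (5, 6, 1),
)


def worked_example_pair() -> tuple[SignedNetwork, SignedNetwork]:
    """The frozen 8-node network ``G`` and its single-rewire partner ``G*``.

    ``G*`` differs from ``G`` by rewiring the negative edge (4, 7) to
    (4, 6), keeping node 4 as the anchor and preserving the sign; both
    networks are connected.
    """
    g = SignedNetwork(8, frozenset(_EDGES))
    g_star = g.with_edge_state(4, 7, 0).with_edge_state(4, 6, -1)
    return g, g_star
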