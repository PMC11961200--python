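"""Localize a single rewired edge from the attractor mismatch alone.

Uses the frozen 8-node worked example: rewiring the negative edge (4,7)
to (4,6) changes the attractor set, and the sorted-nodes vector SN ranks
the three involved nodes (6, 7, 4) first.
"""

from edame import (
    abs_difference_arrays,
    compute_attractors,
    sorted_nodes,
    worked_example_pair,
)

g, g_star = worked_example_pair()
A, A_star = compute_attractors(g), compute_attractors(g_star)

d, c, b, e = abs_difference_arrays(A, A_star)
sn = sorted_nodes(A, A_star)

print("per-node |D| :", d.values)
print("per-node |C| :", c.values)
print("per-node |B| :", b.values)
print("per-node |E| :", e.values)
print("sorted nodes :", sn.order)
# |E| peaks at the rewired-edge endpoints: SN starts with 6, 7, 4 — the
# node that gained the edge, the node that lost it, and the anchor.
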