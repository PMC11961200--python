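"""Enumerate the Boolean attractors of a small signed interaction network.

Builds a 10-node network with 10 synergistic and 10 competitive edges,
runs the synchronous threshold ("majority vote") dynamics over all 2^10
presence/absence states and reports the asymptotic states.
"""

from edame import basin_sizes, compute_attractors, generate_random_network

net = generate_random_network(n_nodes=10, m_pos=10, m_neg=10, seed=42)
attrs = compute_attractors(net)
basins = basin_sizes(net)

print(f"network: {net.n_nodes} nodes, {net.n_edges} signed edges")
print(f"fixed-point attractors: {len(attrs.fixed_points)}")
print(f"cyclic attractors:      {len(attrs.cycles)}")
largest = max(basins.items(), key=lambda kv: kv[1])
print(f"largest basin: attractor {largest[0]} drains {largest[1]} of "
      f"{2**net.n_nodes} initial states")
# Each attractor is one stable community composition (which taxa persist
# together); the basin size says how many initial compositions relax to it.
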