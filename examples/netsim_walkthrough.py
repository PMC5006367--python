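"""Network-propagation similarity on a six-gene toy network.

Two diseases share a tightly connected corner of a small interaction
network; a third disease sits on the opposite side.  Random walk with
restart spreads each disease's seed probability over the network, and
NetSim averages how much of one disease's walk lands on the other's
genes.
"""

from diseasesim import InteractionNetwork, NetSimParams, netsim, rwr

# two triangles joined by a single bridge edge
edges = [
    ("ga", "gb"), ("gb", "gc"), ("gc", "ga"),       # left triangle
    ("gd", "ge"), ("ge", "gf"), ("gf", "gd"),       # right triangle
    ("gc", "gd"),                                   # bridge
]
network = InteractionNetwork.from_edges(edges)
params = NetSimParams(restart_prob=0.7)

left = {"ga", "gb"}
left2 = {"gb", "gc"}
right = {"ge", "gf"}

res = rwr(network, left, params)
print("RWR steady state seeded by", sorted(left))
for gene in network.nodes:
    print(f"  {gene}: {res.probabilities[gene]:.4f}")
print("Seed-adjacent genes hold most probability; the right triangle "
      "receives only what leaks over the bridge.\n")

print(f"NetSim(left, left2)  = {netsim(network, left, left2, params):.4f}")
print(f"NetSim(left, right)  = {netsim(network, left, right, params):.4f}")
print("Overlapping same-corner gene sets score an order of magnitude "
      "higher than sets on opposite sides of the bridge.")
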