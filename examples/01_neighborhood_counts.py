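"""Count level-1, level-2 and bridging interactors on a hand-sized network.

Builds a five-protein toy interactome around a seed M and classifies the
gene set {A, C} by network distance from the seed.
"""

import networkx as nx

from seedprox import InteractionNetwork, compute_neighborhood

network = InteractionNetwork(
    graph=nx.Graph([("M", "A"), ("M", "B"), ("A", "C"), ("B", "C"), ("C", "D")])
)
counts = compute_neighborhood(network, seed="M", gene_set={"A", "C"})

print("level-1 interactors :", sorted(counts.level1))
print("level-2 interactors :", sorted(counts.level2))
print("bridging proteins   :", sorted(counts.bridging))
# A touches M directly (level-1); C is two steps away (level-2); both A and B
# sit on M->X->C paths, so they are the bridging intermediaries.
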