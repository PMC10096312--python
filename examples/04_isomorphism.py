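"""Colored mixed-graph isomorphism: why vertex colors and arc directions
matter when deciding whether two configurations are the same conformer."""

from mdgraphs import are_isomorphic, canonical_key
from mdgraphs.molgraph import MolGraph


def mixed(vertices, ec=(), ah=()):
    return MolGraph(vertices, frozenset(ec), frozenset(ah), frozenset(),
                    frozenset())


# Two graphs identical up to exchanging the two oxygens: isomorphic.
g1 = mixed({0: "C", 1: "O", 2: "O"}, ec=[(0, 1)], ah=[(0, 2)])
g2 = mixed({0: "C", 1: "O", 2: "O"}, ec=[(0, 2)], ah=[(0, 1)])
print("same-color exchange isomorphic:", are_isomorphic(g1, g2))

# Same shape, but the swapped vertices are N vs O: colors forbid the map.
g3 = mixed({0: "C", 1: "N", 2: "O"}, ec=[(0, 1)], ah=[(0, 2)])
g4 = mixed({0: "C", 1: "N", 2: "O"}, ec=[(0, 2)], ah=[(0, 1)])
print("colored exchange isomorphic   :", are_isomorphic(g3, g4))

# H-bond arcs are directed: donor->acceptor reversal is a different graph
# unless a color-preserving relabeling maps one onto the other.
g5 = mixed({0: "N", 1: "O"}, ah=[(0, 1)])
g6 = mixed({0: "N", 1: "O"}, ah=[(1, 0)])
print("reversed arc isomorphic       :", are_isomorphic(g5, g6))

# Canonical keys give registry lookups in one dictionary access:
print("keys equal (g1 vs g2)         :",
      canonical_key(g1) == canonical_key(g2))
print("keys equal (g3 vs g4)         :",
      canonical_key(g3) == canonical_key(g4))
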