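"""Ring and connectivity analytics of a hexagonal water sheet.

A honeycomb sheet of water molecules — the idealized limit of the flat
H-bond network formed by interfacial water at hydrophobic surfaces — is
analyzed with the minimum cycle basis: ring sizes, connected components,
and the share of molecules participating in polygons.
"""

from mdgraphs import (build_molgraph, connected_component_sizes, load_params,
                      minimum_cycle_basis, polygon_membership_fraction,
                      ring_size_histogram)
from mdgraphs.fixtures import make_ring_chain_graph, make_water_sheet

params, thresholds = load_params()

sheet = make_water_sheet(2, 2)
graph = build_molgraph(sheet, params, thresholds)
basis = minimum_cycle_basis(graph)

print(f"sheet: {graph.n_vertices} waters, {len(graph.ah)} H-bonds")
print(f"connected components: {connected_component_sizes(graph)}")
print(f"minimum cycle basis : {len(basis)} rings, sizes {sorted(set(basis.sizes()))}")
print(f"ring-size histogram : {ring_size_histogram([graph])}")
print(f"polygon membership  : {polygon_membership_fraction([graph]):.1f} %")

# A ring with a pendant chain: only the ring half of the vertices belongs
# to a polygon, so the membership fraction is exactly 50%.
ring_chain = make_ring_chain_graph(ring=6, chain=6)
print(f"ring+chain membership: "
      f"{polygon_membership_fraction([ring_chain]):.1f} %")
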