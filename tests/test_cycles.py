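"""Minimum cycle basis and ring/connectivity analytics."""

import itertools

import networkx as nx
import pytest

from mdgraphs.cycles import (connected_component_sizes,
                             cycle_interaction_graph, minimum_cycle_basis,
                             polygon_membership_fraction, ring_size_histogram,
                             select_z_slab, _cycle_edges)
from mdgraphs.fixtures import make_ring_chain_graph, make_water_sheet
from mdgraphs.molgraph import MolGraph, build_molgraph, pooled_undirected


def mixed(vertices, ec=(), ah=(), ei=(), eo=()):
    return MolGraph(vertices, frozenset(ec), frozenset(ah), frozenset(ei),
                    frozenset(eo))


def from_nx(graph):
    return mixed({v: "C" for v in graph.nodes},
                 ec=[tuple(sorted(e)) for e in graph.edges()])


def gf2_rank(cycles, graph):
    edge_index = {tuple(sorted(e)): i for i, e in enumerate(graph.edges())}
    vecs = []
    for cyc in cycles:
        v = 0
        for e in _cycle_edges(cyc):
            v |= 1 << edge_index[e]
        vecs.append(v)
    rank = 0
    pivots = {}
    for v in vecs:
        while v:
            low = v & -v
            if low in pivots:
                v ^= pivots[low]
            else:
                pivots[low] = v
                rank += 1
                break
    return rank


class TestMinimumCycleBasis:
    def test_tree_has_empty_basis(self):
        g = mixed({i: "C" for i in range(5)},
                  ec=[(0, 1), (1, 2), (2, 3), (3, 4)])
        assert len(minimum_cycle_basis(g)) == 0

    def test_k4_basis_is_three_triangles(self):
        g = from_nx(nx.complete_graph(4))
        basis = minimum_cycle_basis(g)
        assert sorted(basis.sizes()) == [3, 3, 3]
        assert gf2_rank(basis.cycles, pooled_undirected(g)) == 3

    def test_dimension_on_random_graphs(self, nprng):
        """Basis size = |E| - |V| + C, and cycles are GF(2)-independent."""
        for _ in range(100):
            n = int(nprng.integers(3, 14))
            p = float(nprng.uniform(0.15, 0.6))
            gx = nx.gnp_random_graph(n, p, seed=int(nprng.integers(2**31)))
            g = from_nx(gx)
            basis = minimum_cycle_basis(g)
            dim = (gx.number_of_edges() - gx.number_of_nodes()
                   + nx.number_connected_components(gx))
            assert len(basis) == dim
            assert gf2_rank(basis.cycles, gx) == dim
            ug = pooled_undirected(g)
            for cyc in basis.cycles:
                assert len(set(cyc)) == len(cyc)  # simple cycle
                for a, b in _cycle_edges(cyc):
                    assert ug.has_edge(a, b)

    def test_minimal_weight_matches_networkx_oracle(self, nprng):
        """Total basis weight equals networkx's minimum cycle basis weight."""
        for _ in range(40):
            n = int(nprng.integers(4, 11))
            gx = nx.gnp_random_graph(n, 0.45, seed=int(nprng.integers(2**31)))
            basis = minimum_cycle_basis(from_nx(gx))
            oracle = nx.minimum_cycle_basis(gx)
            assert sum(basis.sizes()) == sum(len(c) for c in oracle)

    def test_deterministic(self, nprng):
        gx = nx.gnp_random_graph(9, 0.4, seed=7)
        g = from_nx(gx)
        assert minimum_cycle_basis(g).cycles == minimum_cycle_basis(g).cycles

    def test_hexagonal_sheet_all_sixes(self, params, thresholds):
        for rows, cols in ((1, 1), (2, 2)):
            g = build_molgraph(make_water_sheet(rows, cols), params, thresholds)
            basis = minimum_cycle_basis(g)
            lattice = nx.hexagonal_lattice_graph(rows, cols)
            dim = lattice.number_of_edges() - lattice.number_of_nodes() + 1
            assert len(basis) == dim
            assert set(basis.sizes()) == {6}


class TestComponents:
    def test_edgeless_graph(self):
        g = mixed({i: "O" for i in range(5)})
        assert connected_component_sizes(g) == {1: 5}

    def test_two_components(self):
        g = mixed({i: "C" for i in range(8)},
                  ec=[(0, 1), (1, 2), (3, 4), (4, 5), (5, 6), (6, 7), (3, 7)])
        assert connected_component_sizes(g) == {3: 1, 5: 1}

    def test_sheet_fully_connected(self, params, thresholds):
        g = build_molgraph(make_water_sheet(2, 2), params, thresholds)
        assert connected_component_sizes(g) == {g.n_vertices: 1}


class TestRingHistogram:
    def test_acyclic_graphs_empty(self):
        g = mixed({0: "O", 1: "O"}, ah=[(0, 1)])
        assert ring_size_histogram([g, g]) == {}

    def test_hexagonal_sheet(self, params, thresholds):
        g = build_molgraph(make_water_sheet(2, 2), params, thresholds)
        assert ring_size_histogram([g]) == {6: 1.0}

    def test_square_and_pentagon_pooled_over_frames(self):
        square = mixed({i: "O" for i in range(4)},
                       ah=[(i, (i + 1) % 4) for i in range(4)])
        pentagon = mixed({i: "O" for i in range(5)},
                         ah=[(i, (i + 1) % 5) for i in range(5)])
        graphs = [square, pentagon] * 10
        hist = ring_size_histogram(graphs)
        assert hist == {4: 0.5, 5: 0.5}


class TestPolygonMembership:
    def test_all_vertices_on_cycles(self):
        g = mixed({i: "O" for i in range(6)},
                  ah=[(i, (i + 1) % 6) for i in range(6)])
        assert polygon_membership_fraction([g]) == pytest.approx(100.0)

    def test_ring_plus_chain_is_half(self):
        assert polygon_membership_fraction(
            [make_ring_chain_graph(6, 6)]) == pytest.approx(50.0)

    def test_acyclic_graph_zero(self):
        g = mixed({0: "O", 1: "O", 2: "O"}, ah=[(0, 1), (1, 2)])
        assert polygon_membership_fraction([g]) == pytest.approx(0.0)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            polygon_membership_fraction([mixed({})])


class TestCycleGraph:
    def test_single_cycle(self):
        g = mixed({i: "O" for i in range(6)},
                  ah=[(i, (i + 1) % 6) for i in range(6)])
        cg = cycle_interaction_graph(g)
        assert len(cg.cycles) == 1 and not cg.edges

    def test_fused_hexagons_share_edge(self):
        # two hexagons sharing the edge (0, 1)
        arcs = [(i, (i + 1) % 6) for i in range(6)]
        arcs += [(0, 6), (6, 7), (7, 8), (8, 9), (9, 1)]
        gm = mixed({i: "O" for i in range(10)}, ah=arcs)
        cg = cycle_interaction_graph(gm)
        assert len(cg.cycles) == 2
        assert cg.edges == {(0, 1)}

    def test_disjoint_cycles_no_edges(self):
        arcs = [(i, (i + 1) % 3) for i in range(3)]
        arcs += [(3 + i, 3 + (i + 1) % 3) for i in range(3)]
        g = mixed({i: "O" for i in range(6)}, ah=arcs)
        cg = cycle_interaction_graph(g)
        assert len(cg.cycles) == 2 and not cg.edges

    def test_covalent_only_cycles_excluded(self):
        # a benzene-like ring has no H-bond arc: not an H-bonded cycle
        g = mixed({i: "C" for i in range(6)},
                  ec=[(i, (i + 1) % 6) for i in range(6)])
        cg = cycle_interaction_graph(g)
        assert len(cg.cycles) == 0


class TestZSlab:
    def test_selects_and_reindexes(self, params, thresholds):
        snap = make_water_sheet(1, 1)
        sub = select_z_slab(snap, -0.5, 0.5)
        assert sub.n_atoms < snap.n_atoms  # out-of-plane spare H dropped
        assert [a.index for a in sub.atoms] == list(range(sub.n_atoms))
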