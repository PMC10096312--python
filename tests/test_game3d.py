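"""Sequential game, LRI learning and RMSD evaluation."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from mdgraphs.fixtures import make_carbon_chain, make_molecule
from mdgraphs.game3d import (FullMolGraph, GameConfig, PlayerState,
                             VseprTemplates, bfs_covering_tree,
                             direct_utility, icosphere_directions,
                             indirect_utility, local_term, lri_update,
                             normalized_utility, place_children, rmsd,
                             round_cost, run_game, strategy_grid,
                             format_block_table)
from mdgraphs.game3d import _build_grids


def chain_graph(n, element="C"):
    return FullMolGraph({i: element for i in range(n)},
                        {(i, i + 1): "covalent" for i in range(n - 1)})


class TestCoveringTree:
    def test_single_vertex(self):
        tree = bfs_covering_tree(FullMolGraph({0: "C"}, {}))
        assert tree.root == 0 and tree.children[0] == ()

    def test_path_rooted_at_end(self):
        tree = bfs_covering_tree(chain_graph(3), root=0)
        assert tree.parent[2] == 1
        assert tree.dist(0, 2) == 2

    def test_random_graph_tree_properties(self, nprng):
        gx = nx.gnp_random_graph(10, 0.4, seed=11)
        while not nx.is_connected(gx):
            gx = nx.gnp_random_graph(10, 0.4, seed=int(nprng.integers(2**31)))
        g = FullMolGraph({v: "C" for v in gx.nodes},
                         {tuple(sorted(e)): "covalent" for e in gx.edges()})
        tree = bfs_covering_tree(g)
        assert len(tree.parent) == 9  # n - 1 tree edges
        tx = nx.Graph([(v, p) for v, p in tree.parent.items()])
        for u in gx.nodes:
            for v in gx.nodes:
                assert tree.dist(u, v) == nx.shortest_path_length(tx, u, v)

    def test_disconnected_rejected(self):
        g = FullMolGraph({0: "C", 1: "C", 2: "C"}, {(0, 1): "covalent"})
        with pytest.raises(ValueError, match="connected"):
            bfs_covering_tree(g)

    def test_default_root_is_highest_degree(self):
        g = FullMolGraph({0: "H", 1: "C", 2: "H", 3: "H"},
                         {(0, 1): "covalent", (1, 2): "covalent",
                          (1, 3): "covalent"})
        assert bfs_covering_tree(g).root == 1


class TestStrategyGrid:
    def test_exactly_42_distinct_unit_directions(self):
        dirs = icosphere_directions()
        assert dirs.shape == (42, 3)
        assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)
        assert len({tuple(np.round(d, 9)) for d in dirs}) == 42

    def test_min_pairwise_separation_positive(self):
        dirs = icosphere_directions()
        for i, j in itertools.combinations(range(42), 2):
            assert np.linalg.norm(dirs[i] - dirs[j]) > 1e-9

    def test_radius_from_edge_type(self):
        cov = strategy_grid("covalent", "C", "C")
        assert cov.radius == pytest.approx(1.52)
        hb = strategy_grid("hbond", "N", "O")
        assert hb.radius == pytest.approx(2.9)


class TestPlacement:
    def _setup(self, g, root=None):
        config = GameConfig()
        tree = bfs_covering_tree(g, root)
        grids = _build_grids(g, tree, config)
        return tree, grids

    def test_child_at_grid_radius_from_root(self):
        g = chain_graph(2)
        tree, grids = self._setup(g)
        pos = {tree.root: np.zeros(3)}
        place_children(tree.root, {1: 17}, pos, tree, grids)
        assert np.linalg.norm(pos[1]) == pytest.approx(grids[(0, 1)].radius)

    def test_aligned_parent_identity_rotation(self):
        g = chain_graph(3)
        tree, grids = self._setup(g, root=0)
        dirs = icosphere_directions()
        pos = {0: np.zeros(3)}
        place_children(0, {1: 5}, pos, tree, grids)
        # put atom 1's parent exactly along the virtual parent slot
        pos[1] = pos[0] - grids[(0, 1)].radius * dirs[0]
        place_children(1, {2: 9}, pos, tree, grids)
        expected = pos[1] + grids[(1, 2)].radius * dirs[9]
        assert np.allclose(pos[2], expected, atol=1e-12)

    def test_parent_slot_alignment(self, nprng):
        """The rotated virtual-parent direction matches the actual parent."""
        g = chain_graph(3)
        tree, grids = self._setup(g, root=0)
        dirs = icosphere_directions()
        for _ in range(20):
            pos = {0: np.zeros(3)}
            pos[1] = nprng.normal(size=3)
            pos[1] *= grids[(0, 1)].radius / np.linalg.norm(pos[1])
            place_children(1, {2: 23}, pos, tree, grids)
            child_dir = (pos[2] - pos[1]) / grids[(1, 2)].radius
            parent_dir = (pos[0] - pos[1]) / np.linalg.norm(pos[0] - pos[1])
            # rotation R satisfies R @ dirs[0] = parent_dir and
            # pos[2] - pos[1] = radius * R @ dirs[23]
            angle_pc = math.acos(np.clip(np.dot(child_dir, parent_dir), -1, 1))
            angle_grid = math.acos(np.clip(np.dot(dirs[23], dirs[0]), -1, 1))
            assert angle_pc == pytest.approx(angle_grid, abs=1e-9)


class TestDirectUtility:
    def test_perfect_tetrahedron_scores_zero(self):
        _, g = make_molecule("methane")
        snap, _ = make_molecule("methane")
        pos = {a.index: a.position for a in snap.atoms}
        assert direct_utility(0, pos, g) == pytest.approx(0.0, abs=1e-9)

    def test_isolated_atom_zero(self):
        g = FullMolGraph({0: "C"}, {})
        assert direct_utility(0, {0: np.zeros(3)}, g) == 0.0

    def test_matches_brute_force_on_perturbed_methane(self, nprng):
        """Exact value agrees with an assignment x rotation brute force."""
        snap, g = make_molecule("methane")
        pos = {a.index: a.position.copy() for a in snap.atoms}
        tilt = Rotation.from_rotvec(np.radians(10.0) * np.array([0, 0, 1.0]))
        pos[1] = tilt.apply(pos[1])  # one H rotated by 10 degrees
        value = direct_utility(0, pos, g, exact=True)

        template = VseprTemplates().lookup(4, 0)
        points = np.array([pos[i] / np.linalg.norm(pos[i])
                           for i in (1, 2, 3, 4)])
        best = np.inf
        for perm in itertools.permutations(range(4)):
            a = template[list(perm)]

            def cost(rv, a=a):
                return np.linalg.norm(
                    a @ Rotation.from_rotvec(rv).as_matrix().T - points,
                    axis=1).sum()

            for _ in range(8):
                res = minimize(cost, nprng.uniform(-2, 2, 3),
                               method="Nelder-Mead",
                               options={"xatol": 1e-9, "fatol": 1e-11,
                                        "maxiter": 800})
                best = min(best, res.fun)
        assert value == pytest.approx(best, abs=1e-3)

    def test_steric_number_above_table_rejected(self):
        g = FullMolGraph({i: "C" for i in range(6)},
                         {(0, i): "covalent" for i in range(1, 6)})
        pos = {0: np.zeros(3)}
        for i in range(1, 6):
            pos[i] = np.eye(3)[i % 3] * (1.0 + i)
        with pytest.raises(ValueError, match="template"):
            direct_utility(0, pos, g)


class TestLocalAndIndirect:
    def test_no_nontree_neighbors_no_intruders_zero(self):
        g = chain_graph(3)
        tree = bfs_covering_tree(g, root=0)
        grids = _build_grids(g, tree, GameConfig())
        pos = {0: np.zeros(3), 1: np.array([1.52, 0, 0]),
               2: np.array([3.04, 0, 0])}
        for w in range(3):
            assert local_term(w, pos, g, tree, grids) == 0.0

    def test_nontree_neighbor_on_sphere_contributes_zero(self):
        # triangle: edge (0,2) is a non-tree bond at exactly ideal length
        g = FullMolGraph({0: "C", 1: "C", 2: "C"},
                         {(0, 1): "covalent", (1, 2): "covalent",
                          (0, 2): "covalent"})
        tree = bfs_covering_tree(g, root=0)
        grids = _build_grids(g, tree, GameConfig())
        pos = {0: np.zeros(3), 1: np.array([1.52, 0, 0])}
        # place 2 at ideal distance from BOTH 0 and 1 (equilateral)
        pos[2] = np.array([0.76, 1.52 * math.sqrt(3) / 2, 0])
        assert local_term(0, pos, g, tree, grids) == pytest.approx(0.0)

    def test_intruder_contributes_its_distance(self):
        # atom 3 not bonded to 0 sits at half the grid radius from it
        g = FullMolGraph({0: "C", 1: "C", 2: "C", 3: "C"},
                         {(0, 1): "covalent", (1, 2): "covalent",
                          (2, 3): "covalent"})
        tree = bfs_covering_tree(g, root=0)
        grids = _build_grids(g, tree, GameConfig())
        pos = {0: np.zeros(3), 1: np.array([1.52, 0, 0]),
               2: np.array([3.04, 0, 0]), 3: np.array([0.76, 0, 0])}
        assert local_term(0, pos, g, tree, grids) == pytest.approx(0.76)

    def test_indirect_leaf_zero(self):
        g = chain_graph(3)
        tree = bfs_covering_tree(g, root=0)
        assert indirect_utility(2, {0: 5.0, 1: 5.0, 2: 5.0}, tree) == 0.0

    def test_indirect_star_hand_value(self):
        g = FullMolGraph({0: "C", 1: "H", 2: "H"},
                         {(0, 1): "covalent", (0, 2): "covalent"})
        tree = bfs_covering_tree(g, root=0)
        assert indirect_utility(0, {0: 9.0, 1: 1.0, 2: 2.0}, tree) == \
            pytest.approx(3.0)  # 1/1 + 2/1; u's own term excluded

    def test_round_cost_arithmetic(self):
        assert round_cost(0.0, 0.0) == 0.0
        assert round_cost(2.0, 4.0) == pytest.approx(3.0)


class TestNormalizedUtility:
    def test_endpoints(self):
        st = PlayerState.fresh((0, 1))
        assert normalized_utility(st, 3, 5.0) == 0.5  # first play: Max=Min
        assert normalized_utility(st, 3, 1.0) == 1.0  # new minimum
        assert normalized_utility(st, 3, 9.0) == 0.0  # new maximum

    def test_interior_value(self):
        st = PlayerState.fresh((0, 1))
        normalized_utility(st, 7, 3.0)
        normalized_utility(st, 7, 5.0)
        assert normalized_utility(st, 7, 4.0) == pytest.approx(0.5)

    def test_per_strategy_histories_independent(self):
        st = PlayerState.fresh((0, 1))
        normalized_utility(st, 0, 10.0)
        assert normalized_utility(st, 1, 10.0) == 0.5  # fresh strategy


class TestLRI:
    def test_zero_utility_is_inaction(self, nprng):
        v = nprng.dirichlet(np.ones(42))
        assert np.array_equal(lri_update(v, 7, 0.0, 0.1), v)

    def test_hand_computed_update(self):
        v = np.zeros(42)
        v[0] = v[1] = 0.5
        out = lri_update(v, 0, 1.0, 0.1)
        assert out[0] == pytest.approx(0.55)
        assert out[1] == pytest.approx(0.45)

    def test_simplex_preserved(self, nprng):
        v = nprng.dirichlet(np.ones(42))
        for _ in range(2000):
            s = int(nprng.integers(42))
            v = lri_update(v, s, float(nprng.uniform()), 0.1)
            assert np.all(v >= 0)
            assert abs(v.sum() - 1.0) < 1e-12

    def test_invalid_inputs_rejected(self):
        v = np.full(42, 1 / 42)
        with pytest.raises(ValueError):
            lri_update(v, 0, 1.5, 0.1)
        with pytest.raises(ValueError):
            lri_update(v, 0, 0.5, 1.5)


class TestRmsd:
    def test_self_zero(self, nprng):
        a = nprng.normal(size=(8, 3))
        assert rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, nprng):
        a = nprng.normal(size=(10, 3)) * 3
        rot = Rotation.random(rng=nprng).as_matrix()
        b = a @ rot.T + np.array([1.0, -2.0, 0.5])
        assert rmsd(a, b, superpose=True) == pytest.approx(0.0, abs=1e-8)
        assert rmsd(a, b, superpose=False) > 0.1

    def test_two_point_closed_form(self):
        a = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        b = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        # optimal superposition leaves a residual of 1.0 exactly
        assert rmsd(a, b, superpose=True) == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestRunGame:
    def test_diatomic_bond_length_is_grid_radius(self):
        g = chain_graph(2)
        res = run_game(g, GameConfig(blocks=1, rounds_per_block=40,
                                     patience=40, seed=1))
        d = np.linalg.norm(res.best_positions[0] - res.best_positions[1])
        assert d == pytest.approx(1.52, abs=1e-12)

    def test_trace_is_non_decreasing_within_block(self):
        g = chain_graph(4)
        res = run_game(g, GameConfig(blocks=2, rounds_per_block=300,
                                     patience=300, seed=4))
        for trace in res.traces:
            assert np.all(np.diff(trace) >= 0)

    def test_shared_vertex_players_equal_cost(self):
        """Players (u, v1), (u, v2) receive the same cost each round."""
        from mdgraphs.game3d import play_round
        snap, g = make_molecule("methane")
        config = GameConfig(seed=2)
        tree = bfs_covering_tree(g)
        grids = _build_grids(g, tree, config)
        players = {(u, v): PlayerState.fresh((u, v))
                   for v, u in sorted(tree.parent.items())}
        templates = VseprTemplates()
        rng = np.random.default_rng(0)
        play_round(g, tree, grids, players, rng, config, templates)
        # all four players share u = 0 (the carbon): identical extremes seen
        extremes = {
            (st.cost_max[st.last_strategy], st.cost_min[st.last_strategy])
            for st in players.values()
        }
        costs = {hi for hi, lo in extremes}
        assert len(costs) == 1

    def test_utilities_bounded(self):
        g = chain_graph(4)
        res = run_game(g, GameConfig(blocks=1, rounds_per_block=200,
                                     patience=200, seed=9))
        assert 0.0 <= res.best_m <= 1.0
        for trace in res.traces:
            assert np.all((trace >= 0.0) & (trace <= 1.0))

    def test_disconnected_rejected(self):
        g = FullMolGraph({0: "C", 1: "C"}, {})
        with pytest.raises(ValueError):
            run_game(g, GameConfig(blocks=1, rounds_per_block=10))

    def test_block_table_format(self):
        g = chain_graph(2)
        res = run_game(g, GameConfig(blocks=3, rounds_per_block=30,
                                     patience=30, seed=5))
        ref = np.array([[0.0, 0, 0], [1.52, 0, 0]])
        table = format_block_table(res, target=ref, atom_order=[0, 1])
        lines = table.splitlines()
        assert lines[0].split()[:2] == ["Block", "1"]
        assert lines[1].startswith("Best mk")
        assert lines[2].startswith("RMSD")
        assert len(lines[1].split()) == 5  # label(2) + one entry per block
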