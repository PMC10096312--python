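"""3D structure generation from a molecular graph by a sequential game.

The input is a hydrogen-inclusive molecular graph (covalent bonds plus any
target H-bonds). Every edge (u, v) of a BFS covering tree, with v a child
of u, is a *player* that repeatedly chooses one of 42 discrete directions on
an icosphere centered on u (icosahedron vertices plus edge midpoints); the
chosen direction, scaled by the edge's ideal bond length, fixes v's position
for the round. No energy function is ever evaluated: the only geometric
guidance is VSEPR — each atom's cost compares the directions of its
neighbors with the ideal electron-domain template for its element — plus a
steric term penalizing non-bonded intrusions. Players learn by
Linear-Reward-Inaction: after each round a normalized utility in [0, 1]
reinforces the played strategy, and the game is restarted over independent
blocks, keeping the structure with the best mean utility m_k.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

__all__ = [
    "FullMolGraph",
    "CoveringTree",
    "StrategyGrid",
    "VseprTemplates",
    "GameConfig",
    "GameResult",
    "bfs_covering_tree",
    "strategy_grid",
    "icosphere_directions",
    "place_children",
    "direct_utility",
    "local_term",
    "indirect_utility",
    "round_cost",
    "normalized_utility",
    "lri_update",
    "run_game",
    "rmsd",
    "format_block_table",
    "DEFAULT_COVALENT_RADII",
    "LONE_PAIRS",
]

# Covalent radii (Angstrom) used for ideal covalent bond lengths r(u)+r(v).
DEFAULT_COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02,
}

# Electron lone pairs per element, used to pick the VSEPR template variant.
LONE_PAIRS = {"H": 0, "C": 0, "N": 1, "O": 2, "S": 2, "F": 3, "Cl": 3, "B": 0,
              "P": 1}

DEFAULT_HBOND_RADIUS = 2.9  # Angstrom, heavy-heavy ideal H-bond length


# ---------------------------------------------------------------------------
# Graph and covering tree

@dataclass(frozen=True)
class FullMolGraph:
    """Hydrogen-inclusive molecular graph: the input of the game.

    ``bonds`` maps sorted vertex pairs to an edge kind, ``"covalent"`` or
    ``"hbond"`` (a *target* hydrogen bond the structure should realize).
    """

    elements: Mapping[int, str]
    bonds: Mapping[tuple[int, int], str]

    def __post_init__(self):
        object.__setattr__(self, "elements", dict(self.elements))
        bonds = {}
        for (a, b), kind in dict(self.bonds).items():
            if kind not in ("covalent", "hbond"):
                raise ValueError(f"unknown bond kind {kind!r}")
            if a not in self.elements or b not in self.elements:
                raise ValueError(f"bond ({a},{b}) has an unknown endpoint")
            bonds[tuple(sorted((a, b)))] = kind
        object.__setattr__(self, "bonds", bonds)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbors(self, u: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == u:
                out.append(b)
            elif b == u:
                out.append(a)
        return sorted(out)

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {v: [] for v in self.elements}
        for a, b in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        return {v: sorted(ns) for v, ns in adj.items()}

    def is_connected(self) -> bool:
        if not self.elements:
            return True
        adj = self.adjacency()
        seen = {next(iter(self.elements))}
        stack = list(seen)
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == len(self.elements)


@dataclass(frozen=True)
class CoveringTree:
    """BFS covering tree: parent/children maps, BFS order, tree distances."""

    root: int
    parent: Mapping[int, int]
    children: Mapping[int, tuple[int, ...]]
    order: tuple[int, ...]
    depth: Mapping[int, int]

    def dist(self, u: int, v: int) -> int:
        """Path length between u and v inside the tree (via lowest ancestor)."""
        du, dv = self.depth[u], self.depth[v]
        a, b, d = u, v, 0
        while self.depth[a] > self.depth[b]:
            a, d = self.parent[a], d + 1
        while self.depth[b] > self.depth[a]:
            b, d = self.parent[b], d + 1
        while a != b:
            a, b, d = self.parent[a], self.parent[b], d + 2
        return d

    def descendants(self, u: int) -> list[int]:
        """Proper descendants of u, in BFS-discovery order."""
        out: list[int] = []
        stack = list(self.children[u])
        while stack:
            w = stack.pop()
            out.append(w)
            stack.extend(self.children[w])
        return out


def bfs_covering_tree(g: FullMolGraph, root: int | None = None) -> CoveringTree:
    """BFS tree with ascending-id neighbor order; root defaults to the
    highest-degree vertex (ties to the lowest id)."""
    if not g.is_connected():
        raise ValueError("graph must be connected to build a covering tree")
    adj = g.adjacency()
    if root is None:
        root = min(adj, key=lambda v: (-len(adj[v]), v))
    if root not in g.elements:
        raise ValueError(f"root {root} is not a vertex")
    parent: dict[int, int] = {}
    children: dict[int, list[int]] = {v: [] for v in g.elements}
    depth = {root: 0}
    order = [root]
    queue = [root]
    while queue:
        u = queue.pop(0)
        for w in adj[u]:
            if w not in depth:
                depth[w] = depth[u] + 1
                parent[w] = u
                children[u].append(w)
                order.append(w)
                queue.append(w)
    return CoveringTree(
        root=root,
        parent=parent,
        children={u: tuple(c) for u, c in children.items()},
        order=tuple(order),
        depth=depth,
    )


# ---------------------------------------------------------------------------
# Strategy grid (icosphere)

def icosphere_directions() -> np.ndarray:
    """The 42 unit directions: icosahedron vertices + edge midpoints.

    Deterministic order (lexicographic after rounding); index 0 is the
    designated *parent slot* used by the alignment rotation.
    """
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            verts.append((0.0, a, b))
            verts.append((a, b, 0.0))
            verts.append((b, 0.0, a))
    verts = np.array(verts)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    # icosahedron edges connect vertex pairs at the minimal pairwise distance
    d2 = np.sum((verts[:, None, :] - verts[None, :, :]) ** 2, axis=-1)
    min_d2 = np.min(d2[d2 > 1e-9])
    mids = []
    for i in range(12):
        for j in range(i + 1, 12):
            if abs(d2[i, j] - min_d2) < 1e-9:
                m = verts[i] + verts[j]
                mids.append(m / np.linalg.norm(m))
    dirs = np.vstack([verts, np.array(mids)])
    key = np.round(dirs, 9)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    return dirs[order]


@dataclass(frozen=True)
class StrategyGrid:
    """42 unit directions and the radius (ideal bond length) of one player."""

    directions: np.ndarray
    radius: float

    def __post_init__(self):
        if self.directions.shape != (42, 3):
            raise ValueError("strategy grid must hold exactly 42 directions")
        if self.radius <= 0:
            raise ValueError("grid radius must be positive")

    @property
    def n_strategies(self) -> int:
        return len(self.directions)


def strategy_grid(
    edge_kind: str,
    element_u: str,
    element_v: str,
    covalent_radii: Mapping[str, float] = DEFAULT_COVALENT_RADII,
    hbond_radius: float = DEFAULT_HBOND_RADIUS,
) -> StrategyGrid:
    """Grid for player (u, v): icosphere directions at the edge's ideal length."""
    if edge_kind == "covalent":
        radius = covalent_radii[element_u] + covalent_radii[element_v]
    elif edge_kind == "hbond":
        radius = hbond_radius
    else:
        raise ValueError(f"unknown edge kind {edge_kind!r}")
    return StrategyGrid(icosphere_directions(), radius)


# ---------------------------------------------------------------------------
# Placement

def _align_rotation(target: np.ndarray) -> np.ndarray:
    """Minimal-angle rotation taking the parent slot (direction 0) to target."""
    src = icosphere_directions()[0]
    target = target / np.linalg.norm(target)
    cross = np.cross(src, target)
    dot = float(np.dot(src, target))
    if np.linalg.norm(cross) < 1e-12:
        if dot > 0:
            return np.eye(3)
        # antiparallel: rotate 180 degrees about any axis orthogonal to src
        axis = np.cross(src, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(src, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(math.pi * axis).as_matrix()
    axis = cross / np.linalg.norm(cross)
    angle = math.atan2(np.linalg.norm(cross), dot)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def place_children(
    u: int,
    strategies: Mapping[int, int],
    positions: dict[int, np.ndarray],
    tree: CoveringTree,
    grids: Mapping[tuple[int, int], StrategyGrid],
) -> dict[int, np.ndarray]:
    """Place u's tree children on u's icosphere, aligned to u's parent.

    The icosphere around u is rotated (minimal-angle rotation) so that its
    designated parent slot points at the actual position of u's parent; each
    child v then lands at ``p(u) + R (radius_uv * direction[s_uv])``. The
    root's icosphere is used unrotated.
    """
    if u == tree.root:
        rot = np.eye(3)
    else:
        w = tree.parent[u]
        rot = _align_rotation(positions[w] - positions[u])
    for v in tree.children[u]:
        grid = grids[(u, v)]
        d = grid.directions[strategies[v]]
        positions[v] = positions[u] + rot @ (grid.radius * d)
    return positions


# ---------------------------------------------------------------------------
# VSEPR templates

def _cone_directions(n: int, mutual_angle_deg: float) -> np.ndarray:
    """n directions, azimuths 2pi/n apart, with the given mutual angle."""
    beta = math.radians(mutual_angle_deg)
    # cos(beta) = cos^2(t) + sin^2(t) cos(2 pi / n), t = polar angle
    c = (math.cos(beta) - math.cos(2 * math.pi / n)) / (1 - math.cos(2 * math.pi / n))
    c = min(max(c, 0.0), 1.0)
    t = math.acos(math.sqrt(c))
    out = []
    for k in range(n):
        a = 2 * math.pi * k / n
        out.append((math.sin(t) * math.cos(a), math.sin(t) * math.sin(a),
                    math.cos(t)))
    return np.array(out)


def _bent(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([[0.0, 0.0, 1.0], [math.sin(a), 0.0, math.cos(a)]])


@dataclass(frozen=True)
class VseprTemplates:
    """Ideal unit-direction sets keyed by (bonded neighbors, lone pairs)."""

    table: Mapping[tuple[int, int], np.ndarray] = field(default_factory=lambda: {
        (1, 0): np.array([[0.0, 0.0, 1.0]]),
        (2, 0): np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]),  # linear
        (2, 1): _bent(107.0),
        (2, 2): _bent(104.5),
        (3, 0): _cone_directions(3, 120.0),  # trigonal planar
        (3, 1): _cone_directions(3, 107.0),  # trigonal pyramidal
        (4, 0): np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]])
        / math.sqrt(3.0),  # tetrahedral
    })

    def lookup(self, n_neighbors: int, lone_pairs: int) -> np.ndarray:
        if n_neighbors > 4:
            raise ValueError(
                f"no VSEPR template for {n_neighbors} bonded neighbors"
            )
        for lp in range(lone_pairs, -1, -1):
            if (n_neighbors, lp) in self.table:
                return self.table[(n_neighbors, lp)]
        raise ValueError(
            f"no VSEPR template for ({n_neighbors} neighbors, {lone_pairs} lone pairs)"
        )


def _kabsch_all_perms(template: np.ndarray, points: np.ndarray) -> tuple[float, int, np.ndarray]:
    """Best (sum-of-distances, perm index, rotation) over slot assignments.

    For each assignment the rotation comes from a least-squares (Kabsch)
    alignment of the assigned template directions onto the observed ones.
    """
    n = len(points)
    perms = np.array(list(itertools.permutations(range(n))))
    a = template[perms]  # (m, n, 3) template directions per assignment
    h = np.einsum("mni,nj->mij", a, points)  # cross-covariance
    u_, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("mij,mjk->mik", u_, vt))
    d = np.ones((len(perms), 3))
    d[:, 2] = np.sign(det)
    # R maps template -> points: R = (U diag(d) Vt)^T per matrix algebra below
    r = np.einsum("mij,mj,mjk->mki", u_, d, vt)
    rotated = np.einsum("mkj,mnj->mnk", r, a)
    costs = np.linalg.norm(rotated - points[None, :, :], axis=-1).sum(axis=1)
    best = int(np.argmin(costs))
    return float(costs[best]), best, r[best]


def direct_utility(
    u: int,
    positions: Mapping[int, np.ndarray],
    graph: FullMolGraph,
    templates: VseprTemplates | None = None,
    lone_pairs: Mapping[str, int] = LONE_PAIRS,
    exact: bool = True,
) -> float:
    """VSEPR discomfort of atom u: distance of neighbors to ideal slots.

    The directions from u to all its graph neighbors (normalized onto the
    unit sphere, i.e. projected onto u's icosphere) are matched against the
    element's ideal template: the value is the minimum over neighbor-to-slot
    assignments and rigid template rotations of the summed Euclidean
    distances. With ``exact=False`` the rotation of each assignment is the
    least-squares (Kabsch) one, a fast and very close surrogate used inside
    the game loop.
    """
    templates = templates or VseprTemplates()
    nbrs = graph.neighbors(u)
    if not nbrs:
        return 0.0
    dirs = []
    for v in nbrs:
        d = np.asarray(positions[v], dtype=float) - np.asarray(positions[u], dtype=float)
        norm = np.linalg.norm(d)
        dirs.append(d / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0]))
    points = np.array(dirs)
    template = templates.lookup(len(nbrs), lone_pairs.get(graph.elements[u], 0))
    cost, best_perm, r = _kabsch_all_perms(template, points)
    if not exact or len(nbrs) == 1:
        return cost if len(nbrs) > 1 else 0.0
    # polish the best assignment: minimize the *sum of distances* over rotations
    perm = list(itertools.permutations(range(len(nbrs))))[best_perm]
    a = template[list(perm)]

    def objective(rotvec: np.ndarray) -> float:
        rr = Rotation.from_rotvec(rotvec).as_matrix() @ r
        return float(np.linalg.norm(a @ rr.T - points, axis=1).sum())

    res = minimize(objective, np.zeros(3), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400})
    return float(min(cost, res.fun))


# ---------------------------------------------------------------------------
# Local / indirect terms and costs

def _grid_radius_of(u: int, grids: Mapping[tuple[int, int], StrategyGrid]) -> float:
    radii = [g.radius for (a, b), g in grids.items() if u in (a, b)]
    return max(radii) if radii else 0.0


def local_term(
    w: int,
    positions: Mapping[int, np.ndarray],
    graph: FullMolGraph,
    tree: CoveringTree,
    grids: Mapping[tuple[int, int], StrategyGrid],
    hbond_radius: float = DEFAULT_HBOND_RADIUS,
) -> float:
    """Local discomfort of w: non-tree bond violations + steric intruders.

    First sum: for every graph neighbor v of w that is *not* a tree child or
    parent of w, the distance between v's actual position and its projection
    onto w's icosphere (the sphere at the edge's ideal length) — zero exactly
    when the non-tree bond has its ideal length. Second sum: for every vertex
    z not bonded to w whose distance to w is within w's grid radius, that
    distance is added (a steric-intrusion penalty).
    """
    pw = np.asarray(positions[w], dtype=float)
    tree_adj = set(tree.children[w])
    if w != tree.root:
        tree_adj.add(tree.parent[w])
    total = 0.0
    bonded = set(graph.neighbors(w))
    for v in sorted(bonded - tree_adj):
        pv = np.asarray(positions[v], dtype=float)
        d = np.linalg.norm(pv - pw)
        kind = graph.bonds[tuple(sorted((w, v)))]
        if kind == "covalent":
            ideal = (DEFAULT_COVALENT_RADII[graph.elements[w]]
                     + DEFAULT_COVALENT_RADII[graph.elements[v]])
        else:
            ideal = hbond_radius
        if d > 1e-12:
            proj = pw + ideal * (pv - pw) / d
            total += float(np.linalg.norm(proj - pv))
        else:
            total += ideal
    r_w = _grid_radius_of(w, grids)
    for z in graph.elements:
        if z == w or z in bonded:
            continue
        d = float(np.linalg.norm(np.asarray(positions[z], dtype=float) - pw))
        if d <= r_w:
            total += d
    return total


def indirect_utility(
    u: int,
    local_terms: Mapping[int, float],
    tree: CoveringTree,
) -> float:
    """Impact of u's placement on its subtree: sum of local(v)/dist_T(u, v)
    over proper descendants v of u (a leaf scores 0)."""
    total = 0.0
    for v in tree.descendants(u):
        total += local_terms[v] / tree.dist(u, v)
    return total


def round_cost(direct: float, indirect: float) -> float:
    """Player cost R_k(u, v) = (Direct_k(u) + Indirect_k(u)) / 2 — the same
    for every player sharing the vertex u."""
    return 0.5 * (direct + indirect)


# ---------------------------------------------------------------------------
# Learning

@dataclass
class PlayerState:
    """One player (u, v): strategy probabilities + per-strategy cost extremes."""

    player: tuple[int, int]
    probabilities: np.ndarray
    cost_max: np.ndarray  # running Max(s) of R over rounds that played s
    cost_min: np.ndarray  # running Min(s)
    played: np.ndarray  # whether s has ever been played
    global_max: float = -np.inf  # extremes of R over all strategies
    global_min: float = np.inf
    last_strategy: int = -1

    @classmethod
    def fresh(cls, player: tuple[int, int], n: int = 42) -> "PlayerState":
        return cls(
            player=player,
            probabilities=np.full(n, 1.0 / n),
            cost_max=np.full(n, -np.inf),
            cost_min=np.full(n, np.inf),
            played=np.zeros(n, dtype=bool),
        )


def normalized_utility(state: PlayerState, strategy: int, cost: float) -> float:
    """U = (Max(s) - R) / (Max(s) - Min(s)) with running per-strategy extremes
    (current round included).

    When Max(s) = Min(s) the formula is undefined. This happens on a
    strategy's first play, but also *persistently* whenever a player's cost
    is a deterministic function of its own strategy (e.g. a chain atom whose
    subtree is clash-free): every strategy then repeats its own cost forever
    and a flat fallback would leave the player with no learning signal at
    all. The degenerate case therefore falls back to the player's running
    extremes across all strategies, which ranks deterministic strategies by
    their cost; only a player that has seen a single cost value overall gets
    the neutral 0.5.
    """
    state.played[strategy] = True
    state.cost_max[strategy] = max(state.cost_max[strategy], cost)
    state.cost_min[strategy] = min(state.cost_min[strategy], cost)
    state.global_max = max(state.global_max, cost)
    state.global_min = min(state.global_min, cost)
    hi, lo = state.cost_max[strategy], state.cost_min[strategy]
    if hi - lo < 1e-15:
        ghi, glo = state.global_max, state.global_min
        if ghi - glo < 1e-15:
            return 0.5
        return float((ghi - cost) / (ghi - glo))
    return float((hi - cost) / (hi - lo))


def lri_update(
    probabilities: np.ndarray, strategy: int, utility: float, b: float
) -> np.ndarray:
    """Linear-Reward-Inaction step; preserves the probability simplex.

    The played strategy gains ``(1 - V(s)) * b * u``; every other one loses
    ``V(s') * b * u``. With u = 0 the vector is unchanged (inaction).
    """
    if not (0.0 <= utility <= 1.0):
        raise ValueError("utility must lie in [0, 1]")
    if not (0.0 <= b <= 1.0):
        raise ValueError("slowing factor b must lie in [0, 1]")
    v = probabilities.copy()
    step = b * utility
    v -= v * step
    v[strategy] = probabilities[strategy] + (1.0 - probabilities[strategy]) * step
    assert np.all(v >= 0.0)
    return v


# ---------------------------------------------------------------------------
# The game loop

@dataclass
class GameConfig:
    """Run parameters: block/round counts, learning rate, stop patience."""

    blocks: int = 10
    rounds_per_block: int = 5000
    b: float = 0.1  # LRI slowing factor
    patience: int = 500  # stop a block after this many non-improving rounds
    seed: int = 0
    hbond_radius: float = DEFAULT_HBOND_RADIUS
    root: int | None = None
    covalent_radii: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVALENT_RADII))


@dataclass
class GameResult:
    """Best structure found plus per-block diagnostics."""

    best_positions: dict[int, np.ndarray]
    best_m: float
    best_block: int
    block_best_m: list[float]
    block_best_cost: list[float]
    block_best_positions: list[dict[int, np.ndarray]]
    block_rounds: list[int]
    traces: list[np.ndarray]  # per block: running best m_k per round
    tree: CoveringTree | None = None


def _build_grids(
    graph: FullMolGraph, tree: CoveringTree, config: GameConfig
) -> dict[tuple[int, int], StrategyGrid]:
    grids = {}
    for v, u in tree.parent.items():
        kind = graph.bonds[tuple(sorted((u, v)))]
        grids[(u, v)] = strategy_grid(
            kind, graph.elements[u], graph.elements[v],
            config.covalent_radii, config.hbond_radius)
    return grids


def play_round(
    graph: FullMolGraph,
    tree: CoveringTree,
    grids: Mapping[tuple[int, int], StrategyGrid],
    players: dict[tuple[int, int], PlayerState],
    rng: np.random.Generator,
    config: GameConfig,
    templates: VseprTemplates,
) -> tuple[dict[int, np.ndarray], float, float]:
    """One round: sample, place, score, learn -> (positions, m_k, mean cost).

    The mean player cost is returned alongside m_k because m_k is a
    *relative* (per-strategy-history) measure: in small systems it saturates
    at 1.0, so ties are resolved on the raw cost the players minimize."""
    strategies: dict[int, int] = {}
    for (u, v), st in players.items():
        s = int(rng.choice(42, p=st.probabilities))
        st.last_strategy = s
        strategies[v] = s
    positions: dict[int, np.ndarray] = {tree.root: np.zeros(3)}
    for u in tree.order:
        if tree.children[u]:
            place_children(u, strategies, positions, tree, grids)

    locals_ = {
        w: local_term(w, positions, graph, tree, grids, config.hbond_radius)
        for w in graph.elements
    }
    parents = {u for u in tree.order if tree.children[u]}
    costs = {
        u: round_cost(
            direct_utility(u, positions, graph, templates, exact=False),
            indirect_utility(u, locals_, tree),
        )
        for u in parents
    }
    utilities = []
    player_costs = []
    for (u, v), st in players.items():
        uk = normalized_utility(st, st.last_strategy, costs[u])
        utilities.append(uk)
        player_costs.append(costs[u])
        st.probabilities = lri_update(st.probabilities, st.last_strategy,
                                      uk, config.b)
    m_k = float(np.mean(utilities))
    return positions, m_k, float(np.mean(player_costs))


def run_game(graph: FullMolGraph, config: GameConfig | None = None) -> GameResult:
    """Run the sequential game over independent blocks.

    Each block restarts strategies and cost histories, plays rounds until
    the block budget or ``patience`` non-improving rounds, and records the
    positions at its best mean utility m_k; the overall best block wins.
    """
    config = config or GameConfig()
    if graph.n_atoms == 0:
        raise ValueError("empty graph")
    if not graph.is_connected():
        raise ValueError("graph must be connected")
    tree = bfs_covering_tree(graph, config.root)
    grids = _build_grids(graph, tree, config)
    templates = VseprTemplates()
    rng = np.random.default_rng(config.seed)

    block_best_m: list[float] = []
    block_best_cost: list[float] = []
    block_best_pos: list[dict[int, np.ndarray]] = []
    block_rounds: list[int] = []
    traces: list[np.ndarray] = []
    for _ in range(config.blocks):
        players = {
            (u, v): PlayerState.fresh((u, v))
            for v, u in sorted(tree.parent.items())
        }
        best_m = -np.inf
        best_cost = np.inf
        best_pos: dict[int, np.ndarray] = {}
        stall = 0
        trace = []
        rounds = 0
        for _k in range(config.rounds_per_block):
            positions, m_k, cost_k = play_round(graph, tree, grids, players,
                                                rng, config, templates)
            rounds += 1
            # primary key: best mean utility m_k; ties (m_k saturates at 1.0
            # in small systems) resolved on the round's mean player cost.
            # a round counts as an improvement when the tracked best solution
            # improves under this key.
            if (m_k, -cost_k) > (best_m, -best_cost):
                stall = 0
            else:
                stall += 1
            if (m_k, -cost_k) >= (best_m, -best_cost):
                best_m, best_cost = m_k, cost_k
                best_pos = {v: p.copy() for v, p in positions.items()}
            trace.append(best_m)
            if stall >= config.patience:
                break
        block_best_m.append(best_m)
        block_best_cost.append(best_cost)
        block_best_pos.append(best_pos)
        block_rounds.append(rounds)
        traces.append(np.array(trace))

    best_block = max(range(config.blocks),
                     key=lambda i: (block_best_m[i], -block_best_cost[i]))
    return GameResult(
        best_positions=block_best_pos[best_block],
        best_m=block_best_m[best_block],
        best_block=best_block + 1,
        block_best_m=block_best_m,
        block_best_cost=block_best_cost,
        block_best_positions=block_best_pos,
        block_rounds=block_rounds,
        traces=traces,
        tree=tree,
    )


# ---------------------------------------------------------------------------
# Evaluation

def rmsd(a: np.ndarray, b: np.ndarray, superpose: bool = True) -> float:
    """Root-mean-square deviation between paired structures, in Angstrom.

    With ``superpose`` the minimum over rigid rotations and translations
    (least-squares superposition) is returned; otherwise the raw deviation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("structures must be matching (n, 3) arrays")
    if len(a) == 0:
        raise ValueError("empty structures")
    if not superpose:
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    if len(a) == 1:
        return 0.0
    import warnings

    with warnings.catch_warnings():
        # collinear point sets make the optimal rotation non-unique; any
        # minimizer gives the same residual, so the warning is benign
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(ac, bc)
    return float(np.sqrt(np.mean(np.sum((ac - rot.apply(bc)) ** 2, axis=1))))


def format_block_table(result: GameResult,
                       target: np.ndarray | None = None,
                       atom_order: Sequence[int] | None = None) -> str:
    """Per-block report: best m_k (and RMSD to a target when given)."""
    ids = list(atom_order) if atom_order is not None else sorted(
        result.best_positions)
    header = ["Block"] + [str(i + 1) for i in range(len(result.block_best_m))]
    rows = [header, ["Best mk"] + [f"{m:.3f}" for m in result.block_best_m]]
    if target is not None:
        rmsds = []
        for pos in result.block_best_positions:
            coords = np.array([pos[i] for i in ids])
            rmsds.append(rmsd(coords, np.asarray(target), superpose=True))
        rows.append(["RMSD"] + [f"{r:.3f}" for r in rmsds])
    widths = [max(len(r[c]) for r in rows) for c in range(len(header))]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)) for row in rows
    )
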