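"""Synthetic molecules, scripted trajectories and lattice water sheets.

Everything the package analyzes in its tests and examples is generated
here, from closed-form geometry: small molecules (water, methane, ammonia,
a water dimer), peptide-like chains with the printed compositions
(NH3+-Ala3-COOH-like, C9H18N3O4; a benzyl-capped hexa-alanine-like chain,
C26H39N7O8, 80 atoms), bare carbon chains, hexagonal water sheets whose
H-bond network is a honeycomb, and scripted trajectories whose conformer
schedule is known by construction — the ground truth end-to-end tests run
against.

Peptide-like fixtures are topology-faithful (correct composition and bond
graph, idealized extended geometry); they are synthetic stand-ins, not
DFT-quality structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .chemio import Atom, Snapshot, Trajectory, load_params
from .game3d import FullMolGraph
from .isomorph import canonical_key
from .molgraph import MolGraph, build_molgraph

__all__ = [
    "make_molecule",
    "make_carbon_chain",
    "make_water_sheet",
    "make_ring_chain_graph",
    "TrajectoryScript",
    "make_scripted_trajectory",
    "MOLECULE_NAMES",
]

MOLECULE_NAMES = ("water", "methane", "ammonia", "water_dimer",
                  "triala_like", "zala6_like")

# bond lengths (Angstrom) / angles (deg) used by the geometry builders
_OH, _NH, _CH = 0.9572, 1.01, 1.09
_HOH, _HNH = 104.5, 107.0


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d from internal coordinates w.r.t. frame atoms a-b-c."""
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(chi),
        bond * math.sin(theta) * math.sin(chi),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


class _Builder:
    """Incremental structure builder tracking atoms and covalent bonds."""

    def __init__(self):
        self.elements: list[str] = []
        self.coords: list[np.ndarray] = []
        self.bonds: set[tuple[int, int]] = set()

    def add(self, element: str, xyz, bond_to: int | None = None) -> int:
        self.elements.append(element)
        self.coords.append(np.asarray(xyz, dtype=float))
        idx = len(self.elements) - 1
        if bond_to is not None:
            self.bonds.add(tuple(sorted((bond_to, idx))))
        return idx

    def add_nerf(self, element: str, a: int, b: int, c: int,
                 bond: float, angle: float, dihedral: float) -> int:
        xyz = _nerf(self.coords[a], self.coords[b], self.coords[c],
                    bond, angle, dihedral)
        return self.add(element, xyz, bond_to=c)

    def snapshot(self, frame: int = 0) -> Snapshot:
        atoms = tuple(Atom(i, el, xyz)
                      for i, (el, xyz) in enumerate(zip(self.elements, self.coords)))
        return Snapshot(frame, atoms)

    def graph(self, hbonds: set[tuple[int, int]] = frozenset()) -> FullMolGraph:
        bonds = {p: "covalent" for p in self.bonds}
        for p in hbonds:
            bonds[tuple(sorted(p))] = "hbond"
        return FullMolGraph(dict(enumerate(self.elements)), bonds)


def _water(b: _Builder, origin, axis_deg: float = 0.0) -> tuple[int, int, int]:
    o = b.add("O", origin)
    half = math.radians(_HOH) / 2
    rot = math.radians(axis_deg)
    for sign in (+1, -1):
        a = rot + sign * half
        h = b.add("H", np.asarray(origin) + _OH * np.array(
            [math.cos(a), math.sin(a), 0.0]), bond_to=o)
    return o, o + 1, o + 2


def _make_water() -> _Builder:
    b = _Builder()
    _water(b, (0.0, 0.0, 0.0))
    return b


def _make_methane() -> _Builder:
    b = _Builder()
    c = b.add("C", (0.0, 0.0, 0.0))
    for v in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        b.add("H", _CH * np.array(v) / math.sqrt(3.0), bond_to=c)
    return b


def _make_ammonia() -> _Builder:
    b = _Builder()
    n = b.add("N", (0.0, 0.0, 0.0))
    beta = math.radians(_HNH)
    cos_t2 = (math.cos(beta) - math.cos(2 * math.pi / 3)) / (1 - math.cos(2 * math.pi / 3))
    t = math.acos(math.sqrt(max(cos_t2, 0.0)))
    for k in range(3):
        a = 2 * math.pi * k / 3
        b.add("H", _NH * np.array([math.sin(t) * math.cos(a),
                                   math.sin(t) * math.sin(a),
                                   math.cos(t)]), bond_to=n)
    return b


def _make_water_dimer() -> tuple[_Builder, set[tuple[int, int]]]:
    """Donor water H-bonded to an acceptor water, O-O 2.9 A, D-H...A 180."""
    b = _Builder()
    o1 = b.add("O", (0.0, 0.0, 0.0))
    b.add("H", (_OH, 0.0, 0.0), bond_to=o1)  # bridging H, on the O-O axis
    a2 = math.radians(_HOH)
    b.add("H", _OH * np.array([math.cos(a2), math.sin(a2), 0.0]), bond_to=o1)
    o2 = b.add("O", (2.9, 0.0, 0.0))
    # acceptor H's point away from the donor, tilted out of the O-O axis
    half = math.radians(_HOH) / 2
    for sign in (+1, -1):
        b.add("H", np.array([2.9, 0.0, 0.0]) + _OH * np.array(
            [math.cos(sign * half + math.radians(52.25)),
             math.sin(sign * half + math.radians(52.25)), 0.0]), bond_to=o2)
    return b, {(o1, o2)}


def _append_alanine(b: _Builder, prev_c: int, prev_frame: tuple[int, int]) -> tuple[int, int, tuple[int, int]]:
    """Append one -NH-CH(CH3)-CO- unit to carbonyl carbon ``prev_c``.

    ``prev_frame`` supplies the two atoms before prev_c for the NeRF frame.
    Returns (amide N, new carbonyl C, frame for the next residue).
    """
    f1, f2 = prev_frame
    n = b.add_nerf("N", f1, f2, prev_c, 1.33, 116.0, 180.0)
    b.add_nerf("H", f2, prev_c, n, _NH, 119.0, 0.0)
    ca = b.add_nerf("C", f2, prev_c, n, 1.46, 121.7, 180.0)
    cp = b.add_nerf("C", prev_c, n, ca, 1.52, 110.0, 180.0)
    b.add_nerf("O", n, ca, cp, 1.23, 121.0, 0.0)
    cb = b.add_nerf("C", cp, n, ca, 1.52, 109.5, 122.0)
    b.add_nerf("H", cp, n, ca, _CH, 109.5, -118.0)
    for chi in (60.0, 180.0, 300.0):
        b.add_nerf("H", n, ca, cb, _CH, 109.5, chi)
    return n, cp, (n, ca)


def _make_triala() -> tuple[_Builder, set[tuple[int, int]]]:
    """NH3+-Ala3-COOH-like chain, C9H18N3O4 (34 atoms), extended geometry.

    The returned graph carries one target H-bond between the N-terminus
    nitrogen and the carbonyl oxygen of the terminal COOH.
    """
    b = _Builder()
    n1 = b.add("N", (0.0, 0.0, 0.0))
    ca = b.add("C", (1.46, 0.0, 0.0), bond_to=n1)
    ang = math.radians(180.0 - 110.0)
    cp = b.add("C", np.array([1.46, 0.0, 0.0]) + 1.52 * np.array(
        [math.cos(ang), math.sin(ang), 0.0]), bond_to=ca)
    for chi in (60.0, 180.0, 300.0):  # NH3+ terminus
        b.add_nerf("H", cp, ca, n1, _NH, 109.5, chi)
    b.add_nerf("O", n1, ca, cp, 1.23, 121.0, 0.0)
    cb = b.add_nerf("C", cp, n1, ca, 1.52, 109.5, 122.0)
    b.add_nerf("H", cp, n1, ca, _CH, 109.5, -118.0)
    for chi in (60.0, 180.0, 300.0):
        b.add_nerf("H", n1, ca, cb, _CH, 109.5, chi)
    frame = (n1, ca)
    prev_c = cp
    for _ in range(2):
        _, prev_c, frame = _append_alanine(b, prev_c, frame)
    # terminal COOH: hydroxyl O + its H on the last carbonyl carbon
    oh = b.add_nerf("O", frame[0], frame[1], prev_c, 1.34, 115.0, 180.0)
    b.add_nerf("H", frame[1], prev_c, oh, 0.96, 105.0, 180.0)
    carbonyl_o = [i for i in _bond_partners(b, prev_c)
                  if b.elements[i] == "O" and i != oh][0]
    return b, {(n1, carbonyl_o)}


def _bond_partners(b: _Builder, idx: int) -> list[int]:
    out = []
    for i, j in b.bonds:
        if i == idx:
            out.append(j)
        elif j == idx:
            out.append(i)
    return sorted(out)


def _make_zala6() -> tuple[_Builder, set[tuple[int, int]]]:
    """Benzyl-capped hexa-alanine-like chain, C26H39N7O8 (80 atoms).

    Built as Ph-CH2-NH-CO-(Ala)6-OH, which reproduces the printed
    composition exactly; idealized extended geometry.
    """
    b = _Builder()
    ring = []
    for k in range(6):  # phenyl ring in the xy-plane, C-C 1.39 A
        a = 2 * math.pi * k / 6
        ring.append(b.add("C", 1.39 * np.array([math.cos(a), math.sin(a), 0.0])))
    for i, j in zip(ring, ring[1:] + ring[:1]):
        b.bonds.add(tuple(sorted((i, j))))
    for k in range(1, 6):  # H on five ring carbons, radial
        a = 2 * math.pi * k / 6
        b.add("H", (1.39 + _CH) * np.array([math.cos(a), math.sin(a), 0.0]),
              bond_to=ring[k])
    ch2 = b.add("C", (1.39 + 1.50) * np.array([1.0, 0.0, 0.0]), bond_to=ring[0])
    for sign in (+1, -1):
        b.add_nerf("H", ring[1], ring[0], ch2, _CH, 109.5, sign * 121.0)
    n0 = b.add_nerf("N", ring[1], ring[0], ch2, 1.47, 112.0, 0.0)
    b.add_nerf("H", ring[0], ch2, n0, _NH, 118.0, 90.0)
    cp0 = b.add_nerf("C", ring[0], ch2, n0, 1.35, 122.0, 270.0)
    b.add_nerf("O", ch2, n0, cp0, 1.23, 121.0, 0.0)
    frame = (ch2, n0)
    prev_c = cp0
    first_res_n = None
    for r in range(6):
        res_n, prev_c, frame = _append_alanine(b, prev_c, frame)
        if r == 0:
            first_res_n = res_n
    oh = b.add_nerf("O", frame[0], frame[1], prev_c, 1.34, 115.0, 180.0)
    b.add_nerf("H", frame[1], prev_c, oh, 0.96, 105.0, 180.0)
    carbonyl_o = [i for i in _bond_partners(b, prev_c)
                  if b.elements[i] == "O" and i != oh][0]
    return b, {(first_res_n, carbonyl_o)}


def make_molecule(name: str) -> tuple[Snapshot, FullMolGraph]:
    """Idealized coordinates + hydrogen-inclusive graph for a named fixture."""
    if name == "water":
        b, hb = _make_water(), set()
    elif name == "methane":
        b, hb = _make_methane(), set()
    elif name == "ammonia":
        b, hb = _make_ammonia(), set()
    elif name == "water_dimer":
        b, hb = _make_water_dimer()
    elif name == "triala_like":
        b, hb = _make_triala()
    elif name == "zala6_like":
        b, hb = _make_zala6()
    else:
        raise ValueError(f"unknown molecule fixture {name!r}; "
                         f"known: {MOLECULE_NAMES}")
    return b.snapshot(), b.graph(hb)


def make_carbon_chain(n: int = 5) -> tuple[Snapshot, FullMolGraph]:
    """Bare n-carbon chain along x (two-neighbor carbons: linear VSEPR)."""
    if n < 2:
        raise ValueError("chain needs at least 2 atoms")
    b = _Builder()
    prev = None
    for i in range(n):
        prev = b.add("C", (1.52 * i, 0.0, 0.0), bond_to=prev)
    return b.snapshot(), b.graph()


# ---------------------------------------------------------------------------
# Hexagonal water sheet

def _eulerian_orientation(graph: nx.Graph) -> list[tuple]:
    """Orient every edge so each vertex's out-degree is at most deg/2 rounded
    up: pair odd-degree vertices with dummy edges, walk Eulerian circuits,
    keep the traversal direction of the real edges."""
    mg = nx.MultiGraph()
    mg.add_nodes_from(sorted(graph.nodes))
    for u, v in graph.edges():
        mg.add_edge(u, v, dummy=False)
    odd = sorted(v for v in mg if mg.degree(v) % 2 == 1)
    for a, b in zip(odd[::2], odd[1::2]):
        mg.add_edge(a, b, dummy=True)
    oriented: list[tuple] = []
    for comp in nx.connected_components(mg):
        sub = mg.subgraph(comp)
        if sub.number_of_edges() == 0:
            continue
        for u, v, key in nx.eulerian_circuit(sub, source=min(comp), keys=True):
            if not mg.edges[u, v, key]["dummy"]:
                oriented.append((u, v))
    return oriented


def make_water_sheet(rows: int, cols: int, oo_distance: float = 2.8) -> Snapshot:
    """Planar honeycomb of water molecules whose perceived H-bond network is
    hexagonal: every lattice edge carries exactly one donated hydrogen.

    Donor orientation rule: every honeycomb edge is donated by exactly one
    of its two endpoints, with no oxygen donating more than twice (an
    Eulerian orientation of the lattice, degree <= 3, gives out-degree <= 2
    everywhere). Oxygens left with spare hydrogens point them out of the
    plane, where they cannot reach an acceptor.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    lattice = nx.hexagonal_lattice_graph(rows, cols)
    pos = {v: np.array(p, dtype=float) for v, p in
           nx.get_node_attributes(lattice, "pos").items()}
    # scale so that every edge has length oo_distance
    u0, v0 = next(iter(lattice.edges()))
    scale = oo_distance / np.linalg.norm(pos[u0] - pos[v0])
    pos = {v: p * scale for v, p in pos.items()}

    donors: dict = {v: [] for v in lattice.nodes}
    for d, a in _eulerian_orientation(lattice):
        donors[d].append(a)

    b = _Builder()
    oxygen_ids = {}
    for v in sorted(lattice.nodes):
        oxygen_ids[v] = b.add("O", (pos[v][0], pos[v][1], 0.0))
    for v in sorted(lattice.nodes):
        o = oxygen_ids[v]
        n_h = 0
        for acc in sorted(donors[v]):
            direction = pos[acc] - pos[v]
            direction /= np.linalg.norm(direction)
            b.add("H", np.array([pos[v][0], pos[v][1], 0.0]) + _OH *
                  np.array([direction[0], direction[1], 0.0]), bond_to=o)
            n_h += 1
        for z in (1.0, -1.0)[: 2 - n_h]:  # spare H out of plane
            b.add("H", (pos[v][0], pos[v][1], z * _OH), bond_to=o)
    return b.snapshot()


def make_ring_chain_graph(ring: int = 6, chain: int = 6) -> MolGraph:
    """H-bonded ring with a pendant H-bonded chain (graph-level fixture).

    ``ring`` vertices form one cycle of arcs; ``chain`` further vertices
    hang off vertex 0 as a path, so exactly ring/(ring+chain) of the
    vertices sit on the single basis cycle.
    """
    n = ring + chain
    vertices = {i: "O" for i in range(n)}
    arcs = {(i, (i + 1) % ring) for i in range(ring)}
    prev = 0
    for i in range(ring, n):
        arcs.add((prev, i))
        prev = i
    return MolGraph(vertices=vertices, ec=frozenset(), ah=frozenset(arcs),
                    ei=frozenset(), eo=frozenset())


# ---------------------------------------------------------------------------
# Scripted trajectories

@dataclass
class TrajectoryScript:
    """A base molecule plus a per-frame toggle schedule.

    ``schedule`` maps each frame index to a tuple of active toggle names
    (empty tuple = base geometry). Toggles are named geometric perturbations
    of the base structure; the expected conformer-id sequence follows from
    the schedule alone.
    """

    base: str = "water_dimer"
    n_frames: int = 10
    schedule: dict[int, tuple[str, ...]] = field(default_factory=dict)
    jitter: float = 0.0  # optional uniform coordinate noise, Angstrom
    seed: int = 0

    def states(self) -> list[tuple[str, ...]]:
        return [tuple(self.schedule.get(f, ())) for f in range(self.n_frames)]


def _toggle_break_hbond(snapshot: Snapshot) -> Snapshot:
    """Rotate the water dimer's bridging H by 120 deg about z: arc vanishes."""
    atoms = list(snapshot.atoms)
    o1, h1 = atoms[0], atoms[1]
    ang = math.radians(120.0)
    rel = h1.position - o1.position
    rot = np.array([[math.cos(ang), -math.sin(ang), 0.0],
                    [math.sin(ang), math.cos(ang), 0.0],
                    [0.0, 0.0, 1.0]])
    atoms[1] = Atom(1, "H", o1.position + rot @ rel)
    return Snapshot(snapshot.frame_index, tuple(atoms))


def _toggle_separate(snapshot: Snapshot) -> Snapshot:
    """Translate the acceptor water 3 A further out: beyond every cutoff."""
    shift = np.array([3.0, 0.0, 0.0])
    atoms = [
        a if a.index < 3 else Atom(a.index, a.element, a.position + shift)
        for a in snapshot.atoms
    ]
    return Snapshot(snapshot.frame_index, tuple(atoms))


def _toggle_donate_back(snapshot: Snapshot) -> Snapshot:
    """Point one acceptor H back along the O-O axis: a second arc appears,
    making the dimer doubly H-bonded (distinct from the single-arc state)."""
    atoms = list(snapshot.atoms)
    o1, o2 = atoms[0], atoms[3]
    direction = o1.position - o2.position
    direction /= np.linalg.norm(direction)
    atoms[4] = Atom(4, "H", o2.position + _OH * direction)
    return Snapshot(snapshot.frame_index, tuple(atoms))


_TOGGLES = {
    "break_hbond": _toggle_break_hbond,
    "separate": _toggle_separate,
    "donate_back": _toggle_donate_back,
}


def make_scripted_trajectory(
    script: TrajectoryScript,
) -> tuple[Trajectory, list[int]]:
    """Build the trajectory and its ground-truth conformer-id sequence.

    Conformer ids are 1-based in first-appearance order of the distinct
    toggle states. Each distinct state is verified to produce a 2D-MolGraph
    different from every other state's under the default thresholds — a
    toggle that does not change the graph raises, loudly, at build time.
    """
    base, _ = make_molecule(script.base)
    params, thresholds = load_params()
    rng = np.random.default_rng(script.seed)

    state_snaps: dict[tuple[str, ...], Snapshot] = {}
    state_keys: dict[tuple[str, ...], str] = {}
    for state in script.states():
        if state in state_snaps:
            continue
        snap = base
        for name in state:
            try:
                snap = _TOGGLES[name](snap)
            except KeyError:
                raise ValueError(f"unknown toggle {name!r}") from None
        state_snaps[state] = snap
        state_keys[state] = canonical_key(
            build_molgraph(snap, params, thresholds))
    keys = list(state_keys.values())
    if len(set(keys)) != len(keys):
        raise ValueError(
            "script error: two distinct toggle states produce isomorphic "
            "2D-MolGraphs under the default thresholds")

    ids: dict[tuple[str, ...], int] = {}
    expected: list[int] = []
    snapshots: list[Snapshot] = []
    for frame, state in enumerate(script.states()):
        if state not in ids:
            ids[state] = len(ids) + 1
        expected.append(ids[state])
        snap = state_snaps[state]
        atoms = []
        for a in snap.atoms:
            xyz = a.position
            if script.jitter > 0:
                xyz = xyz + rng.uniform(-script.jitter, script.jitter, 3)
            atoms.append(Atom(a.index, a.element, xyz))
        snapshots.append(Snapshot(frame, tuple(atoms)))
    return Trajectory(tuple(snapshots)), expected
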