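"""Build the topological 2D molecular graph (2D-MolGraph) of a snapshot.

A molecular configuration is encoded as a colored mixed graph
``G = (V, EC, AH, EI, EO)``: vertices are the heavy (non-hydrogen) atoms,
colored by element; EC holds covalent bonds, AH holds hydrogen bonds as
directed arcs (donor-heavy -> acceptor-heavy), EI electrostatic and EO
organometallic contacts. Hydrogens enter the graph only through the arc
direction (and a side table mapping each arc to its mediating hydrogen), so
conformational change shows up purely as a change of graph topology.

Perception is geometric: covalent bonds from covalent-radii sums with a
tolerance and per-element valence caps (overflow resolved nearest-first),
H-bonds from a heavy-heavy distance cutoff plus a D-H...A angle criterion,
electrostatic/organometallic contacts from flat distance cutoffs around
flagged ions/metals. To avoid all-pairs scans on every frame, each atom
keeps an *orbit* — the set of atoms close enough to possibly interact —
recomputed only at reference snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .chemio import Atom, ElementParams, Snapshot, Thresholds

__all__ = [
    "MolGraph",
    "Orbits",
    "compute_orbits",
    "orbits_valid",
    "default_orbit_radius",
    "perceive_covalent",
    "perceive_hbonds",
    "perceive_special",
    "build_molgraph",
    "write_graphml",
    "pooled_undirected",
]

BOND_TYPES = ("covalent", "hbond", "electrostatic", "organometallic")


@dataclass(frozen=True)
class MolGraph:
    """Colored mixed graph of one molecular configuration.

    ``vertices`` maps heavy-atom id -> element color. ``ec``/``ei``/``eo``
    store unordered pairs with sorted endpoints; ``ah`` stores ordered
    (donor, acceptor) arcs. ``hbond_hydrogens`` maps each arc to the id of
    the hydrogen mediating it (not part of the isomorphism signature).
    """

    vertices: Mapping[int, str]
    ec: frozenset[tuple[int, int]]
    ah: frozenset[tuple[int, int]]
    ei: frozenset[tuple[int, int]]
    eo: frozenset[tuple[int, int]]
    hbond_hydrogens: Mapping[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "vertices", dict(self.vertices))
        for name in ("ec", "ei", "eo"):
            pairs = frozenset(tuple(sorted(p)) for p in getattr(self, name))
            object.__setattr__(self, name, pairs)
        object.__setattr__(self, "ah", frozenset(tuple(p) for p in self.ah))
        object.__setattr__(self, "hbond_hydrogens", dict(self.hbond_hydrogens))
        verts = set(self.vertices)
        for name in ("ec", "ah", "ei", "eo"):
            for a, b in getattr(self, name):
                if a not in verts or b not in verts:
                    raise ValueError(f"{name} edge ({a},{b}) has a non-vertex endpoint")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def typed_edges(self) -> frozenset[tuple[str, int, int]]:
        """All interactions as (type, a, b); arcs keep their order."""
        return frozenset(
            {("covalent", a, b) for a, b in self.ec}
            | {("hbond", a, b) for a, b in self.ah}
            | {("electrostatic", a, b) for a, b in self.ei}
            | {("organometallic", a, b) for a, b in self.eo}
        )

    def __eq__(self, other):  # identity on labeled content, not isomorphism
        if not isinstance(other, MolGraph):
            return NotImplemented
        return (dict(self.vertices) == dict(other.vertices)
                and self.ec == other.ec and self.ah == other.ah
                and self.ei == other.ei and self.eo == other.eo)

    def __hash__(self):
        return hash((frozenset(self.vertices.items()), self.ec, self.ah,
                     self.ei, self.eo))


@dataclass
class Orbits:
    """Per-atom candidate neighbor sets at the last reference snapshot."""

    candidates: dict[int, set[int]]
    reference_frame: int
    reference_positions: np.ndarray
    radius: float

    def __getitem__(self, atom_id: int) -> set[int]:
        return self.candidates[atom_id]


def default_orbit_radius(thresholds: Thresholds, margin: float = 2.0) -> float:
    """Orbit radius = largest perception cutoff + a displacement margin."""
    return thresholds.max_cutoff + margin


def compute_orbits(snapshot: Snapshot, orbit_radius: float) -> Orbits:
    """orbit(a) = all atoms within ``orbit_radius`` of a at this snapshot."""
    pos = snapshot.positions
    candidates: dict[int, set[int]] = {a.index: set() for a in snapshot.atoms}
    if len(snapshot.atoms) > 1:
        tree = cKDTree(pos)
        for i, j in tree.query_pairs(orbit_radius):
            candidates[i].add(j)
            candidates[j].add(i)
    return Orbits(candidates, snapshot.frame_index, pos.copy(), orbit_radius)


def orbits_valid(orbits: Orbits, snapshot: Snapshot, thresholds: Thresholds) -> bool:
    """Soundness test: no atom drifted more than (radius - max cutoff)/2.

    While this holds, perception restricted to the orbits equals an
    all-pairs perception, since two atoms must jointly close at most the
    slack distance before a new contact can form.
    """
    slack = (orbits.radius - thresholds.max_cutoff) / 2.0
    disp = np.linalg.norm(snapshot.positions - orbits.reference_positions, axis=1)
    return bool(np.all(disp <= slack))


def perceive_covalent(
    snapshot: Snapshot,
    params: Mapping[str, ElementParams],
    thresholds: Thresholds,
    orbits: Orbits | None = None,
) -> set[tuple[int, int]]:
    """Covalent pairs by radii-sum cutoff with nearest-first cap resolution.

    A pair qualifies when d(a,b) <= r_cov(a) + r_cov(b) + tolerance. When an
    atom has more qualifying partners than its valence cap, bonds are granted
    greedily in ascending (distance, partner-id) order, so the nearest
    partners win deterministically.
    """
    atoms = snapshot.atoms
    pos = snapshot.positions
    if orbits is None:
        orbits = compute_orbits(snapshot, default_orbit_radius(thresholds))
    candidates: list[tuple[float, int, int]] = []
    for a in atoms:
        pa = params[a.element]
        for j in orbits[a.index]:
            if j <= a.index:
                continue
            b = atoms[j]
            pb = params[b.element]
            cutoff = pa.covalent_radius + pb.covalent_radius + thresholds.covalent_tolerance
            d = float(np.linalg.norm(pos[a.index] - pos[j]))
            if d <= cutoff:
                candidates.append((d, a.index, j))
    candidates.sort()
    degree = {a.index: 0 for a in atoms}
    caps = {a.index: params[a.element].max_covalent_bonds for a in atoms}
    bonds: set[tuple[int, int]] = set()
    for d, i, j in candidates:
        if degree[i] < caps[i] and degree[j] < caps[j]:
            bonds.add((i, j))
            degree[i] += 1
            degree[j] += 1
    return bonds


def perceive_hbonds(
    snapshot: Snapshot,
    covalent_pairs: set[tuple[int, int]],
    thresholds: Thresholds,
) -> tuple[set[tuple[int, int]], dict[tuple[int, int], int]]:
    """Directed H-bond arcs (donor-heavy -> acceptor-heavy) + mediating H.

    An arc (D, A) exists when a hydrogen H is covalently bonded to heavy
    donor D, A is an acceptor element not covalently bonded to H, A != D,
    d(D, A) <= hbond_heavy_max and the D-H...A angle (at H) is at least
    hbond_angle_min degrees.
    """
    atoms = snapshot.atoms
    pos = snapshot.positions
    adj: dict[int, set[int]] = {a.index: set() for a in atoms}
    for i, j in covalent_pairs:
        adj[i].add(j)
        adj[j].add(i)
    arcs: set[tuple[int, int]] = set()
    hydrogens: dict[tuple[int, int], int] = {}
    for h in atoms:
        if h.element != "H":
            continue
        donors = [d for d in adj[h.index] if atoms[d].element != "H"]
        for d in donors:
            for a in atoms:
                ai = a.index
                if ai == d or ai == h.index or a.element not in thresholds.acceptor_elements:
                    continue
                if ai in adj[h.index]:
                    continue  # H is covalently bonded to it: not an H-bond
                if np.linalg.norm(pos[d] - pos[ai]) > thresholds.hbond_heavy_max:
                    continue
                v1 = pos[d] - pos[h.index]
                v2 = pos[ai] - pos[h.index]
                cosang = float(np.dot(v1, v2) /
                               (np.linalg.norm(v1) * np.linalg.norm(v2)))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle >= thresholds.hbond_angle_min:
                    arc = (d, ai)
                    if arc not in arcs:
                        arcs.add(arc)
                        hydrogens[arc] = h.index
    return arcs, hydrogens


def perceive_special(
    snapshot: Snapshot,
    kind: str,
    params: Mapping[str, ElementParams],
    thresholds: Thresholds,
    covalent_pairs: set[tuple[int, int]] | None = None,
) -> set[tuple[int, int]]:
    """Electrostatic (ion) or organometallic (metal) contact pairs.

    A pair is included when exactly one endpoint carries the kind's flag,
    the distance is within the kind's cutoff, neither atom is a hydrogen,
    and the pair is not already covalently bonded.
    """
    if kind not in ("electrostatic", "organometallic"):
        raise ValueError(f"unknown interaction kind: {kind!r}")
    flag = "is_ion_candidate" if kind == "electrostatic" else "is_metal"
    cutoff = (thresholds.electrostatic_max if kind == "electrostatic"
              else thresholds.organometallic_max)
    covalent_pairs = covalent_pairs or set()
    atoms = snapshot.atoms
    pos = snapshot.positions
    pairs: set[tuple[int, int]] = set()
    for a in atoms:
        if a.element == "H" or not getattr(params[a.element], flag):
            continue
        for b in atoms:
            if b.index == a.index or b.element == "H":
                continue
            if getattr(params[b.element], flag):
                continue  # exactly one flagged endpoint
            pair = tuple(sorted((a.index, b.index)))
            if pair in covalent_pairs:
                continue
            if np.linalg.norm(pos[a.index] - pos[b.index]) <= cutoff:
                pairs.add(pair)
    return pairs


def build_molgraph(
    snapshot: Snapshot,
    params: Mapping[str, ElementParams],
    thresholds: Thresholds,
    orbits: Orbits | None = None,
) -> MolGraph:
    """Perceive all interactions and assemble the heavy-atom mixed graph."""
    covalent = perceive_covalent(snapshot, params, thresholds, orbits)
    arcs, hydrogens = perceive_hbonds(snapshot, covalent, thresholds)
    ei = perceive_special(snapshot, "electrostatic", params, thresholds, covalent)
    eo = perceive_special(snapshot, "organometallic", params, thresholds, covalent)
    heavy = {a.index: a.element for a in snapshot.atoms if a.element != "H"}
    ec_heavy = {p for p in covalent if p[0] in heavy and p[1] in heavy}
    return MolGraph(
        vertices=heavy,
        ec=frozenset(ec_heavy),
        ah=frozenset(arcs),
        ei=frozenset(ei),
        eo=frozenset(eo),
        hbond_hydrogens=hydrogens,
    )


# ---------------------------------------------------------------------------
# Conversions / export

def to_networkx(g: MolGraph) -> nx.DiGraph:
    """Encode the mixed graph as a digraph with typed edge colors.

    Undirected edge types contribute both directions; H-bond arcs one.
    The per-direction set of types is stored as a sorted tuple under
    ``types`` — this encoding is what isomorphism and canonical labeling
    operate on.
    """
    dg = nx.DiGraph()
    for v, el in g.vertices.items():
        dg.add_node(v, element=el)
    type_map: dict[tuple[int, int], set[str]] = {}
    for name, attr in (("ec", "covalent"), ("ei", "electrostatic"),
                       ("eo", "organometallic")):
        for a, b in getattr(g, name):
            type_map.setdefault((a, b), set()).add(attr)
            type_map.setdefault((b, a), set()).add(attr)
    for a, b in g.ah:
        type_map.setdefault((a, b), set()).add("hbond")
    for (a, b), types in type_map.items():
        dg.add_edge(a, b, types=tuple(sorted(types)))
    return dg


def pooled_undirected(g: MolGraph) -> nx.Graph:
    """All edge types pooled as a simple undirected graph (for cycles etc.)."""
    ug = nx.Graph()
    for v, el in g.vertices.items():
        ug.add_node(v, element=el)
    for name in ("ec", "ei", "eo"):
        for a, b in getattr(g, name):
            ug.add_edge(a, b)
    for a, b in g.ah:
        ug.add_edge(a, b)
    return ug


def write_graphml(g: MolGraph, path) -> None:
    """GraphML export: vertex 'element', edge 'bond_type' (+H-bond extras)."""
    dg = nx.DiGraph()
    for v, el in g.vertices.items():
        dg.add_node(v, element=el)
    for a, b in sorted(g.ec):
        dg.add_edge(a, b, bond_type="covalent", directed="false")
    for a, b in sorted(g.ei):
        dg.add_edge(a, b, bond_type="electrostatic", directed="false")
    for a, b in sorted(g.eo):
        dg.add_edge(a, b, bond_type="organometallic", directed="false")
    for a, b in sorted(g.ah):
        dg.add_edge(a, b, bond_type="hbond", directed="true",
                    hydrogen_id=int(g.hbond_hydrogens.get((a, b), -1)))
    nx.write_graphml(dg, path)
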