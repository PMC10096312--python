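"""Cycle and connectivity analytics on 2D-MolGraphs.

The central primitive is a minimum cycle basis (unit edge weights) computed
with Horton's construction: candidate cycles ``C(v, e) = SP(v,x) + (x,y) +
SP(y,v)`` for every vertex v and edge e=(x,y), filtered to simple cycles,
then greedily accepted in ascending (length, lexicographic) order subject to
independence over GF(2) edge space. Shortest paths are made unique by a
lexicographic parent rule, and ties among equal-length candidates are broken
on the canonical vertex sequence, so the basis is deterministic (minimum
cycle bases are generally not unique).

On top of the basis: H-bonded ring-size distributions, the percentage of
vertices participating in polygons, connected-component size histograms, and
the per-conformer coarse-grained graph of cycles (vertices = H-bonded basis
cycles, edges = cycles sharing a vertex or an edge). All edge types are
pooled and treated as undirected for these analytics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .chemio import Snapshot
from .molgraph import MolGraph, pooled_undirected

__all__ = [
    "CycleBasis",
    "CycleGraph",
    "minimum_cycle_basis",
    "connected_component_sizes",
    "ring_size_histogram",
    "polygon_membership_fraction",
    "cycle_interaction_graph",
    "select_z_slab",
]


@dataclass(frozen=True)
class CycleBasis:
    """Minimum cycle basis: each cycle a vertex sequence (no repeats)."""

    cycles: tuple[tuple[int, ...], ...]
    graph: MolGraph

    def __len__(self) -> int:
        return len(self.cycles)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.cycles]


@dataclass(frozen=True)
class CycleGraph:
    """Coarse-grained graph of H-bonded cycles of one conformer."""

    cycles: tuple[tuple[int, ...], ...]  # vertex sequences of H-bonded cycles
    edges: frozenset[tuple[int, int]]  # pairs of cycle indices that interact


def _canonical_cycle(seq: Sequence[int]) -> tuple[int, ...]:
    """Rotate/reflect a cycle's vertex sequence to a canonical form."""
    n = len(seq)
    i = min(range(n), key=lambda k: seq[k])
    fwd = tuple(seq[(i + k) % n] for k in range(n))
    rev = tuple(seq[(i - k) % n] for k in range(n))
    return min(fwd, rev)


def _cycle_edges(seq: Sequence[int]) -> frozenset[tuple[int, int]]:
    n = len(seq)
    return frozenset(tuple(sorted((seq[k], seq[(k + 1) % n]))) for k in range(n))


def _lex_bfs_paths(ug: nx.Graph, source: int) -> dict[int, list[int]]:
    """Unique shortest paths via BFS with smallest-id parent selection."""
    depth = {source: 0}
    parent: dict[int, int] = {}
    frontier = [source]
    while frontier:
        nxt = []
        for u in sorted(frontier):
            for w in sorted(ug.neighbors(u)):
                if w not in depth:
                    depth[w] = depth[u] + 1
                    parent[w] = u
                    nxt.append(w)
                elif depth[w] == depth[u] + 1 and parent[w] > u:
                    parent[w] = u  # lexicographic tie-break
        frontier = nxt
    paths = {source: [source]}

    def path(v: int) -> list[int]:
        if v not in paths:
            paths[v] = path(parent[v]) + [v]
        return paths[v]

    for v in depth:
        path(v)
    return paths


def _horton_candidates(ug: nx.Graph) -> list[tuple[int, ...]]:
    seen: set[frozenset] = set()
    out: list[tuple[int, ...]] = []
    edges = [tuple(sorted(e)) for e in ug.edges()]
    for v in sorted(ug.nodes):
        paths = _lex_bfs_paths(ug, v)
        for x, y in edges:
            if x not in paths or y not in paths:
                continue
            px, py = paths[x], paths[y]
            # vertex-disjoint except at v -> simple cycle
            if set(px) & set(py) != {v}:
                continue
            seq = px + py[::-1][:-1]
            if len(seq) < 3:
                continue
            canon = _canonical_cycle(seq)
            eset = _cycle_edges(canon)
            if len(eset) != len(canon):
                continue
            if eset not in seen:
                seen.add(eset)
                out.append(canon)
    return out


def minimum_cycle_basis(g: MolGraph | nx.Graph) -> CycleBasis:
    """Deterministic minimum cycle basis of the pooled undirected graph."""
    if isinstance(g, MolGraph):
        ug = pooled_undirected(g)
        ref = g
    else:
        ug = g
        ref = MolGraph(vertices={v: "X" for v in g.nodes},
                       ec=frozenset(tuple(sorted(e)) for e in g.edges()),
                       ah=frozenset(), ei=frozenset(), eo=frozenset())
    n_comp = nx.number_connected_components(ug) if len(ug) else 0
    dim = ug.number_of_edges() - len(ug) + n_comp
    if dim == 0:
        return CycleBasis((), ref)

    candidates = _horton_candidates(ug)
    # fundamental cycles guarantee the candidate pool spans the cycle space
    for fc in nx.cycle_basis(ug):
        canon = _canonical_cycle(fc)
        if canon not in set(candidates):
            candidates.append(canon)
    candidates.sort(key=lambda c: (len(c), c))

    edge_index = {tuple(sorted(e)): i for i, e in enumerate(ug.edges())}
    basis: list[tuple[int, ...]] = []
    pivots: dict[int, int] = {}  # lowest set bit -> reduced GF(2) mask
    for cyc in candidates:
        vec = 0
        for e in _cycle_edges(cyc):
            vec |= 1 << edge_index[e]
        while vec:
            low = vec & -vec
            if low in pivots:
                vec ^= pivots[low]
            else:
                pivots[low] = vec
                basis.append(cyc)
                break
        if len(basis) == dim:
            break
    if len(basis) != dim:  # pragma: no cover - candidate pool always spans
        raise RuntimeError("cycle candidate pool did not span the cycle space")
    return CycleBasis(tuple(basis), ref)


def connected_component_sizes(g: MolGraph) -> dict[int, int]:
    """Histogram {component size (vertices): number of components}."""
    ug = pooled_undirected(g)
    hist: dict[int, int] = {}
    for comp in nx.connected_components(ug):
        hist[len(comp)] = hist.get(len(comp), 0) + 1
    return hist


def ring_size_histogram(
    graphs: Iterable[MolGraph],
    bases: Iterable[CycleBasis] | None = None,
    hbonded_only: bool = False,
) -> dict[int, float]:
    """Relative frequency of basis-cycle sizes pooled across graphs."""
    graphs = list(graphs)
    if bases is None:
        bases = [minimum_cycle_basis(g) for g in graphs]
    counts: dict[int, int] = {}
    total = 0
    for g, basis in zip(graphs, bases):
        cycles = basis.cycles
        if hbonded_only:
            cycles = tuple(c for c in cycles if _is_hbonded(c, g))
        for c in cycles:
            counts[len(c)] = counts.get(len(c), 0) + 1
            total += 1
    if total == 0:
        return {}
    return {size: n / total for size, n in sorted(counts.items())}


def polygon_membership_fraction(graphs: Iterable[MolGraph]) -> float:
    """Average percentage of vertices belonging to at least one basis cycle."""
    graphs = list(graphs)
    if not graphs:
        raise ValueError("no graphs given")
    fractions = []
    for g in graphs:
        if not g.vertices:
            raise ValueError("polygon membership undefined for an empty graph")
        basis = minimum_cycle_basis(g)
        on_cycles: set[int] = set()
        for c in basis.cycles:
            on_cycles.update(c)
        fractions.append(100.0 * len(on_cycles) / len(g.vertices))
    return sum(fractions) / len(fractions)


def _is_hbonded(cycle: Sequence[int], g: MolGraph) -> bool:
    for e in _cycle_edges(cycle):
        a, b = e
        if (a, b) in g.ah or (b, a) in g.ah:
            return True
    return False


def cycle_interaction_graph(g: MolGraph, basis: CycleBasis | None = None) -> CycleGraph:
    """Graph of H-bonded cycles; edge = sharing >=1 vertex or edge."""
    if basis is None:
        basis = minimum_cycle_basis(g)
    hcycles = [c for c in basis.cycles if _is_hbonded(c, g)]
    edges: set[tuple[int, int]] = set()
    for i in range(len(hcycles)):
        vi = set(hcycles[i])
        for j in range(i + 1, len(hcycles)):
            if vi & set(hcycles[j]):
                edges.add((i, j))
    return CycleGraph(tuple(hcycles), frozenset(edges))


def select_z_slab(snapshot: Snapshot, z_min: float, z_max: float) -> Snapshot:
    """Convenience slab filter: keep atoms with z in [z_min, z_max], reindexed.

    Intended for picking an interfacial water layer by height; selection of
    a genuine binding interfacial layer is up to the caller.
    """
    from .chemio import Atom

    kept = [a for a in snapshot.atoms if z_min <= a.position[2] <= z_max]
    atoms = tuple(Atom(i, a.element, a.position) for i, a in enumerate(kept))
    return Snapshot(snapshot.frame_index, atoms)
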