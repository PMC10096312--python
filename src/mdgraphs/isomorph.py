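"""Colored mixed-graph isomorphism and the conformer registry.

Two configurations are the *same conformer* exactly when their 2D-MolGraphs
are isomorphic: a vertex bijection preserving element colors and mapping
each typed edge set onto its counterpart, with H-bond arc direction
preserved. The mediating hydrogen's identity is not part of the test — a
hydrogen bond is represented only by its directed donor->acceptor arc.

Two engines are provided. ``are_isomorphic`` runs VF2 on a typed-digraph
encoding of the mixed graph. ``canonical_key`` computes a canonical form by
color refinement plus individualization backtracking; keys are equal *iff*
the graphs are isomorphic, which makes registry lookup a dictionary access.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import pandas as pd

from .molgraph import MolGraph, to_networkx, write_graphml

__all__ = [
    "are_isomorphic",
    "canonical_key",
    "ConformerRegistry",
    "assign_conformer",
]


def are_isomorphic(g1: MolGraph, g2: MolGraph) -> bool:
    """Exact colored mixed-graph isomorphism (VF2 on the typed encoding)."""
    d1, d2 = to_networkx(g1), to_networkx(g2)
    if len(d1) != len(d2) or d1.number_of_edges() != d2.number_of_edges():
        return False
    matcher = nx.algorithms.isomorphism.DiGraphMatcher(
        d1, d2,
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["types"] == b["types"],
    )
    return matcher.is_isomorphic()


# ---------------------------------------------------------------------------
# Canonical labeling: color refinement + individualization backtracking

def _refine(n, adj_out, adj_in, colors):
    """Iterate color refinement to a stable partition; colors are int ranks."""
    while True:
        sigs = []
        for v in range(n):
            out_sig = tuple(sorted((types, colors[u]) for u, types in adj_out[v]))
            in_sig = tuple(sorted((types, colors[u]) for u, types in adj_in[v]))
            sigs.append((colors[v], out_sig, in_sig))
        order = sorted(set(sigs))
        rank = {s: i for i, s in enumerate(order)}
        new_colors = [rank[s] for s in sigs]
        if new_colors == colors:
            return colors
        colors = new_colors


def _certificate(n, elements, adj_out, colors):
    """Certificate of a discretely-colored graph (colors form a permutation)."""
    pos = [0] * n
    for v in range(n):
        pos[colors[v]] = v
    relabel = {v: colors[v] for v in range(n)}
    edges = sorted(
        (relabel[v], relabel[u], types) for v in range(n) for u, types in adj_out[v]
    )
    verts = tuple(elements[pos[i]] for i in range(n))
    return (verts, tuple(edges))


def _canonical_search(n, elements, adj_out, adj_in, colors):
    colors = _refine(n, adj_out, adj_in, colors)
    # find the first non-singleton color class (by color value)
    by_color: dict[int, list[int]] = {}
    for v, c in enumerate(colors):
        by_color.setdefault(c, []).append(v)
    target = None
    for c in sorted(by_color):
        if len(by_color[c]) > 1:
            target = by_color[c]
            break
    if target is None:
        return _certificate(n, elements, adj_out, colors)
    best = None
    for v in target:
        branched = [2 * c + 1 for c in colors]
        branched[v] = 2 * colors[v]  # individualize v below its old class
        cert = _canonical_search(n, elements, adj_out, adj_in, branched)
        if best is None or cert < best:
            best = cert
    return best


def canonical_key(g: MolGraph) -> str:
    """Canonical string key: equal for two graphs iff they are isomorphic."""
    if not g.vertices:
        return "empty"
    ids = sorted(g.vertices)
    idx = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    elements = [g.vertices[a] for a in ids]
    dg = to_networkx(g)
    adj_out = [[] for _ in range(n)]
    adj_in = [[] for _ in range(n)]
    for a, b, data in dg.edges(data=True):
        adj_out[idx[a]].append((idx[b], data["types"]))
        adj_in[idx[b]].append((idx[a], data["types"]))
    order = sorted(set(elements))
    rank = {e: i for i, e in enumerate(order)}
    colors = [rank[e] for e in elements]
    cert = _canonical_search(n, elements, adj_out, adj_in, colors)
    return repr(cert)


# ---------------------------------------------------------------------------
# Conformer registry

@dataclass
class Conformer:
    id: int
    representative: MolGraph
    key: str
    appearance: list[int] = field(default_factory=list)


@dataclass
class ConformerRegistry:
    """Distinct (pairwise non-isomorphic) 2D-MolGraphs seen so far.

    ``registry_lookups_avoided`` counts frames resolved by the previous-frame
    shortcut, i.e. without touching the canonical-key index.
    """

    conformers: list[Conformer] = field(default_factory=list)
    _by_key: dict[str, int] = field(default_factory=dict)
    registry_lookups_avoided: int = 0

    def __len__(self) -> int:
        return len(self.conformers)

    def by_id(self, cid: int) -> Conformer:
        return self.conformers[cid - 1]

    @property
    def assigned_frames(self) -> list[int]:
        out: list[int] = []
        for c in self.conformers:
            out.extend(c.appearance)
        return sorted(out)

    def to_frame(self, total_frames: int) -> pd.DataFrame:
        """Registry summary: id, count, percentage, first frame, bonds."""
        rows = []
        for c in self.conformers:
            g = c.representative
            rows.append({
                "conformer_id": c.id,
                "count": len(c.appearance),
                "percentage": 100.0 * len(c.appearance) / total_frames,
                "first_frame": min(c.appearance) if c.appearance else -1,
                "n_covalent": len(g.ec),
                "n_hbond": len(g.ah),
                "n_electrostatic": len(g.ei),
                "n_organometallic": len(g.eo),
            })
        return pd.DataFrame(rows)

    def export(self, out_dir, total_frames: int) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame(total_frames).to_csv(out / "conformers.csv", index=False)
        for c in self.conformers:
            write_graphml(c.representative, out / f"conformer_{c.id}.graphml")


def assign_conformer(
    registry: ConformerRegistry,
    g: MolGraph,
    frame: int,
    previous_id: Optional[int] = None,
) -> int:
    """Assign a frame's graph to a conformer, registering a new one if needed.

    The previous frame's conformer is tried first (cheap isomorphism test);
    only on a miss is the canonical key computed and looked up in the
    registry index.
    """
    for c in registry.conformers:
        if frame in c.appearance:
            raise ValueError(f"frame {frame} already assigned to conformer {c.id}")
    if previous_id is not None:
        prev = registry.by_id(previous_id)
        if are_isomorphic(g, prev.representative):
            prev.appearance.append(frame)
            registry.registry_lookups_avoided += 1
            return prev.id
    key = canonical_key(g)
    cid = registry._by_key.get(key)
    if cid is not None:
        registry.by_id(cid).appearance.append(frame)
        return cid
    cid = len(registry.conformers) + 1
    registry.conformers.append(Conformer(cid, g, key, [frame]))
    registry._by_key[key] = cid
    return cid
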