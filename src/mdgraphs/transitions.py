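"""Trajectory analysis loop and the directed graph of transitions.

The analysis walks a trajectory frame by frame, builds each frame's
2D-MolGraph (refreshing atom orbits only when the soundness margin is
exhausted or every ``orbit_refresh_every`` frames), assigns each frame to a
conformer, and summarizes the dynamics as a *graph of transitions*: one
vertex per conformer carrying its percentage of appearance, one directed
edge per observed interconversion carrying the transition count and the
interactions formed/broken between the two conformations. Consecutive
identical conformers are residence, not transitions, so there are no
self-loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx

from .chemio import ElementParams, Thresholds, Trajectory
from .isomorph import ConformerRegistry, assign_conformer
from .molgraph import (MolGraph, build_molgraph, compute_orbits,
                       default_orbit_radius, orbits_valid)

__all__ = [
    "BondDiff",
    "TransitionGraph",
    "analyze_trajectory",
    "diff_bonds",
    "build_transition_graph",
    "export_transition_graph",
    "atom_labels",
]

DEFAULT_P_MIN = 4.0  # percent: vertices at or above are highlighted


@dataclass(frozen=True)
class BondDiff:
    """Typed interactions formed/broken between two configurations."""

    formed: frozenset[tuple[str, int, int]]
    broken: frozenset[tuple[str, int, int]]

    def __post_init__(self):
        if self.formed & self.broken:
            raise ValueError("an interaction cannot be both formed and broken")

    @property
    def empty(self) -> bool:
        return not self.formed and not self.broken


@dataclass
class TransitionGraph:
    """Directed conformer graph with percentages and changed-bond labels."""

    vertices: dict[int, dict]  # id -> {"percentage", "count", "bonds"}
    edges: dict[tuple[int, int], dict]  # (i, j) -> {"count", "diff": BondDiff}
    total_frames: int


def diff_bonds(gi: MolGraph, gj: MolGraph) -> BondDiff:
    """Interactions of ``gj`` absent from ``gi`` (formed) and vice versa.

    Both graphs must live on the same atom-id universe (same trajectory);
    edges are compared by atom ids and type, arcs by their ordered pair.
    """
    if dict(gi.vertices) != dict(gj.vertices):
        raise ValueError("graphs are over different atom universes")
    ei, ej = gi.typed_edges(), gj.typed_edges()
    return BondDiff(formed=frozenset(ej - ei), broken=frozenset(ei - ej))


def analyze_trajectory(
    trajectory: Trajectory,
    params: Mapping[str, ElementParams],
    thresholds: Thresholds,
    orbit_margin: float = 2.0,
    orbit_refresh_every: int = 100,
) -> tuple[ConformerRegistry, TransitionGraph, list[int]]:
    """Full conformer-tracking loop over a trajectory.

    Returns the conformer registry, the graph of transitions and the
    per-frame conformer-id assignment (ids are 1-based in first-appearance
    order).
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    radius = default_orbit_radius(thresholds, orbit_margin)
    registry = ConformerRegistry()
    ids: list[int] = []
    orbits = None
    frames_since_refresh = 0
    prev_id = None
    for snap in trajectory:
        if (orbits is None or frames_since_refresh >= orbit_refresh_every
                or not orbits_valid(orbits, snap, thresholds)):
            orbits = compute_orbits(snap, radius)
            frames_since_refresh = 0
        g = build_molgraph(snap, params, thresholds, orbits)
        prev_id = assign_conformer(registry, g, snap.frame_index, prev_id)
        ids.append(prev_id)
        frames_since_refresh += 1
    tg = build_transition_graph(ids, registry)
    return registry, tg, ids


def build_transition_graph(
    frame_ids: list[int], registry: ConformerRegistry
) -> TransitionGraph:
    """Count adjacent-frame interconversions and label them with bond diffs."""
    total = len(frame_ids)
    counts: dict[int, int] = {}
    for cid in frame_ids:
        counts[cid] = counts.get(cid, 0) + 1
    vertices = {
        cid: {
            "percentage": 100.0 * n / total,
            "count": n,
            "bonds": sorted(registry.by_id(cid).representative.typed_edges()),
        }
        for cid, n in counts.items()
    }
    edges: dict[tuple[int, int], dict] = {}
    for a, b in zip(frame_ids, frame_ids[1:]):
        if a == b:
            continue
        entry = edges.setdefault((a, b), {"count": 0, "diff": None})
        entry["count"] += 1
    for (a, b), entry in edges.items():
        entry["diff"] = diff_bonds(
            registry.by_id(a).representative, registry.by_id(b).representative
        )
    return TransitionGraph(vertices=vertices, edges=edges, total_frames=total)


def atom_labels(g: MolGraph) -> dict[int, str]:
    """Element+ordinal vertex names (N1, O8, ...) by first-appearance order."""
    counters: dict[str, int] = {}
    labels: dict[int, str] = {}
    for v in sorted(g.vertices):
        el = g.vertices[v]
        counters[el] = counters.get(el, 0) + 1
        labels[v] = f"{el}{counters[el]}"
    return labels


def _diff_label(diff: BondDiff, labels: Mapping[int, str]) -> str:
    def fmt(edges):
        parts = []
        for typ, a, b in sorted(edges):
            sep = "->" if typ == "hbond" else "-"
            parts.append(f"{typ[:2]}:{labels[a]}{sep}{labels[b]}")
        return ",".join(parts)

    parts = []
    if diff.formed:
        parts.append("+" + fmt(diff.formed))
    if diff.broken:
        parts.append("-" + fmt(diff.broken))
    return " ".join(parts)


def export_transition_graph(
    tg: TransitionGraph,
    registry: ConformerRegistry,
    out_prefix: str | Path,
    p_min: float = DEFAULT_P_MIN,
) -> None:
    """Emit ``<prefix>.dot`` and ``<prefix>.graphml``.

    Vertices with appearance percentage >= ``p_min`` are colored red, the
    rest green; edge labels carry the transition count and the formed/broken
    interaction list (element+ordinal atom names).
    """
    if not (0.0 <= p_min <= 100.0):
        raise ValueError("p_min must be a percentage in [0, 100]")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    any_rep = registry.conformers[0].representative
    labels = atom_labels(any_rep)

    dot_lines = ["digraph transitions {"]
    for cid in sorted(tg.vertices):
        info = tg.vertices[cid]
        color = "red" if info["percentage"] >= p_min else "green"
        dot_lines.append(
            f'  c{cid} [label="{cid}\\n{info["percentage"]:.2f}%", '
            f'color={color}, style=filled, fillcolor={color}];'
        )
    for (a, b) in sorted(tg.edges):
        entry = tg.edges[(a, b)]
        lbl = f'{entry["count"]}; {_diff_label(entry["diff"], labels)}'
        dot_lines.append(f'  c{a} -> c{b} [label="{lbl}"];')
    dot_lines.append("}")
    Path(str(out_prefix) + ".dot").write_text("\n".join(dot_lines) + "\n")

    dg = nx.DiGraph()
    for cid, info in tg.vertices.items():
        dg.add_node(cid, percentage=info["percentage"], count=info["count"],
                    highlighted=bool(info["percentage"] >= p_min))
    for (a, b), entry in tg.edges.items():
        dg.add_edge(a, b, count=entry["count"],
                    label=_diff_label(entry["diff"], labels))
    nx.write_graphml(dg, str(out_prefix) + ".graphml")
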