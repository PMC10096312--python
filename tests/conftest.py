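"""Shared fixtures and the brute-force isomorphism oracle."""

from __future__ import annotations

import itertools
import random

import numpy as np
import pytest

from mdgraphs.chemio import load_params
from mdgraphs.molgraph import MolGraph


@pytest.fixture(scope="session")
def params_thresholds():
    return load_params()


@pytest.fixture(scope="session")
def params(params_thresholds):
    return params_thresholds[0]


@pytest.fixture(scope="session")
def thresholds(params_thresholds):
    return params_thresholds[1]


# ---------------------------------------------------------------------------
# Random colored mixed graphs + an exhaustive isomorphism oracle

def random_molgraph(rng: random.Random, n: int, colors: str = "CNO") -> MolGraph:
    """Random colored mixed graph with all four edge types."""
    vertex_colors = [rng.choice(colors) for _ in range(n)]
    ec, ah, ei, eo = set(), set(), set(), set()
    for i in range(n):
        for j in range(i + 1, n):
            r = rng.random()
            if r < 0.25:
                ec.add((i, j))
            elif r < 0.35:
                ah.add((i, j) if rng.random() < 0.5 else (j, i))
            elif r < 0.40:
                ei.add((i, j))
            elif r < 0.45:
                eo.add((i, j))
    return MolGraph(dict(enumerate(vertex_colors)), frozenset(ec),
                    frozenset(ah), frozenset(ei), frozenset(eo))


def permute_molgraph(g: MolGraph, perm: list[int]) -> MolGraph:
    """Relabel vertices of g by an arbitrary permutation."""
    m = dict(zip(sorted(g.vertices), perm))
    return MolGraph({m[v]: c for v, c in g.vertices.items()},
                    frozenset((m[a], m[b]) for a, b in g.ec),
                    frozenset((m[a], m[b]) for a, b in g.ah),
                    frozenset((m[a], m[b]) for a, b in g.ei),
                    frozenset((m[a], m[b]) for a, b in g.eo))


def brute_force_isomorphic(g1: MolGraph, g2: MolGraph) -> bool:
    """Exhaustive search over all color-respecting vertex bijections."""
    v1, v2 = sorted(g1.vertices), sorted(g2.vertices)
    if len(v1) != len(v2):
        return False
    for perm in itertools.permutations(v2):
        m = dict(zip(v1, perm))
        if any(g1.vertices[a] != g2.vertices[m[a]] for a in v1):
            continue
        if ({tuple(sorted((m[a], m[b]))) for a, b in g1.ec} == g2.ec
                and {tuple(sorted((m[a], m[b]))) for a, b in g1.ei} == g2.ei
                and {tuple(sorted((m[a], m[b]))) for a, b in g1.eo} == g2.eo
                and {(m[a], m[b]) for a, b in g1.ah} == g2.ah):
            return True
    return False


@pytest.fixture
def rng():
    return random.Random(20240901)


@pytest.fixture
def nprng():
    return np.random.default_rng(20240901)
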