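"""Trajectory I/O and the element/threshold parameter database.

Coordinates are Cartesian, in Angstrom, throughout the package. A trajectory
is an ordered list of snapshots with a fixed atom ordering; interaction
perception (see :mod:`mdgraphs.molgraph`) is driven by per-element covalent
radii and valence caps plus a small set of distance/angle thresholds, all of
which can be overridden from a YAML configuration file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Atom",
    "Snapshot",
    "Trajectory",
    "ElementParams",
    "Thresholds",
    "TrajectoryError",
    "ParamError",
    "read_trajectory",
    "write_xyz",
    "load_params",
    "dump_params",
]


class TrajectoryError(ValueError):
    """Malformed or structurally inconsistent trajectory input."""


class ParamError(ValueError):
    """Invalid parameter database or threshold configuration."""


@dataclass(frozen=True)
class Atom:
    """One atom: 0-based index, element symbol, position (Angstrom)."""

    index: int
    element: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.index} ({self.element}): non-finite position")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class Snapshot:
    """One frame of a trajectory."""

    frame_index: int
    atoms: tuple[Atom, ...]

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.atoms)

    @property
    def positions(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.position for a in self.atoms])


@dataclass(frozen=True)
class Trajectory:
    """Ordered snapshots with identical atom count/element sequence."""

    snapshots: tuple[Snapshot, ...]
    timestep_fs: float | None = None

    def __post_init__(self):
        snaps = tuple(self.snapshots)
        object.__setattr__(self, "snapshots", snaps)
        if snaps:
            ref = snaps[0].elements
            for s in snaps:
                if s.elements != ref:
                    raise TrajectoryError(
                        f"frame {s.frame_index}: atom count/element sequence differs "
                        f"from frame {snaps[0].frame_index}"
                    )

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)


@dataclass(frozen=True)
class ElementParams:
    """Per-element perception parameters."""

    symbol: str
    covalent_radius: float  # Angstrom
    max_covalent_bonds: int
    is_metal: bool = False
    is_ion_candidate: bool = False

    def __post_init__(self):
        if self.covalent_radius <= 0:
            raise ParamError(f"{self.symbol}: covalent_radius must be > 0")
        if not (0 <= self.max_covalent_bonds <= 8):
            raise ParamError(f"{self.symbol}: max_covalent_bonds must be in 0..8")


@dataclass(frozen=True)
class Thresholds:
    """Distance/angle cutoffs for interaction perception."""

    covalent_tolerance: float = 0.40  # Angstrom, added to the radii sum
    hbond_heavy_max: float = 3.5  # Angstrom, donor-heavy to acceptor-heavy
    hbond_angle_min: float = 140.0  # degrees, D-H...A
    electrostatic_max: float = 3.0  # Angstrom
    organometallic_max: float = 2.8  # Angstrom
    acceptor_elements: frozenset[str] = frozenset({"N", "O", "F", "S", "Cl"})
    metal_elements: frozenset[str] = frozenset({"Mn", "Fe", "Cu", "Zn", "Ru", "Au"})

    def __post_init__(self):
        for name in ("covalent_tolerance", "hbond_heavy_max", "electrostatic_max",
                     "organometallic_max"):
            if getattr(self, name) <= 0:
                raise ParamError(f"threshold {name} must be > 0")
        if not (0.0 <= self.hbond_angle_min <= 180.0):
            raise ParamError("hbond_angle_min must be in [0, 180] degrees")
        object.__setattr__(self, "acceptor_elements", frozenset(self.acceptor_elements))
        object.__setattr__(self, "metal_elements", frozenset(self.metal_elements))

    @property
    def max_cutoff(self) -> float:
        """Largest perception cutoff (lower bound for the orbit radius)."""
        return max(self.hbond_heavy_max, self.electrostatic_max,
                   self.organometallic_max)


# Covalent radii (Angstrom) from the Cordero et al. consensus table; valence
# caps are chemical maxima used only to resolve bond overflow (N allows 4 to
# accommodate protonated amine termini).
_DEFAULT_ELEMENTS: dict[str, tuple[float, int, bool, bool]] = {
    # symbol: (radius, cap, is_metal, is_ion_candidate)
    "H": (0.31, 1, False, False),
    "He": (0.28, 0, False, False),
    "Li": (1.28, 1, False, True),
    "B": (0.84, 3, False, False),
    "C": (0.76, 4, False, False),
    "N": (0.71, 4, False, False),
    "O": (0.66, 2, False, False),
    "F": (0.57, 1, False, False),
    "Na": (1.66, 1, False, True),
    "Mg": (1.41, 2, False, True),
    "P": (1.07, 5, False, False),
    "S": (1.05, 4, False, False),
    "Cl": (1.02, 1, False, False),
    "K": (2.03, 1, False, True),
    "Ca": (1.76, 2, False, True),
    "Mn": (1.39, 8, True, False),
    "Fe": (1.32, 8, True, False),
    "Cu": (1.32, 8, True, False),
    "Zn": (1.22, 8, True, False),
    "Br": (1.20, 1, False, False),
    "Ru": (1.46, 8, True, False),
    "I": (1.39, 1, False, False),
    "Au": (1.36, 8, True, False),
}


def default_element_params() -> dict[str, ElementParams]:
    return {
        sym: ElementParams(sym, r, cap, metal, ion)
        for sym, (r, cap, metal, ion) in _DEFAULT_ELEMENTS.items()
    }


def normalize_symbol(raw: str) -> str:
    """Title-case an element symbol ('CL' -> 'Cl')."""
    return raw.strip().capitalize()


# ---------------------------------------------------------------------------
# XYZ

def _parse_xyz(path: Path) -> list[Snapshot]:
    lines = path.read_text().splitlines()
    snapshots: list[Snapshot] = []
    i = 0
    frame = 0
    while i < len(lines):
        if lines[i].strip() == "" and all(l.strip() == "" for l in lines[i:]):
            break  # trailing blank lines
        try:
            n = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise TrajectoryError(
                f"frame {frame}, line {i + 1}: expected atom count, got {lines[i]!r}"
            )
        if n < 0:
            raise TrajectoryError(f"frame {frame}, line {i + 1}: negative atom count")
        if i + 2 + n > len(lines):
            raise TrajectoryError(
                f"frame {frame}, line {i + 1}: truncated frame "
                f"(declared {n} atoms, file ends early)"
            )
        atoms: list[Atom] = []
        for j in range(n):
            ln = i + 2 + j
            parts = lines[ln].split()
            if len(parts) < 4:
                raise TrajectoryError(
                    f"frame {frame}, line {ln + 1}: expected 'symbol x y z', "
                    f"got {lines[ln]!r}"
                )
            sym = normalize_symbol(parts[0])
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError:
                raise TrajectoryError(
                    f"frame {frame}, line {ln + 1}: non-numeric coordinate in "
                    f"{lines[ln]!r}"
                )
            atoms.append(Atom(j, sym, np.array(xyz)))
        snapshots.append(Snapshot(frame, tuple(atoms)))
        i += 2 + n
        frame += 1
    if not snapshots:
        raise TrajectoryError("empty XYZ file: no frames found")
    return snapshots


def _parse_pdb(path: Path) -> list[Snapshot]:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None, altloc="first")
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    snapshots = []
    elements = [normalize_symbol(e) for e in stack.element]
    for f in range(stack.stack_depth()):
        coords = stack.coord[f]
        atoms = tuple(
            Atom(i, elements[i], coords[i]) for i in range(stack.array_length())
        )
        snapshots.append(Snapshot(f, atoms))
    if not snapshots:
        raise TrajectoryError("PDB file contains no coordinate records")
    return snapshots


def read_trajectory(path: str | Path, fmt: str | None = None) -> Trajectory:
    """Read a multi-frame XYZ or PDB file into a :class:`Trajectory`.

    Parameters
    ----------
    path:
        Input file. Must exist.
    fmt:
        ``"xyz"`` or ``"pdb"``; inferred from the suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt == "xyz":
        snaps = _parse_xyz(path)
    elif fmt == "pdb":
        snaps = _parse_pdb(path)
    else:
        raise ValueError(f"unsupported trajectory format: {fmt!r}")
    return Trajectory(tuple(snaps))


def write_xyz(
    atoms_or_frames: Sequence[Atom] | Iterable[Sequence[Atom]],
    path: str | Path,
    comment: str = "written by mdgraphs",
    multi_frame: bool = False,
) -> None:
    """Write atoms (or, with ``multi_frame``, a list of frames) as XYZ.

    Positions must be finite; a NaN/inf coordinate is rejected before any
    output is produced. Round-trip through :func:`read_trajectory` preserves
    elements exactly and coordinates to well below 1e-4 Angstrom.
    """
    frames = list(atoms_or_frames) if multi_frame else [list(atoms_or_frames)]
    out_lines: list[str] = []
    for frame in frames:
        frame = list(frame)
        for a in frame:
            if not np.all(np.isfinite(a.position)):
                raise ValueError(f"atom {a.index}: non-finite position, refusing to write")
        out_lines.append(str(len(frame)))
        out_lines.append(comment)
        for a in frame:
            x, y, z = a.position
            out_lines.append(f"{a.element} {x:.8f} {y:.8f} {z:.8f}")
    Path(path).write_text("\n".join(out_lines) + "\n")


# ---------------------------------------------------------------------------
# Parameter database

_THRESHOLD_KEYS = {
    "covalent_tolerance", "hbond_heavy_max", "hbond_angle_min",
    "electrostatic_max", "organometallic_max", "acceptor_elements",
    "metal_elements",
}
_ELEMENT_KEYS = {"covalent_radius", "max_covalent_bonds", "is_metal",
                 "is_ion_candidate"}


def load_params(
    config_path: str | Path | None = None,
) -> tuple[dict[str, ElementParams], Thresholds]:
    """Built-in element table and thresholds, overlaid by a YAML config.

    The config has two optional sections::

        thresholds:
          covalent_tolerance: 0.45
        elements:
          O: {covalent_radius: 0.68}
          Xx: {covalent_radius: 1.0, max_covalent_bonds: 2}

    Unknown keys are rejected; negative radii/distances raise
    :class:`ParamError`.
    """
    elements = default_element_params()
    thresholds = Thresholds()
    if config_path is None:
        return elements, thresholds

    raw = yaml.safe_load(Path(config_path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ParamError("config root must be a mapping")
    unknown = set(raw) - {"thresholds", "elements"}
    if unknown:
        raise ParamError(f"unknown top-level config keys: {sorted(unknown)}")

    thr_raw = dict(raw.get("thresholds") or {})
    unknown = set(thr_raw) - _THRESHOLD_KEYS
    if unknown:
        raise ParamError(f"unknown threshold keys: {sorted(unknown)}")
    for key in ("acceptor_elements", "metal_elements"):
        if key in thr_raw:
            thr_raw[key] = frozenset(normalize_symbol(s) for s in thr_raw[key])
    thresholds = replace(thresholds, **thr_raw)

    for sym, fields_ in (raw.get("elements") or {}).items():
        sym = normalize_symbol(sym)
        if not isinstance(fields_, Mapping):
            raise ParamError(f"element {sym}: expected a mapping of fields")
        unknown = set(fields_) - _ELEMENT_KEYS
        if unknown:
            raise ParamError(f"element {sym}: unknown keys {sorted(unknown)}")
        base = elements.get(sym)
        merged = {
            "covalent_radius": fields_.get(
                "covalent_radius", base.covalent_radius if base else None),
            "max_covalent_bonds": fields_.get(
                "max_covalent_bonds", base.max_covalent_bonds if base else None),
            "is_metal": fields_.get("is_metal", base.is_metal if base else False),
            "is_ion_candidate": fields_.get(
                "is_ion_candidate", base.is_ion_candidate if base else False),
        }
        if merged["covalent_radius"] is None or merged["max_covalent_bonds"] is None:
            raise ParamError(
                f"element {sym}: new elements need covalent_radius and "
                "max_covalent_bonds"
            )
        elements[sym] = ElementParams(sym, **merged)
    return elements, thresholds


def dump_params(
    elements: Mapping[str, ElementParams], thresholds: Thresholds,
    path: str | Path,
) -> None:
    """Emit the effective configuration; reloading it reproduces the inputs."""
    doc = {
        "thresholds": {
            "covalent_tolerance": thresholds.covalent_tolerance,
            "hbond_heavy_max": thresholds.hbond_heavy_max,
            "hbond_angle_min": thresholds.hbond_angle_min,
            "electrostatic_max": thresholds.electrostatic_max,
            "organometallic_max": thresholds.organometallic_max,
            "acceptor_elements": sorted(thresholds.acceptor_elements),
            "metal_elements": sorted(thresholds.metal_elements),
        },
        "elements": {
            sym: {
                "covalent_radius": p.covalent_radius,
                "max_covalent_bonds": p.max_covalent_bonds,
                "is_metal": p.is_metal,
                "is_ion_candidate": p.is_ion_candidate,
            }
            for sym, p in sorted(elements.items())
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
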