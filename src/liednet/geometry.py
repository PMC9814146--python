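"""Molecular structures, label schemes and deformation databases.

The retrieval problem regresses a real-valued label vector from a scattering
image.  A :class:`LabelScheme` fixes the bidirectional mapping between a
molecular geometry and that vector: two bond lengths for a symmetric linear
molecule such as acetylene, a bond length and a bond angle for a bent
triatomic such as carbon disulfide, or the raw Cartesian coordinates of a set
of tracked atoms for large 3D molecules.

Databases of training structures are generated either on a regular parameter
grid of a label scheme, or — for molecules with too many degrees of freedom —
by rigid shifts of a few atom groups combined with a molecule-wide scale
factor, sampled uniformly.

Coordinate convention: structures built from labels are centred at their
centroid, linear molecules lie along +z, and bent triatomics bend in the
xz-plane.  Orientation-averaged scattering depends only on pair distances, so
any convention works; one is fixed for reproducible labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ATOMIC_NUMBERS",
    "Atom",
    "MolecularStructure",
    "LabelScheme",
    "SymmetricLinearScheme",
    "BentTriatomicScheme",
    "CartesianSubsetScheme",
    "DeformationSpec",
    "apply_group_deformation",
    "generate_database",
    "internuclear_distances",
    "distance_matrix",
    "read_xyz",
    "write_xyz",
    "acetylene",
    "carbon_disulfide",
    "fenchone_like",
]

#: Element symbol -> atomic number, for the elements this package meets.
ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}
_SYMBOLS = {z: s for s, z in ATOMIC_NUMBERS.items()}


@dataclass(frozen=True)
class Atom:
    """A single atom: element symbol, atomic number and position in Angstrom."""

    element: str
    position: np.ndarray

    def __post_init__(self):
        if self.element not in ATOMIC_NUMBERS:
            raise ValueError(f"unknown element symbol {self.element!r}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise ValueError("position must be finite")
        object.__setattr__(self, "position", pos)

    @property
    def Z(self) -> int:
        return ATOMIC_NUMBERS[self.element]


class MolecularStructure:
    """An ordered collection of atoms.

    Atom order is stable and meaningful: label vectors and group definitions
    index into it.
    """

    def __init__(self, atoms: Sequence[Atom], name: str = ""):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("a structure needs at least one atom")
        self.atoms = atoms
        self.name = name

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"MolecularStructure({self.formula()}, name={self.name!r})"

    @classmethod
    def from_arrays(cls, elements: Sequence[str], coords, name: str = "") -> "MolecularStructure":
        coords = np.asarray(coords, dtype=float).reshape(len(elements), 3)
        return cls([Atom(e, c) for e, c in zip(elements, coords)], name=name)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([a.Z for a in self.atoms], dtype=int)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of Cartesian coordinates in Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def formula(self) -> str:
        counts: dict[str, int] = {}
        for e in self.elements:
            counts[e] = counts.get(e, 0) + 1
        return "".join(f"{e}{counts[e] if counts[e] > 1 else ''}"
                       for e in sorted(counts, key=lambda s: (s != "C", s != "H", s)))

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def with_coords(self, coords, name: str | None = None) -> "MolecularStructure":
        return MolecularStructure.from_arrays(
            self.elements, coords, name=self.name if name is None else name)

    def centered(self) -> "MolecularStructure":
        return self.with_coords(self.coords - self.centroid())


def distance_matrix(structure: MolecularStructure) -> np.ndarray:
    """Full symmetric matrix of internuclear distances R_ij in Angstrom."""
    xyz = structure.coords
    d = xyz[:, None, :] - xyz[None, :, :]
    return np.sqrt((d * d).sum(axis=-1))


def internuclear_distances(structure: MolecularStructure) -> np.ndarray:
    """All pair distances R_ij (i < j) in Angstrom; empty for a single atom.

    The orientation-averaged scattering signal depends on the structure only
    through this multiset, which is invariant under rigid motions.
    """
    n = len(structure)
    if n < 2:
        return np.empty(0)
    m = distance_matrix(structure)
    iu = np.triu_indices(n, k=1)
    return m[iu]


# ---------------------------------------------------------------------------
# Label schemes
# ---------------------------------------------------------------------------

class LabelScheme:
    """Bidirectional mapping between a structure and its label vector.

    Subclasses implement :meth:`labels` (structure -> vector) and
    :meth:`structure` (vector -> structure); the round trip is exact to
    floating-point precision.  Distances are in Angstrom, angles in degrees.
    """

    #: label names, fixed length and order
    names: tuple[str, ...]
    #: per-label unit strings ("A" or "deg")
    units: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.names)

    def labels(self, structure: MolecularStructure) -> np.ndarray:
        raise NotImplementedError

    def structure(self, labels: np.ndarray) -> MolecularStructure:
        raise NotImplementedError

    def _check(self, labels) -> np.ndarray:
        v = np.asarray(labels, dtype=float).ravel()
        if v.shape != (self.size,):
            raise ValueError(
                f"expected {self.size} labels {self.names}, got shape {v.shape}")
        return v


class SymmetricLinearScheme(LabelScheme):
    """H-C-C-H-type symmetric linear molecule parametrised by (R_inner, R_outer).

    The structure is built along +z, centred at the centroid: two inner atoms
    separated by ``R_inner`` with one outer atom beyond each at ``R_outer``.
    For acetylene the labels are (R_CC, R_CH).
    """

    def __init__(self, inner_element: str = "C", outer_element: str = "H",
                 names: tuple[str, str] = ("R_CC", "R_CH")):
        self.inner_element = inner_element
        self.outer_element = outer_element
        self.names = tuple(names)
        self.units = ("A", "A")

    def structure(self, labels) -> MolecularStructure:
        r_in, r_out = self._check(labels)
        if r_in <= 0 or r_out <= 0:
            raise ValueError("bond distances must be positive")
        z_inner = r_in / 2.0
        z_outer = z_inner + r_out
        coords = [(0, 0, -z_outer), (0, 0, -z_inner), (0, 0, z_inner), (0, 0, z_outer)]
        elements = [self.outer_element, self.inner_element,
                    self.inner_element, self.outer_element]
        return MolecularStructure.from_arrays(elements, coords,
                                              name=f"{self.inner_element}2{self.outer_element}2")

    def labels(self, structure: MolecularStructure) -> np.ndarray:
        if len(structure) != 4:
            raise ValueError("symmetric linear scheme expects 4 atoms")
        xyz = structure.coords
        r_in = float(np.linalg.norm(xyz[2] - xyz[1]))
        r_out = float(np.linalg.norm(xyz[1] - xyz[0]))
        return np.array([r_in, r_out])


class BentTriatomicScheme(LabelScheme):
    """S-C-S-type symmetric triatomic parametrised in polar form (R, theta).

    Labels are the bond length R (Angstrom) and the bond angle theta
    (degrees, in (0, 180]).  The central atom sits on the z-axis with the two
    outer atoms placed symmetrically in the xz-plane; the structure is then
    recentred at its centroid.  For carbon disulfide the labels are
    (R_CS, theta_SCS).
    """

    def __init__(self, center_element: str = "C", outer_element: str = "S",
                 names: tuple[str, str] = ("R_CS", "theta_SCS")):
        self.center_element = center_element
        self.outer_element = outer_element
        self.names = tuple(names)
        self.units = ("A", "deg")

    def structure(self, labels) -> MolecularStructure:
        r, theta = self._check(labels)
        if r <= 0:
            raise ValueError("bond distance must be positive")
        if not (0.0 < theta <= 180.0):
            raise ValueError("bond angle must be in (0, 180] degrees")
        half = np.deg2rad(theta) / 2.0
        x, z = r * np.sin(half), r * np.cos(half)
        coords = [(-x, 0, z), (0, 0, 0), (x, 0, z)]
        elements = [self.outer_element, self.center_element, self.outer_element]
        s = MolecularStructure.from_arrays(
            elements, coords, name=f"{self.center_element}{self.outer_element}2")
        return s.centered()

    def labels(self, structure: MolecularStructure) -> np.ndarray:
        if len(structure) != 3:
            raise ValueError("bent triatomic scheme expects 3 atoms")
        xyz = structure.coords
        v1, v2 = xyz[0] - xyz[1], xyz[2] - xyz[1]
        r = float(np.linalg.norm(v1))
        cos_t = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        theta = float(np.rad2deg(np.arccos(np.clip(cos_t, -1.0, 1.0))))
        return np.array([r, theta])


class CartesianSubsetScheme(LabelScheme):
    """Labels are the Cartesian coordinates of a subset of tracked atoms.

    Used for large 3D molecules where only a few atoms are reported: the
    label vector is the flattened (x, y, z) of ``tracked_atoms`` in order.
    ``structure(labels)`` places the tracked atoms at the given coordinates
    and leaves every other atom at its base-structure position.
    """

    def __init__(self, base_structure: MolecularStructure,
                 tracked_atoms: Sequence[int]):
        n = len(base_structure)
        tracked = list(tracked_atoms)
        if len(set(tracked)) != len(tracked):
            raise ValueError("tracked atom indices must be unique")
        if any(i < 0 or i >= n for i in tracked):
            raise ValueError("tracked atom index out of range")
        self.base_structure = base_structure
        self.tracked_atoms = tracked
        self.names = tuple(f"{ax}_{base_structure.elements[i]}{i}"
                           for i in tracked for ax in "xyz")
        self.units = ("A",) * (3 * len(tracked))

    def labels(self, structure: MolecularStructure) -> np.ndarray:
        if len(structure) != len(self.base_structure):
            raise ValueError("structure size does not match the base structure")
        return structure.coords[self.tracked_atoms].ravel().copy()

    def structure(self, labels) -> MolecularStructure:
        v = self._check(labels).reshape(-1, 3)
        coords = self.base_structure.coords.copy()
        coords[self.tracked_atoms] = v
        return self.base_structure.with_coords(coords)


# ---------------------------------------------------------------------------
# Deformation databases
# ---------------------------------------------------------------------------

@dataclass
class DeformationSpec:
    """Definition of a structure database.

    Two modes:

    ``parameter-grid``
        ``parameters`` is a list of ``(name, min, max, n_steps)``; every grid
        point of the label scheme's parameter space becomes one database
        entry (cardinality = product of step counts).  ``scheme`` must be
        given and the parameter order must match its label order.

    ``group-deformation``
        ``groups`` is a list of disjoint atom-index sets of
        ``base_structure``; each sampled structure rigidly translates every
        group by a shift drawn uniformly from ``shift_range`` per axis and
        then scales all coordinates about the centroid by a factor drawn
        uniformly from ``global_scale``.  ``count`` structures are drawn
        with the spec's ``seed``.
    """

    mode: str
    base_structure: MolecularStructure | None = None
    scheme: LabelScheme | None = None
    parameters: list[tuple] = field(default_factory=list)
    groups: list[list[int]] = field(default_factory=list)
    shift_range: tuple[float, float] = (-0.3, 0.3)
    global_scale: tuple[float, float] = (0.9, 1.1)
    count: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("parameter-grid", "group-deformation"):
            raise ValueError(f"unknown deformation mode {self.mode!r}")
        if self.mode == "parameter-grid":
            if self.scheme is None:
                raise ValueError("parameter-grid mode needs a label scheme")
            if not self.parameters:
                raise ValueError("parameter list must not be empty")
            for name, lo, hi, n in self.parameters:
                if lo > hi:
                    raise ValueError(f"parameter {name}: min > max")
                if isinstance(n, str):
                    if n != "uniform":
                        raise ValueError(f"parameter {name}: unknown sampler {n!r}")
                    if self.count <= 0:
                        raise ValueError("sampled parameters need a positive count")
                elif n < 1:
                    raise ValueError(f"parameter {name}: n_steps must be >= 1")
        else:
            if self.base_structure is None:
                raise ValueError("group-deformation mode needs a base structure")
            if self.count <= 0:
                raise ValueError("requested count must be positive")
            n = len(self.base_structure)
            seen: set[int] = set()
            for g in self.groups:
                gs = set(g)
                if gs & seen:
                    raise ValueError("atom groups must be disjoint")
                if any(i < 0 or i >= n for i in gs):
                    raise ValueError("group atom index out of range")
                seen |= gs
            if self.shift_range[0] > self.shift_range[1]:
                raise ValueError("shift_range: min > max")
            if not (0 < self.global_scale[0] <= self.global_scale[1]):
                raise ValueError("global_scale bounds must be positive and ordered")


def apply_group_deformation(spec: DeformationSpec, group_shifts,
                            scale: float = 1.0) -> MolecularStructure:
    """Rigidly translate each atom group, then scale about the centroid.

    ``group_shifts`` is one 3-vector (Angstrom) per group in ``spec.groups``.
    Atoms outside every group move only through the global scale.  Intra-group
    distances are unchanged by the shifts; the scale multiplies every pair
    distance uniformly.
    """
    if spec.base_structure is None:
        raise ValueError("spec has no base structure")
    if scale <= 0:
        raise ValueError("scale must be positive")
    shifts = np.asarray(group_shifts, dtype=float)
    if shifts.shape != (len(spec.groups), 3):
        raise ValueError(
            f"expected {len(spec.groups)} group shift vectors, got shape {shifts.shape}")
    coords = spec.base_structure.coords.copy()
    for g, s in zip(spec.groups, shifts):
        coords[list(g)] += s
    centroid = coords.mean(axis=0)
    coords = centroid + scale * (coords - centroid)
    return spec.base_structure.with_coords(coords)


def generate_database(spec: DeformationSpec,
                      scheme: LabelScheme | None = None
                      ) -> list[tuple[MolecularStructure, np.ndarray]]:
    """Generate ``(structure, label_vector)`` pairs from a deformation spec.

    Deterministic under a fixed ``spec.seed``.  In parameter-grid mode the
    labels are the grid coordinates themselves; in group-deformation mode the
    labels come from ``scheme`` (default: Cartesian coordinates of all atoms).
    """
    if spec.mode == "parameter-grid":
        if any(isinstance(p[3], str) for p in spec.parameters):
            # uniform sampling of the parameter box instead of a regular grid
            rng = np.random.default_rng(spec.seed)
            bounds = np.array([(lo, hi) for _, lo, hi, _ in spec.parameters])
            samples = rng.uniform(bounds[:, 0], bounds[:, 1],
                                  size=(spec.count, len(spec.parameters)))
            return [(spec.scheme.structure(v), v) for v in samples]
        axes = [np.linspace(lo, hi, int(n)) for _, lo, hi, n in spec.parameters]
        entries = []
        for values in itertools.product(*axes):
            v = np.array(values, dtype=float)
            entries.append((spec.scheme.structure(v), v))
        return entries

    rng = np.random.default_rng(spec.seed)
    if scheme is None:
        scheme = CartesianSubsetScheme(spec.base_structure,
                                       range(len(spec.base_structure)))
    lo, hi = spec.shift_range
    slo, shi = spec.global_scale
    entries = []
    for _ in range(spec.count):
        shifts = rng.uniform(lo, hi, size=(len(spec.groups), 3))
        scale = rng.uniform(slo, shi)
        s = apply_group_deformation(spec, shifts, scale)
        entries.append((s, scheme.labels(s)))
    return entries


# ---------------------------------------------------------------------------
# XYZ file I/O
# ---------------------------------------------------------------------------

def read_xyz(path) -> MolecularStructure:
    """Read a standard XYZ file (count line, comment line, ``el x y z`` rows)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: malformed atom-count line {lines[0]!r}")
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) < n:
        raise ValueError(f"{path}: count line says {n} atoms, found {len(body)} rows")
    atoms = []
    for ln in body[:n]:
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed atom row {ln!r}")
        atoms.append(Atom(parts[0], np.array(parts[1:4], dtype=float)))
    name = lines[1].strip() if len(lines) > 1 else ""
    return MolecularStructure(atoms, name=name)


def write_xyz(structure: MolecularStructure, path, comment: str | None = None) -> None:
    """Write a structure as a standard XYZ file (coordinates in Angstrom)."""
    lines = [str(len(structure)), comment if comment is not None else structure.name]
    for a in structure.atoms:
        x, y, z = a.position
        lines.append(f"{a.element:2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Reference structures
# ---------------------------------------------------------------------------

def acetylene(r_cc: float = 1.20, r_ch: float = 1.06) -> MolecularStructure:
    """Equilibrium-geometry acetylene (linear H-C#C-H), distances in Angstrom."""
    return SymmetricLinearScheme().structure([r_cc, r_ch])


def carbon_disulfide(r_cs: float = 1.55, theta: float = 180.0) -> MolecularStructure:
    """Equilibrium-geometry carbon disulfide (linear S=C=S)."""
    return BentTriatomicScheme().structure([r_cs, theta])


def fenchone_like() -> MolecularStructure:
    """Packaged 27-atom bicyclic ketone (C10H16O) used as the large-molecule demo.

    This is a synthetic conformer generated with a distance-geometry embedding,
    a stand-in for the experimental equilibrium geometry; see the packaged
    ``data/fenchone_synthetic.xyz``.
    """
    from importlib.resources import as_file, files

    with as_file(files("liednet.data").joinpath("fenchone_synthetic.xyz")) as p:
        return read_xyz(p)
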