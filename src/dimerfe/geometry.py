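"""Reference-frame geometry and harmonic restraints for the SOD1 dimer.

The relative position and orientation of chain B with respect to chain A are
described through six anchor points — three per chain — each the center of
mass of a fixed residue group:

* ``P1``: the central β-barrel (residues 1–48, 84–120, 143–153),
* ``P2``: a point on the barrel's β-sheet surface (residues 5–7, 17–19, 32–34),
* ``P3``: the barrel "lid" (residues 11–13, 40–42, 120–122),

with primed points defined identically on chain B.  From these the spherical
position coordinates (r, θ, ϕ) and the Euler-like orientation angles
(Θ, Φ, Ψ) follow:

* r = \\|P1P1′\\|, θ = ∠P1′-P1-P2, ϕ = dihedral(P1′, P1, P2, P3),
* Θ = ∠P1-P1′-P2′, Φ = dihedral(P1, P1′, P2′, P3′),
  Ψ = dihedral(P2, P1, P1′, P2′).

Dihedrals use the IUPAC sign convention (atan2 of cross products), range
(−π, π].  Harmonic restraints on angular coordinates use the minimum-image
difference so that a center near ±π does not produce spurious 2π jumps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "AtomSelection",
    "ReferenceFrame",
    "HarmonicRestraint",
    "RestraintSchedule",
    "DEFAULT_RESTRAINT_ORDER",
    "FRAME_RESIDUE_GROUPS",
    "SelectionError",
    "DegenerateGeometryError",
    "wrap_angle",
    "angle_between",
    "dihedral",
    "compute_frame_points",
    "spherical_coordinates",
    "euler_angles",
    "reference_frame",
    "kabsch_rmsd",
    "rmsd",
    "restraint_energy",
    "read_pdb",
    "write_pdb",
]


class SelectionError(KeyError):
    """An atom selection resolved to nothing, or a named residue is missing."""


class DegenerateGeometryError(ValueError):
    """Collinear or coincident points make an angle or dihedral undefined."""


# Standard atomic masses (amu) keyed by element symbol; atoms whose element
# cannot be inferred fall back to carbon, which only matters for exotic names.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "CU": 63.546, "ZN": 65.38,
    "MG": 24.305, "MN": 54.938, "K": 39.098, "NA": 22.990, "CA": 40.078,
    "CL": 35.45,
}

#: Residue groups (1-based, inclusive ranges) defining the per-chain frame points.
FRAME_RESIDUE_GROUPS = {
    "P1": [(1, 48), (84, 120), (143, 153)],
    "P2": [(5, 7), (17, 19), (32, 34)],
    "P3": [(11, 13), (40, 42), (120, 122)],
}


def element_of(atom_name: str, element: str | None = None) -> str:
    """Infer an element symbol from a PDB atom name (e.g. 'CA' → C, 'ZN' → ZN)."""
    if element:
        return element.upper()
    name = atom_name.strip()
    two = name[:2].upper()
    if two in ("CU", "ZN", "FE", "MG", "MN", "SE", "NA", "CL") and len(name) <= 2:
        return two
    # strip leading digits (e.g. 1HB)
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper() if stripped else "C"


@dataclass(frozen=True)
class Atom:
    name: str
    residue_index: int
    chain_id: str
    coord: tuple[float, float, float]
    element: str = ""

    @property
    def mass(self) -> float:
        elem = element_of(self.name, self.element or None)
        return ATOMIC_MASSES.get(elem, ATOMIC_MASSES["C"])


@dataclass
class StructureModel:
    """A minimal atomic structure: a flat atom list with chain/residue indexing."""

    atoms: list[Atom]

    def __post_init__(self) -> None:
        coords = np.asarray([a.coord for a in self.atoms], dtype=float)
        if coords.size and not np.isfinite(coords).all():
            raise ValueError("non-finite atomic coordinates")

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def coordinates(self, atoms: Sequence[Atom] | None = None) -> np.ndarray:
        return np.asarray([a.coord for a in (atoms if atoms is not None else self.atoms)])

    def select(self, selection: "AtomSelection") -> list[Atom]:
        return selection.resolve(self)


@dataclass(frozen=True)
class AtomSelection:
    """Chain + residue-range + atom-name filter.

    ``residue_ranges`` are 1-based inclusive ``(first, last)`` pairs;
    ``atom_names`` of ``None`` keeps every atom, ``"heavy"`` keeps non-hydrogens,
    otherwise an explicit name set (e.g. backbone ``("N", "CA", "C")``).
    """

    chain_id: str
    residue_ranges: tuple[tuple[int, int], ...]
    atom_names: tuple[str, ...] | Literal["heavy"] | None = None

    def _keep_name(self, atom: Atom) -> bool:
        if self.atom_names is None:
            return True
        if self.atom_names == "heavy":
            return element_of(atom.name, atom.element or None) != "H"
        return atom.name in self.atom_names

    def resolve(self, structure: StructureModel) -> list[Atom]:
        chosen = [
            a
            for a in structure.atoms
            if a.chain_id == self.chain_id
            and any(lo <= a.residue_index <= hi for lo, hi in self.residue_ranges)
            and self._keep_name(a)
        ]
        if not chosen:
            raise SelectionError(
                f"selection resolved to no atoms (chain {self.chain_id!r}, "
                f"residues {self.residue_ranges}, atoms {self.atom_names!r})"
            )
        return chosen


# ---------------------------------------------------------------------------
# Elementary vector operations
# ---------------------------------------------------------------------------

def wrap_angle(x: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle (or array) into (−π, π]."""
    wrapped = np.mod(np.asarray(x, dtype=float) + np.pi, 2.0 * np.pi) - np.pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    return float(wrapped) if np.isscalar(x) or np.ndim(x) == 0 else wrapped


def angle_between(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    """Angle ∠a-vertex-b in [0, π]."""
    u = np.asarray(a, float) - np.asarray(vertex, float)
    v = np.asarray(b, float) - np.asarray(vertex, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("coincident points in angle computation")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(cosang))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral of the ordered points (p0, p1, p2, p3), range (−π, π].

    IUPAC convention via atan2; raises ``DegenerateGeometryError`` when either
    arm is collinear with the central bond.
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 == 0.0 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("collinear arms: dihedral undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / norm_b2)
    return float(wrap_angle(math.atan2(y, x)))


# ---------------------------------------------------------------------------
# Frame points and relative coordinates
# ---------------------------------------------------------------------------

def _group_center(structure: StructureModel, chain: str, ranges, mass_weighted: bool) -> np.ndarray:
    # verify every listed residue is present before averaging
    present = {a.residue_index for a in structure.atoms if a.chain_id == chain}
    for lo, hi in ranges:
        for res in range(lo, hi + 1):
            if res not in present:
                raise SelectionError(f"chain {chain!r} is missing residue {res}")
    atoms = AtomSelection(chain, tuple(ranges)).resolve(structure)
    coords = np.asarray([a.coord for a in atoms])
    if mass_weighted:
        w = np.asarray([a.mass for a in atoms])
    else:
        w = np.ones(len(atoms))
    return coords.T @ w / w.sum()


def compute_frame_points(
    structure: StructureModel, chain: str, mass_weighted: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centers of mass (P1, P2, P3) of the frame residue groups of one chain.

    ``mass_weighted=False`` uses geometric centroids, convenient for toy inputs
    built from single marker atoms.
    """
    return tuple(
        _group_center(structure, chain, FRAME_RESIDUE_GROUPS[p], mass_weighted)
        for p in ("P1", "P2", "P3")
    )


def spherical_coordinates(points_a, points_b) -> tuple[float, float, float]:
    """(r, θ, ϕ) of chain B's P1′ in chain A's frame.

    r = |P1P1′|; θ = ∠P1′-P1-P2 in [0, π]; ϕ = dihedral(P1′, P1, P2, P3)
    in (−π, π].  Raises ``DegenerateGeometryError`` when P1′ coincides with
    P1 or lies on the P1–P2 axis (ϕ undefined).
    """
    p1, p2, p3 = (np.asarray(p, float) for p in points_a)
    p1b = np.asarray(points_b[0], float)
    r = float(np.linalg.norm(p1b - p1))
    if r == 0.0:
        raise DegenerateGeometryError("P1 and P1' coincide")
    theta = angle_between(p1b, p1, p2)
    phi = dihedral(p1b, p1, p2, p3)
    return r, theta, phi


def euler_angles(points_a, points_b) -> tuple[float, float, float]:
    """(Θ, Φ, Ψ) orienting chain B relative to chain A.

    Θ = ∠P1-P1′-P2′ in [0, π]; Φ = dihedral(P1, P1′, P2′, P3′);
    Ψ = dihedral(P2, P1, P1′, P2′); both dihedrals in (−π, π].
    """
    p1, p2, _ = (np.asarray(p, float) for p in points_a)
    p1b, p2b, p3b = (np.asarray(p, float) for p in points_b)
    big_theta = angle_between(p1, p1b, p2b)
    big_phi = dihedral(p1, p1b, p2b, p3b)
    big_psi = dihedral(p2, p1, p1b, p2b)
    return big_theta, big_phi, big_psi


@dataclass(frozen=True)
class ReferenceFrame:
    """The six anchor points and the derived relative coordinates."""

    P1: tuple[float, float, float]
    P2: tuple[float, float, float]
    P3: tuple[float, float, float]
    P1p: tuple[float, float, float]
    P2p: tuple[float, float, float]
    P3p: tuple[float, float, float]
    r: float
    theta: float
    phi: float
    Theta: float
    Phi: float
    Psi: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be positive")
        for name, val in (("theta", self.theta), ("Theta", self.Theta)):
            if not 0.0 <= val <= np.pi:
                raise ValueError(f"{name} outside [0, pi]: {val}")
        for name, val in (("phi", self.phi), ("Phi", self.Phi), ("Psi", self.Psi)):
            if not -np.pi < val <= np.pi + 1e-12:
                raise ValueError(f"{name} outside (-pi, pi]: {val}")


def reference_frame(
    structure: StructureModel, chain_a: str, chain_b: str, mass_weighted: bool = True
) -> ReferenceFrame:
    """Compute the full reference frame of a dimer structure."""
    pts_a = compute_frame_points(structure, chain_a, mass_weighted)
    pts_b = compute_frame_points(structure, chain_b, mass_weighted)
    r, theta, phi = spherical_coordinates(pts_a, pts_b)
    big_t, big_p, big_s = euler_angles(pts_a, pts_b)
    return ReferenceFrame(
        *(tuple(map(float, p)) for p in (*pts_a, *pts_b)),
        r=r, theta=theta, phi=phi, Theta=big_t, Phi=big_p, Psi=big_s,
    )


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Optimal-superposition RMSD between two (n, 3) coordinate sets.

    Centroids are removed and the optimal proper rotation found by SVD
    (Kabsch); the fit set is the compared set itself.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"coordinate shape mismatch: {x.shape} vs {y.shape}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    cov = xc.T @ yc
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    s_corr = np.array([1.0, 1.0, d])
    msd = (np.sum(xc**2) + np.sum(yc**2) - 2.0 * np.sum(s * s_corr)) / len(x)
    return float(np.sqrt(max(msd, 0.0)))


def rmsd(
    structure: StructureModel,
    reference: StructureModel,
    selection: AtomSelection,
) -> float:
    """Optimal-superposition RMSD (Å) over a selection present in both models.

    The selection must resolve to identical atom lists (same names, residues,
    order) in both structures.
    """
    atoms_a = selection.resolve(structure)
    atoms_b = selection.resolve(reference)
    if len(atoms_a) != len(atoms_b):
        raise ValueError(
            f"selection resolves to {len(atoms_a)} atoms in structure but "
            f"{len(atoms_b)} in reference"
        )
    for a, b in zip(atoms_a, atoms_b):
        if (a.name, a.residue_index) != (b.name, b.residue_index):
            raise ValueError(
                f"selection atom mismatch: {a.name}/{a.residue_index} vs "
                f"{b.name}/{b.residue_index}"
            )
    return kabsch_rmsd(
        structure.coordinates(atoms_a), reference.coordinates(atoms_b)
    )


# ---------------------------------------------------------------------------
# Harmonic restraints
# ---------------------------------------------------------------------------

RestraintKind = Literal["angle", "dihedral", "distance", "rmsd"]

#: Serial order in which restraints are imposed in the bound state.
DEFAULT_RESTRAINT_ORDER = (
    "u_LA_c", "u_LB_c", "u_BA_c", "u_BB_c", "u_IA_c", "u_IB_c",
    "u_Theta_o", "u_Phi_o", "u_Psi_o", "u_theta_a", "u_phi_a",
)


@dataclass(frozen=True)
class HarmonicRestraint:
    """One harmonic (parabolic) restraint u(x) = (k/2)·Δ².

    For ``angle`` and ``dihedral`` kinds Δ is the minimum-image angular
    difference wrap(x − center); otherwise Δ = x − center.  Spring constants
    are kcal/mol/rad² for angular kinds and kcal/mol/Å² for distance/rmsd.
    """

    name: str
    kind: RestraintKind
    center: float
    k: float
    selection: AtomSelection | None = None
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("spring constant must be non-negative")
        if self.kind in ("distance", "rmsd") and self.center < 0:
            raise ValueError(f"{self.kind} center must be non-negative")

    def energy(self, value: float | np.ndarray) -> float | np.ndarray:
        return restraint_energy(self, value)


def restraint_energy(restraint: HarmonicRestraint, value):
    """Harmonic restraint energy (kcal/mol) at a coordinate value (or array)."""
    value = np.asarray(value, dtype=float)
    if restraint.kind in ("angle", "dihedral"):
        delta = wrap_angle(value - restraint.center)
    else:
        delta = value - restraint.center
    energy = 0.5 * restraint.k * np.square(delta)
    return float(energy) if energy.ndim == 0 else energy


@dataclass
class RestraintSchedule:
    """An ordered list of named restraints, applied serially."""

    restraints: list[HarmonicRestraint]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.restraints]

    def __iter__(self):
        return iter(self.restraints)

    def __len__(self) -> int:
        return len(self.restraints)


# ---------------------------------------------------------------------------
# PDB I/O (via Biopython)
# ---------------------------------------------------------------------------

def read_pdb(path, model_index: int = 0) -> StructureModel:
    """Read ATOM/HETATM records from a PDB file into a StructureModel."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    bio = parser.get_structure("s", str(path))
    model = list(bio)[model_index]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                atoms.append(
                    Atom(
                        name=atom.get_name(),
                        residue_index=residue.get_id()[1],
                        chain_id=chain.get_id(),
                        coord=tuple(float(c) for c in atom.get_coord()),
                        element=(atom.element or "").strip(),
                    )
                )
    return StructureModel(atoms)


def write_pdb(structure: StructureModel, path) -> None:
    """Write a StructureModel as minimal PDB ATOM records (glycine residues)."""
    with open(path, "w") as fh:
        for i, a in enumerate(structure.atoms, start=1):
            x, y, z = a.coord
            elem = element_of(a.name, a.element or None)
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            fh.write(
                f"ATOM  {i:5d} {name:<4s} GLY {a.chain_id:1s}{a.residue_index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2s}\n"
            )
        fh.write("END\n")
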