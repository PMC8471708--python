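"""Atomic-structure handling for supramolecular chirality analysis.

Reads PDB/mmCIF files (via gemmi), extracts C-alpha traces for the backbone
chirality sum, partitions supramolecular assemblies into their constituent
molecules (one coil of a diphenylalanine nanotube is 6 molecules of 43
atoms), computes mass-weighted centers of mass, estimates point-charge
dipole moments from PQR-style charges, and fits helix parameters (pitch,
radius, axis) to an ordered set of points such as dipole origins.

The point-charge dipole estimator is a classical sum D = sum q_j (r_j -
r_ref) over partial charges.  It is NOT equivalent to a quantum-chemical or
force-field dipole computation; sets built from it are tagged
"point-charge" so downstream output records the provenance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import gemmi
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import least_squares

from .core import CalphaTrace, CoilDipoleSet, DipoleRecord, Vec3
from .errors import (
    DegenerateFitError,
    EmptyTraceError,
    InvalidInputError,
    MassLookupError,
    MissingChargeError,
    PartitionError,
    StructureFormatError,
)

__all__ = [
    "Atom",
    "MoleculeGroup",
    "HelixParams",
    "read_structure",
    "read_pqr",
    "extract_calpha_trace",
    "partition_molecules",
    "center_of_mass",
    "point_charge_dipole",
    "order_groups_along_helix",
    "fit_helix_params",
    "E_ANGSTROM_TO_DEBYE",
]

#: conversion of a dipole in elementary-charge * Angstrom to Debye
E_ANGSTROM_TO_DEBYE = 4.80320


def _element_mass(symbol: str) -> float:
    el = gemmi.Element(symbol)
    # gemmi resolves unknown symbols to the dummy element 'X'
    if el.name == "X":
        raise MassLookupError(f"unknown element symbol {symbol!r}: no standard atomic weight")
    if el.weight <= 0:
        raise MassLookupError(f"element {symbol!r} has no positive standard atomic weight")
    return float(el.weight)


@dataclass
class Atom:
    """One atom: element, standard-atomic-weight mass (u), position (Angstrom)."""

    element: str
    position: np.ndarray
    atom_name: str = ""
    residue_number: int = 0
    chain_id: str = ""
    charge: Optional[float] = None  # elementary charges
    molecule_id: int = -1
    mass: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise InvalidInputError(f"atom position must be a finite 3-vector")
        if self.mass <= 0.0:
            self.mass = _element_mass(self.element)


@dataclass
class MoleculeGroup:
    """Atoms belonging to one molecule."""

    atoms: list[Atom]
    molecule_id: int = -1
    expected_atom_count: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise PartitionError("a molecule group cannot be empty")
        if (
            self.expected_atom_count is not None
            and len(self.atoms) != self.expected_atom_count
        ):
            raise PartitionError(
                f"molecule group {self.molecule_id} has {len(self.atoms)} atoms, "
                f"expected {self.expected_atom_count}"
            )

    def __len__(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])


@dataclass(frozen=True)
class HelixParams:
    """Geometry of a discrete helix fitted to ordered points.

    ``pitch`` is the rise per full turn (Angstrom), ``radius`` the mean
    distance of the points from the fitted axis, ``axis_direction`` a unit
    vector.  Residuals quantify how helical the points actually are.
    """

    pitch: float
    radius: float
    axis_direction: Vec3
    n_points: int
    rise_per_point: float
    points_per_turn: float
    radius_rms_residual: float
    rise_std: float
    azimuthal_step_std_deg: float

    def to_dict(self) -> dict:
        return {
            "pitch": self.pitch,
            "radius": self.radius,
            "axis_direction": list(self.axis_direction.as_array()),
            "n_points": self.n_points,
            "rise_per_point": self.rise_per_point,
            "points_per_turn": self.points_per_turn,
            "radius_rms_residual": self.radius_rms_residual,
            "rise_std": self.rise_std,
            "azimuthal_step_std_deg": self.azimuthal_step_std_deg,
        }


# ---------------------------------------------------------------------------
# reading structures


def read_structure(
    path: Union[str, Path], format: Literal["pdb", "mmcif", "auto"] = "auto"
) -> list[Atom]:
    """Read a PDB or mmCIF file into a flat atom list.

    ``molecule_id`` is left unassigned (-1) until :func:`partition_molecules`.
    """
    path = Path(path)
    if not path.exists():
        raise StructureFormatError(f"structure file not found: {path}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, IndexError) as exc:
        raise StructureFormatError(f"could not parse {path}: {exc}") from exc

    atoms: list[Atom] = []
    if not st or len(st) == 0:
        raise StructureFormatError(f"{path}: no models found")
    model = st[0]
    for chain in model:
        for residue in chain:
            for at in residue:
                atoms.append(
                    Atom(
                        element=at.element.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        atom_name=at.name,
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                    )
                )
    if not atoms:
        raise StructureFormatError(f"{path}: no atoms found")
    return atoms


def read_pqr(path: Union[str, Path]) -> list[Atom]:
    """Read a PQR file (PDB-like, whitespace-separated, with per-atom charge
    and radius in place of occupancy/B-factor)."""
    path = Path(path)
    if not path.exists():
        raise StructureFormatError(f"PQR file not found: {path}")
    atoms: list[Atom] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        fields = line.split()
        # ATOM serial name resname [chain] resnum x y z charge radius
        if len(fields) == 11:
            _, _, name, _, chain, resnum, x, y, z, q, _ = fields
        elif len(fields) == 10:
            _, _, name, _, resnum, x, y, z, q, _ = fields
            chain = ""
        else:
            raise StructureFormatError(
                f"{path}:{lineno}: unrecognized PQR record with {len(fields)} fields"
            )
        try:
            pos = np.array([float(x), float(y), float(z)])
            charge = float(q)
            resnum_i = int(resnum)
        except ValueError as exc:
            raise StructureFormatError(f"{path}:{lineno}: {exc}") from exc
        element = _element_from_atom_name(name)
        atoms.append(
            Atom(
                element=element,
                position=pos,
                atom_name=name,
                residue_number=resnum_i,
                chain_id=chain,
                charge=charge,
            )
        )
    if not atoms:
        raise StructureFormatError(f"{path}: no ATOM/HETATM records")
    return atoms


def _element_from_atom_name(name: str) -> str:
    stripped = name.strip()
    if len(stripped) >= 2 and stripped[:2].capitalize() in ("Cl", "Br", "Na", "Mg", "Zn", "Fe", "Ca"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def attach_charges(atoms: Sequence[Atom], charged: Sequence[Atom]) -> list[Atom]:
    """Copy charges from a parallel PQR-derived atom list (by order)."""
    if len(atoms) != len(charged):
        raise MissingChargeError(
            f"charge table has {len(charged)} atoms but structure has {len(atoms)}"
        )
    for a, c in zip(atoms, charged):
        a.charge = c.charge
    return list(atoms)


# ---------------------------------------------------------------------------
# traces and partitions


def extract_calpha_trace(atoms: Sequence[Atom], chain_id: str) -> CalphaTrace:
    """Ordered C-alpha trace of one chain (ascending residue number).

    Gaps in residue numbering are permitted and reported as a warning.
    """
    cas = [a for a in atoms if a.chain_id == chain_id and a.atom_name.strip() == "CA"]
    if not cas:
        raise EmptyTraceError(f"no CA atoms found in chain {chain_id!r}")
    cas.sort(key=lambda a: a.residue_number)
    resnums = [a.residue_number for a in cas]
    gaps = [
        (a, b) for a, b in zip(resnums, resnums[1:]) if b - a != 1
    ]
    if gaps:
        warnings.warn(
            f"chain {chain_id!r}: non-consecutive residue numbering at {gaps}",
            stacklevel=2,
        )
    return CalphaTrace(
        coordinates=np.array([a.position for a in cas]),
        chain_id=chain_id,
        residue_numbers=resnums,
    )


def partition_molecules(
    atoms: Sequence[Atom],
    rule: Literal["by_chain", "by_residue_block", "by_connectivity_distance"] = "by_chain",
    expected_atom_count: Optional[int] = None,
    distance_cutoff: float = 2.0,
) -> list[MoleculeGroup]:
    """Partition an assembly into molecules.

    * ``by_chain`` — one group per chain identifier;
    * ``by_residue_block`` — consecutive atoms grouped into blocks of
      ``expected_atom_count`` atoms (file order);
    * ``by_connectivity_distance`` — single-linkage clustering of atom
      positions with a bond-length ``distance_cutoff`` (Angstrom).

    Every atom is assigned to exactly one group and ``molecule_id`` is set.
    """
    if not atoms:
        raise PartitionError("cannot partition an empty atom list")

    if rule == "by_chain":
        order: list[str] = []
        by_chain: dict[str, list[Atom]] = {}
        for a in atoms:
            if a.chain_id not in by_chain:
                by_chain[a.chain_id] = []
                order.append(a.chain_id)
            by_chain[a.chain_id].append(a)
        groups = [by_chain[c] for c in order]
    elif rule == "by_residue_block":
        if expected_atom_count is None:
            raise PartitionError("by_residue_block requires expected_atom_count")
        if len(atoms) % expected_atom_count != 0:
            raise PartitionError(
                f"{len(atoms)} atoms do not divide into blocks of {expected_atom_count}"
            )
        groups = [
            list(atoms[i : i + expected_atom_count])
            for i in range(0, len(atoms), expected_atom_count)
        ]
    elif rule == "by_connectivity_distance":
        positions = np.array([a.position for a in atoms])
        if len(atoms) == 1:
            groups = [list(atoms)]
        else:
            uniq = np.unique(positions, axis=0)
            if len(uniq) < len(positions):
                dup = len(positions) - len(uniq)
                raise PartitionError(
                    f"degenerate coordinates: {dup} atom(s) coincide exactly with "
                    "another atom; connectivity clustering cannot assign them"
                )
            labels = fcluster(
                linkage(positions, method="single"), t=distance_cutoff, criterion="distance"
            )
            groups_map: dict[int, list[Atom]] = {}
            first_seen: list[int] = []
            for a, lab in zip(atoms, labels):
                if lab not in groups_map:
                    groups_map[lab] = []
                    first_seen.append(lab)
            for a, lab in zip(atoms, labels):
                groups_map[lab].append(a)
            groups = [groups_map[lab] for lab in first_seen]
    else:
        raise PartitionError(f"unknown partition rule {rule!r}")

    result = []
    for mol_id, group_atoms in enumerate(groups, start=1):
        for a in group_atoms:
            a.molecule_id = mol_id
        result.append(
            MoleculeGroup(
                atoms=group_atoms,
                molecule_id=mol_id,
                expected_atom_count=expected_atom_count,
            )
        )
    return result


# ---------------------------------------------------------------------------
# per-molecule quantities


def center_of_mass(group: MoleculeGroup) -> Vec3:
    """Mass-weighted mean atomic position, Angstrom."""
    com = np.average(group.positions(), axis=0, weights=group.masses())
    return Vec3.from_array(com, "angstrom")


def point_charge_dipole(
    group: MoleculeGroup,
    reference: Literal["center_of_mass", "center_of_charge"] = "center_of_mass",
    index: int = 1,
) -> DipoleRecord:
    """Classical point-charge dipole D = sum q_j (r_j - r_ref), in Debye.

    Not equivalent to a quantum-chemical or force-field dipole; tag any
    coil assembled from these records accordingly.  For net-neutral groups
    the result is independent of the reference point.
    """
    missing = [a.atom_name or a.element for a in group.atoms if a.charge is None]
    if missing:
        raise MissingChargeError(
            f"atoms without charges in molecule {group.molecule_id}: {missing[:10]}"
        )
    charges = np.array([a.charge for a in group.atoms])
    positions = group.positions()
    if reference == "center_of_mass":
        ref = center_of_mass(group).as_array()
    elif reference == "center_of_charge":
        total_abs = np.abs(charges).sum()
        if total_abs == 0:
            raise MissingChargeError("all charges are zero; center of charge undefined")
        ref = np.average(positions, axis=0, weights=np.abs(charges))
    else:
        raise InvalidInputError(f"unknown reference {reference!r}")
    dip = ((positions - ref) * charges[:, None]).sum(axis=0) * E_ANGSTROM_TO_DEBYE
    return DipoleRecord(
        index=index,
        components=Vec3.from_array(dip, "debye"),
        origin=center_of_mass(group),
    )


# ---------------------------------------------------------------------------
# helix geometry


def _axis_seed(points: np.ndarray) -> np.ndarray:
    """Initial axis estimate: mean consecutive displacement.

    The tangential in-plane parts of a helix's consecutive displacements
    cancel over whole turns, leaving the axial rise; this is robust where
    principal-component analysis of the raw cloud is not (for short helices
    the radial variance can exceed the axial variance).
    """
    mean_step = np.diff(points, axis=0).mean(axis=0)
    norm = np.linalg.norm(mean_step)
    if norm < 1e-12:
        raise DegenerateFitError("zero net displacement: points do not advance along an axis")
    return mean_step / norm


def fit_helix_params(origins: Union[np.ndarray, Sequence]) -> HelixParams:
    """Fit pitch, radius and axis of a discrete helix to ordered points.

    The axis is seeded from the mean consecutive displacement and refined by
    least-squares cylinder fitting (minimizing the spread of point-to-axis
    distances).  Radius is the mean axial distance; the per-point rise and
    azimuthal step give pitch = rise_per_point * points_per_turn.
    """
    pts = np.asarray(
        [p.as_array() if isinstance(p, Vec3) else p for p in origins], dtype=float
    )
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidInputError(f"origins must be (n, 3), got {pts.shape}")
    if len(pts) < 4:
        raise DegenerateFitError(f"helix fit needs at least 4 points, got {len(pts)}")

    centered = pts - pts.mean(axis=0)
    # collinearity check: rank of the centered cloud
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise DegenerateFitError("origins are collinear; no unique helix axis")

    def _radial_spread(ang: np.ndarray) -> np.ndarray:
        theta, phi = ang
        a = np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        radial = centered - np.outer(centered @ a, a)
        dist = np.linalg.norm(radial, axis=1)
        return dist - dist.mean()

    # two seeds: mean consecutive displacement (right for many-turn helices)
    # and the smallest principal component (right for flat, few-turn clouds);
    # keep whichever refined axis leaves the smaller radial spread
    _, pc = np.linalg.eigh(centered.T @ centered)
    best = None
    for seed_axis in (_axis_seed(pts), pc[:, 0]):
        theta0 = float(np.arccos(np.clip(seed_axis[2], -1.0, 1.0)))
        phi0 = float(np.arctan2(seed_axis[1], seed_axis[0]))
        sol = least_squares(_radial_spread, x0=[theta0, phi0], method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    theta, phi = best.x
    axis = np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    if axis @ _axis_seed(pts) < 0:  # keep axis pointing along traversal
        axis = -axis

    axial = centered @ axis
    radial = centered - np.outer(axial, axis)
    radii = np.linalg.norm(radial, axis=1)
    radius = float(radii.mean())
    if radius < 1e-9:
        raise DegenerateFitError("origins lie on the axis; radius is zero")

    # azimuth in a fixed frame perpendicular to the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ axis) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    angles = np.unwrap(np.arctan2(radial @ v, radial @ u))

    rises = np.diff(axial)
    steps = np.diff(angles)
    rise_per_point = float(rises.mean())
    mean_step = float(steps.mean())
    if abs(rise_per_point) < 1e-6 * max(radius, 1.0):
        raise DegenerateFitError("zero rise per point: points are planar (pitch ~ 0)")
    if abs(mean_step) < 1e-12:
        raise DegenerateFitError("zero azimuthal step: points do not wind about the axis")
    points_per_turn = float(2 * np.pi / abs(mean_step))
    pitch = abs(rise_per_point) * points_per_turn

    return HelixParams(
        pitch=pitch,
        radius=radius,
        axis_direction=Vec3.from_array(axis),
        n_points=len(pts),
        rise_per_point=rise_per_point,
        points_per_turn=points_per_turn,
        radius_rms_residual=float(np.sqrt(np.mean((radii - radius) ** 2))),
        rise_std=float(rises.std()),
        azimuthal_step_std_deg=float(np.degrees(steps.std())),
    )


def order_groups_along_helix(groups: Sequence[MoleculeGroup]) -> list[MoleculeGroup]:
    """Order molecules along the physical helix of their centers of mass.

    Traversal starts at the molecule with the lowest axial coordinate and
    proceeds by ascending azimuthal angle about the fitted axis (measured
    from the starting molecule).  The chirality sum's sign depends on this
    order, so it is part of the method's contract, not cosmetics.
    """
    if len(groups) < 2:
        return list(groups)
    coms = np.array([center_of_mass(g).as_array() for g in groups])
    centered = coms - coms.mean(axis=0)
    # The helix axis of one coil is the normal of the best-fit plane of the
    # centers of mass (smallest principal component): the molecules spread
    # around the axis much more than they rise along it.  This estimate is
    # independent of the (unknown) input order.
    _, vecs = np.linalg.eigh(centered.T @ centered)
    axis = vecs[:, 0]
    # deterministic orientation: largest-magnitude component positive
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    axial = centered @ axis
    radial = centered - np.outer(axial, axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ axis) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    azimuth = np.arctan2(radial @ v, radial @ u)
    start = int(np.argmin(axial))
    relative = np.mod(azimuth - azimuth[start], 2 * np.pi)
    order = sorted(range(len(groups)), key=lambda i: (relative[i], axial[i]))
    return [groups[i] for i in order]
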