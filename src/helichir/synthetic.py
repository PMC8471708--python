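"""Synthetic test objects: dipole rosettes, C-alpha helices, molecular coils.

Everything here is seed-deterministic (identical spec + seed gives
bit-identical output) so that property tests and fixtures need no external
data.  The rosette generator emulates the dipole arrangement of one turn of
a diphenylalanine-like nanotube: each successive molecule's dipole is
rotated by 360/n degrees in the XOY plane with a fixed axial component,
and the dipole origins (centers of mass) lie on a helix.

Handedness convention: "right" labels the arrangement whose chirality sum
is positive in the convention of the dipole measure — for a rosette with a
negative axial dipole component (the published L-FF pattern) this means the
dipole azimuth *decreases* by 360/n per molecule; "left" is its exact
mirror.  For C-alpha helices "right" is the ordinary right-handed screw
(azimuth increasing counterclockwise, viewed from +z, as z rises), which
makes the backbone sum positive.  Both conventions are asserted by tests,
not assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .core import CalphaTrace, CoilDipoleSet, DipoleRecord, Vec3
from .errors import InvalidInputError

__all__ = [
    "RosetteSpec",
    "HelixSpec",
    "make_dipole_rosette",
    "make_calpha_helix",
    "make_molecular_coil",
    "write_calpha_pdb",
    "write_coil_pdb",
    "mirror",
    "random_rotation",
    "rotate",
]

PlaneName = Literal["xy", "xz", "yz"]
_PLANE_AXIS = {"xy": 2, "xz": 1, "yz": 0}


@dataclass(frozen=True)
class RosetteSpec:
    """Parameters of an ideal (optionally noisy) dipole rosette.

    Defaults mirror the published one-coil nanotube geometry: 6 molecules
    per turn (60 degree steps), in-plane dipole magnitude ~19 Debye with
    axial component ~-12 Debye, origins on a helix of radius 8.15 Angstrom
    and pitch 5.456 Angstrom.
    """

    n: int = 6
    in_plane_magnitude: float = 19.0
    z_component: float = -12.0
    handedness: Literal["right", "left"] = "right"
    turns: int = 1
    radius: float = 8.15
    rise_per_turn: float = 5.456
    step_angle: Optional[float] = None  # degrees; default 360/n
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise InvalidInputError(f"a rosette needs n >= 3 molecules per turn, got {self.n}")
        if self.turns < 1:
            raise InvalidInputError(f"turns must be >= 1, got {self.turns}")
        if self.in_plane_magnitude <= 0:
            raise InvalidInputError("in_plane_magnitude must be positive")
        if self.radius <= 0 or self.rise_per_turn <= 0:
            raise InvalidInputError("radius and rise_per_turn must be positive")
        if self.noise_sigma < 0:
            raise InvalidInputError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class HelixSpec:
    """Parameters of an ideal (optionally noisy) C-alpha helix.

    Defaults approximate an alpha-helix: radius 2.3 Angstrom, rise 1.5
    Angstrom per residue, 3.6 residues per turn.
    """

    n_residues: int = 10
    radius: float = 2.3
    rise_per_residue: float = 1.5
    residues_per_turn: float = 3.6
    handedness: Literal["right", "left"] = "right"
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise InvalidInputError(
                f"a helix trace needs at least 4 residues, got {self.n_residues}"
            )
        if min(self.radius, self.rise_per_residue, self.residues_per_turn) <= 0:
            raise InvalidInputError("all geometric fields must be positive")
        if self.noise_sigma < 0:
            raise InvalidInputError("noise_sigma must be non-negative")


def make_dipole_rosette(spec: RosetteSpec) -> CoilDipoleSet:
    """Generate the ideal rosette coil described by ``spec``.

    Dipole i (0-based) has in-plane azimuth ``i * step * s`` with
    ``s = -1`` for right-handed and ``+1`` for left-handed arrangements,
    plus the fixed axial component; its origin sits on the corresponding
    helix of centers of mass.  Gaussian noise of ``noise_sigma`` is added
    per component when requested.
    """
    rng = np.random.default_rng(spec.seed)
    step = np.deg2rad(spec.step_angle if spec.step_angle is not None else 360.0 / spec.n)
    s = -1.0 if spec.handedness == "right" else 1.0
    total = spec.n * spec.turns
    rise = spec.rise_per_turn / spec.n

    records = []
    for i in range(total):
        az = s * step * i
        comp = np.array(
            [
                spec.in_plane_magnitude * np.cos(az),
                spec.in_plane_magnitude * np.sin(az),
                spec.z_component,
            ]
        )
        origin = np.array(
            [spec.radius * np.cos(az), spec.radius * np.sin(az), rise * i]
        )
        if spec.noise_sigma > 0:
            comp = comp + rng.normal(0.0, spec.noise_sigma, 3)
            origin = origin + rng.normal(0.0, spec.noise_sigma, 3)
        records.append(
            DipoleRecord(
                index=i + 1,
                components=Vec3.from_array(comp, "debye"),
                origin=Vec3.from_array(origin, "angstrom"),
            )
        )
    return CoilDipoleSet(
        records=records,
        method_tag=f"synthetic-rosette seed={spec.seed}",
        label=f"rosette-{spec.handedness}",
    )


def make_calpha_helix(spec: HelixSpec) -> CalphaTrace:
    """Generate an ideal circular C-alpha helix trace."""
    rng = np.random.default_rng(spec.seed)
    s = 1.0 if spec.handedness == "right" else -1.0
    i = np.arange(spec.n_residues)
    theta = s * 2 * np.pi / spec.residues_per_turn * i
    pts = np.column_stack(
        [
            spec.radius * np.cos(theta),
            spec.radius * np.sin(theta),
            spec.rise_per_residue * i,
        ]
    )
    if spec.noise_sigma > 0:
        pts = pts + rng.normal(0.0, spec.noise_sigma, pts.shape)
    return CalphaTrace(coordinates=pts, chain_id="A", residue_numbers=list(range(1, spec.n_residues + 1)))


def write_calpha_pdb(trace: CalphaTrace, path: Union[str, Path]) -> Path:
    """Serialize a C-alpha trace as a minimal valid PDB (GLY CA-only chain)."""
    st = gemmi.Structure()
    st.name = "synthetic-calpha-helix"
    model = gemmi.Model("1")
    chain = gemmi.Chain(trace.chain_id or "A")
    for resnum, pos in zip(trace.residue_numbers, trace.coordinates):
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(int(resnum), " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*pos)
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path


_COIL_ELEMENTS = ("C", "N", "O", "H")


def make_molecular_coil(
    n_molecules: int = 6,
    atoms_per_molecule: int = 43,
    radius: float = 8.15,
    rise_per_turn: float = 5.456,
    molecule_extent: float = 1.4,
    seed: int = 0,
    with_charges: bool = False,
) -> list:
    """Generate a supramolecular coil of blob-like molecules.

    Each molecule is a compact random cluster of ``atoms_per_molecule``
    atoms (C/N/O/H) around a center of mass placed on a helix; one chain
    per molecule.  With ``with_charges`` each molecule carries random
    partial charges summing exactly to zero (net-neutral, so point-charge
    dipoles are reference-independent).  Purely geometric scaffolding: no
    attempt at realistic chemistry.
    """
    from .structure import Atom  # local import to avoid a cycle at module load

    if n_molecules < 1 or atoms_per_molecule < 1:
        raise InvalidInputError("n_molecules and atoms_per_molecule must be >= 1")
    rng = np.random.default_rng(seed)
    chains = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    atoms = []
    for m in range(n_molecules):
        az = 2 * np.pi * m / n_molecules
        center = np.array(
            [radius * np.cos(az), radius * np.sin(az), rise_per_turn * m / n_molecules]
        )
        offsets = rng.uniform(-molecule_extent, molecule_extent, (atoms_per_molecule, 3))
        charges = None
        if with_charges:
            charges = rng.uniform(-0.5, 0.5, atoms_per_molecule)
            charges -= charges.mean()  # exact neutrality
        for j in range(atoms_per_molecule):
            el = _COIL_ELEMENTS[j % len(_COIL_ELEMENTS)]
            atoms.append(
                Atom(
                    element=el,
                    position=center + offsets[j],
                    atom_name=f"{el}{j + 1}",
                    residue_number=1,
                    chain_id=chains[m % len(chains)],
                    charge=None if charges is None else float(charges[j]),
                )
            )
    return atoms


def write_coil_pdb(atoms: Sequence, path: Union[str, Path]) -> Path:
    """Serialize a molecular coil (one chain per molecule) as PDB."""
    st = gemmi.Structure()
    st.name = "synthetic-molecular-coil"
    model = gemmi.Model("1")
    by_chain: dict[str, list] = {}
    order: list[str] = []
    for a in atoms:
        if a.chain_id not in by_chain:
            by_chain[a.chain_id] = []
            order.append(a.chain_id)
        by_chain[a.chain_id].append(a)
    for cid in order:
        chain = gemmi.Chain(cid)
        res = gemmi.Residue()
        res.name = "UNK"
        res.seqid = gemmi.SeqId(1, " ")
        for a in by_chain[cid]:
            atom = gemmi.Atom()
            atom.name = a.atom_name[:4]
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.position)
            res.add_atom(atom)
        chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path


def write_coil_pqr(atoms: Sequence, path: Union[str, Path]) -> Path:
    """Serialize a charged coil as PQR (whitespace-separated, charge+radius)."""
    from .errors import MissingChargeError

    lines = []
    for serial, a in enumerate(atoms, start=1):
        if a.charge is None:
            raise MissingChargeError(f"atom {a.atom_name} has no charge to write")
        x, y, z = a.position
        lines.append(
            f"ATOM {serial} {a.atom_name} UNK {a.chain_id} {a.residue_number} "
            f"{x:.4f} {y:.4f} {z:.4f} {a.charge:.6f} 1.5000"
        )
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# parity and rotation operators


def _mirror_vec3(v: Vec3, axis: int) -> Vec3:
    comps = [v.x, v.y, v.z]
    comps[axis] = -comps[axis]
    return Vec3(comps[0], comps[1], comps[2], v.unit)


def mirror(obj, plane: PlaneName = "xy"):
    """Reflect through a coordinate plane (negate the orthogonal component).

    Accepts a Vec3, an (n, 3) array, a CoilDipoleSet (components and
    origins reflected) or a CalphaTrace; returns the same type.  An
    involution: applying it twice is the identity.
    """
    if plane not in _PLANE_AXIS:
        raise InvalidInputError(f"unknown mirror plane {plane!r}")
    axis = _PLANE_AXIS[plane]
    if isinstance(obj, Vec3):
        return _mirror_vec3(obj, axis)
    if isinstance(obj, CoilDipoleSet):
        records = [
            replace(
                r,
                components=_mirror_vec3(r.components, axis),
                magnitude=None,
                origin=None if r.origin is None else _mirror_vec3(r.origin, axis),
            )
            for r in obj.records
        ]
        return CoilDipoleSet(
            records=records, method_tag=obj.method_tag, label=f"{obj.label}|mirror-{plane}"
        )
    if isinstance(obj, CalphaTrace):
        pts = obj.coordinates.copy()
        pts[:, axis] = -pts[:, axis]
        return CalphaTrace(
            coordinates=pts,
            chain_id=obj.chain_id,
            residue_numbers=list(obj.residue_numbers),
        )
    arr = np.asarray(obj, dtype=float).copy()
    if arr.ndim == 1:
        arr[axis] = -arr[axis]
    else:
        arr[:, axis] = -arr[:, axis]
    return arr


def random_rotation(seed: int = 0) -> np.ndarray:
    """A uniformly random proper rotation matrix (det +1), reproducible by seed."""
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


def rotate(obj, matrix: np.ndarray):
    """Apply a 3x3 rotation to a Vec3, array, CoilDipoleSet or CalphaTrace."""
    R = np.asarray(matrix, dtype=float)
    if R.shape != (3, 3):
        raise InvalidInputError(f"rotation matrix must be 3x3, got {R.shape}")
    if isinstance(obj, Vec3):
        return Vec3.from_array(R @ obj.as_array(), obj.unit)
    if isinstance(obj, CoilDipoleSet):
        records = [
            replace(
                r,
                components=Vec3.from_array(R @ r.components.as_array(), "debye"),
                magnitude=None,
                origin=None
                if r.origin is None
                else Vec3.from_array(R @ r.origin.as_array(), "angstrom"),
            )
            for r in obj.records
        ]
        return CoilDipoleSet(records=records, method_tag=obj.method_tag, label=obj.label)
    if isinstance(obj, CalphaTrace):
        return CalphaTrace(
            coordinates=obj.coordinates @ R.T,
            chain_id=obj.chain_id,
            residue_numbers=list(obj.residue_numbers),
        )
    arr = np.asarray(obj, dtype=float)
    return arr @ R.T
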