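"""Chirality mathematics for helical and helix-like structures.

The central quantity is the scalar triple product ([a, b], c) — the
determinant of the 3x3 matrix with rows a, b, c.  It is a pseudoscalar:
invariant under proper rotations, sign-flipping under mirror reflection,
which makes it a natural detector of handedness.

Two chirality sums are provided:

* backbone mode — for a polypeptide helix with n residues, build the n-1
  difference vectors between consecutive C-alpha positions and sum the
  triple products of all n-3 consecutive vector triples (``chi_total``);
* dipole mode — for a helix-like supramolecular assembly (e.g. one turn of
  a diphenylalanine peptide nanotube, 6 molecules), take the per-molecule
  dipole-moment vectors in helix traversal order and sum the triple
  products of the n-2 consecutive triples (``c_total``).

A positive sum means a right-handed twist, a negative one left-handed.
Dipole-mode results are normalized by the cube of the mean dipole
magnitude, giving the dimensionless, method-independent measure
``c_norm = c_total / D_av**3``.

Ordering is a semantic input: the caller supplies vectors in traversal
order along the helix, and reversing that order flips the sign.  Nothing
here ever re-sorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import (
    DegenerateNormalizationError,
    InsufficientVectorsError,
    InvalidInputError,
    UnitMismatchError,
)

Unit = Literal["debye", "angstrom", "dimensionless"]
Handedness = Literal["right", "left", "indeterminate"]

__all__ = [
    "Vec3",
    "DipoleRecord",
    "CoilDipoleSet",
    "CalphaTrace",
    "ChiralityResult",
    "CoilSummary",
    "triple_product",
    "chi_total_backbone",
    "dipole_magnitude",
    "c_total_dipoles",
    "d_av",
    "c_norm",
    "coil_summary",
    "classify_handedness",
    "full_dipole_analysis",
]


@dataclass(frozen=True)
class Vec3:
    """A Cartesian 3-vector with a unit tag (debye, angstrom or dimensionless)."""

    x: float
    y: float
    z: float
    unit: Unit = "dimensionless"

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise InvalidInputError(
                f"Vec3 components must be finite, got ({self.x}, {self.y}, {self.z})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[float], unit: Unit = "dimensionless") -> "Vec3":
        x, y, z = (float(v) for v in a)
        return cls(x, y, z, unit)

    def norm(self) -> float:
        return float(np.linalg.norm(self.as_array()))


def _coerce(v, expected_unit: Optional[str]) -> tuple[np.ndarray, Optional[str]]:
    """Return (array, unit) for a Vec3 or bare 3-sequence, enforcing unit agreement."""
    if isinstance(v, Vec3):
        if expected_unit is not None and v.unit != expected_unit:
            raise UnitMismatchError(
                f"cannot mix units '{expected_unit}' and '{v.unit}' in one computation"
            )
        return v.as_array(), v.unit
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise InvalidInputError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InvalidInputError(f"vector components must be finite, got {a}")
    return a, expected_unit


def triple_product(a, b, c) -> float:
    """Scalar triple product ([a, b], c): det of the 3x3 matrix with rows a, b, c.

    Accepts :class:`Vec3` (units must agree) or bare 3-sequences.  The result
    carries units of unit**3.  Computed by cofactor expansion, exactly:

        (y1 z2 - y2 z1) x3 + (z1 x2 - z2 x1) y3 + (x1 y2 - x2 y1) z3
    """
    av, unit = _coerce(a, None)
    bv, unit = _coerce(b, unit)
    cv, unit = _coerce(c, unit)
    return float(
        (av[1] * bv[2] - bv[1] * av[2]) * cv[0]
        + (av[2] * bv[0] - bv[2] * av[0]) * cv[1]
        + (av[0] * bv[1] - bv[0] * av[1]) * cv[2]
    )


def dipole_magnitude(components) -> float:
    """Euclidean norm of a dipole vector, in Debye."""
    a, _ = _coerce(components, None)
    return float(np.linalg.norm(a))


@dataclass(frozen=True)
class DipoleRecord:
    """One molecule's dipole moment along the coil.

    ``index`` is the molecule's 1-based position in helix traversal order.
    ``origin`` is the molecule's center of mass (Angstrom), when known —
    it anchors the vector in space but does not enter the chirality sum.
    """

    index: int
    components: Vec3
    magnitude: Optional[float] = None
    origin: Optional[Vec3] = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise InvalidInputError(f"dipole index must be >= 1, got {self.index}")
        if self.components.unit != "debye":
            raise UnitMismatchError(
                f"dipole components must be in debye, got '{self.components.unit}'"
            )
        if self.origin is not None and self.origin.unit != "angstrom":
            raise UnitMismatchError(
                f"dipole origin must be in angstrom, got '{self.origin.unit}'"
            )
        norm = self.components.norm()
        if self.magnitude is None:
            object.__setattr__(self, "magnitude", norm)
        else:
            if self.magnitude < 0:
                raise InvalidInputError("dipole magnitude must be non-negative")
            if not math.isclose(self.magnitude, norm, rel_tol=1e-9, abs_tol=1e-12):
                raise InvalidInputError(
                    f"magnitude {self.magnitude} inconsistent with component norm {norm}"
                )


@dataclass
class CoilDipoleSet:
    """The ordered dipoles of one helical turn ('coil').

    Order is the traversal order along the helix and is preserved exactly as
    given; it determines the sign of the chirality sum.  ``method_tag``
    records how the dipoles were obtained (e.g. "PM3-RHF", "Amber",
    "point-charge"), ``label`` names the structure (e.g. "L-FF").
    """

    records: list[DipoleRecord]
    method_tag: str = ""
    label: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise InsufficientVectorsError("a dipole set needs at least 1 record")
        indices = [r.index for r in self.records]
        if indices != list(range(1, len(self.records) + 1)):
            raise InvalidInputError(
                f"dipole indices must be consecutive starting at 1, got {indices}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def component_matrix(self) -> np.ndarray:
        """(n, 3) array of dipole components in traversal order, Debye."""
        return np.array([r.components.as_array() for r in self.records])

    def magnitudes(self) -> np.ndarray:
        return np.array([r.magnitude for r in self.records])

    def origins(self) -> Optional[np.ndarray]:
        """(n, 3) array of dipole origins in Angstrom, or None if any is missing."""
        if any(r.origin is None for r in self.records):
            return None
        return np.array([r.origin.as_array() for r in self.records])


@dataclass
class CalphaTrace:
    """Ordered C-alpha coordinates of one chain, in Angstrom."""

    coordinates: np.ndarray
    chain_id: str = ""
    residue_numbers: Optional[list[int]] = None

    def __post_init__(self) -> None:
        pts = np.asarray(
            [p.as_array() if isinstance(p, Vec3) else p for p in self.coordinates],
            dtype=float,
        )
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InvalidInputError(f"coordinates must be (n, 3), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("coordinates must be finite")
        if len(pts) >= 2 and np.any(np.all(np.diff(pts, axis=0) == 0.0, axis=1)):
            raise InvalidInputError("consecutive C-alpha coordinates must be distinct")
        self.coordinates = pts
        if self.residue_numbers is None:
            self.residue_numbers = list(range(1, len(pts) + 1))
        elif len(self.residue_numbers) != len(pts):
            raise InvalidInputError("residue_numbers length must match coordinates")

    def __len__(self) -> int:
        return len(self.coordinates)

    def difference_vectors(self) -> np.ndarray:
        """The n-1 vectors between consecutive C-alpha positions."""
        return np.diff(self.coordinates, axis=0)


@dataclass(frozen=True)
class ChiralityResult:
    """Outcome of a chirality computation.

    ``c_total`` is in Debye^3 (dipole mode) or Angstrom^3 (backbone mode);
    ``d_av`` and ``c_norm`` are present only in dipole mode.
    """

    c_total: float
    n_vectors: int
    n_terms: int
    handedness: Handedness
    symbol: Literal["D", "L", "none"]
    mode: Literal["dipole", "backbone"]
    d_av: Optional[float] = None
    c_norm: Optional[float] = None

    def to_dict(self) -> dict:
        """Full-precision JSON-ready mapping; rounding is the caller's job."""
        return {
            "c_total": self.c_total,
            "d_av": self.d_av,
            "c_norm": self.c_norm,
            "n_vectors": self.n_vectors,
            "n_terms": self.n_terms,
            "handedness": self.handedness,
            "symbol": self.symbol,
            "mode": self.mode,
        }


@dataclass(frozen=True)
class CoilSummary:
    """Aggregates over one coil: total dipole and average magnitudes."""

    d_coil_vector: Vec3
    d_coil_magnitude: float
    d_av: float
    d_component_means: Vec3

    def to_dict(self) -> dict:
        return {
            "d_coil_vector": list(self.d_coil_vector.as_array()),
            "d_coil_magnitude": self.d_coil_magnitude,
            "d_av": self.d_av,
            "d_component_means": list(self.d_component_means.as_array()),
        }


def classify_handedness(c_value: float) -> tuple[Handedness, str]:
    """Map the sign of a chirality sum to (handedness, D/L symbol).

    Positive -> right-handed -> D; negative -> left-handed -> L; exactly
    zero -> indeterminate (the sign convention is undefined at zero).
    """
    if not math.isfinite(c_value):
        raise InvalidInputError(f"chirality value must be finite, got {c_value}")
    if c_value > 0:
        return "right", "D"
    if c_value < 0:
        return "left", "L"
    return "indeterminate", "none"


def _consecutive_triple_sum(vectors: np.ndarray) -> float:
    """Sum of triple products over consecutive vector triples, no wrap-around."""
    return sum(
        triple_product(vectors[i], vectors[i + 1], vectors[i + 2])
        for i in range(len(vectors) - 2)
    )


def chi_total_backbone(trace: CalphaTrace) -> ChiralityResult:
    """Backbone chirality sum chi_total over C-alpha difference vectors.

    With n residues there are n-1 difference vectors v_i and n-3 triples
    (v_i, v_{i+1}, v_{i+2}); chi_total is their triple-product sum, in
    Angstrom^3.  Requires n >= 4.
    """
    n = len(trace)
    if n < 4:
        raise InsufficientVectorsError(
            f"backbone chirality needs at least 4 C-alpha points, got {n}"
        )
    vectors = trace.difference_vectors()
    total = _consecutive_triple_sum(vectors)
    handedness, symbol = classify_handedness(total)
    return ChiralityResult(
        c_total=total,
        n_vectors=len(vectors),
        n_terms=n - 3,
        handedness=handedness,
        symbol=symbol,
        mode="backbone",
    )


def c_total_dipoles(coil: CoilDipoleSet) -> float:
    """Dipole chirality sum: triple products of the n-2 consecutive dipole
    triples in traversal order, Debye^3.  No wrap-around term."""
    if len(coil) < 3:
        raise InsufficientVectorsError(
            f"dipole chirality needs at least 3 dipoles, got {len(coil)}"
        )
    return _consecutive_triple_sum(coil.component_matrix())


def d_av(coil: CoilDipoleSet) -> float:
    """Arithmetic mean of the per-molecule dipole magnitudes, Debye.

    This is the mean of the |D_i|, not the magnitude of the mean vector.
    """
    if len(coil) == 0:
        raise InsufficientVectorsError("cannot average an empty coil")
    return float(np.mean(coil.magnitudes()))


def c_norm(c_total: float, d_av_value: float) -> float:
    """Dimensionless normalized chirality c_total / d_av**3."""
    if not math.isfinite(c_total) or not math.isfinite(d_av_value):
        raise InvalidInputError("c_norm inputs must be finite")
    if d_av_value <= 0:
        raise DegenerateNormalizationError(
            f"mean dipole magnitude must be positive, got {d_av_value}"
        )
    return c_total / d_av_value**3


def coil_summary(coil: CoilDipoleSet) -> CoilSummary:
    """Componentwise sum (D_coil), its magnitude, mean magnitude (D_av) and
    componentwise means for one coil."""
    if len(coil) == 0:
        raise InsufficientVectorsError("cannot summarize an empty coil")
    comps = coil.component_matrix()
    total = comps.sum(axis=0)
    return CoilSummary(
        d_coil_vector=Vec3.from_array(total, "debye"),
        d_coil_magnitude=float(np.linalg.norm(total)),
        d_av=d_av(coil),
        d_component_means=Vec3.from_array(total / len(coil), "debye"),
    )


def full_dipole_analysis(coil: CoilDipoleSet) -> ChiralityResult:
    """Complete dipole-mode analysis: c_total, D_av, c_norm and handedness."""
    total = c_total_dipoles(coil)
    mean_mag = d_av(coil)
    normalized = c_norm(total, mean_mag)
    handedness, symbol = classify_handedness(total)
    return ChiralityResult(
        c_total=total,
        n_vectors=len(coil),
        n_terms=len(coil) - 2,
        handedness=handedness,
        symbol=symbol,
        mode="dipole",
        d_av=mean_mag,
        c_norm=normalized,
    )
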