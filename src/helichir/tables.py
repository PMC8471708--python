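"""Per-molecule dipole tables: TSV dialect, bundled reference fixtures.

Dialect: tab-separated; '#'-prefixed metadata lines (``# label=L-FF``,
``# method=PM3-RHF``); one header row; columns ``i  Dx  Dy  Dz`` with
optional ``Di`` and origin columns ``ox  oy  oz``.  Dipole components are
in Debye, origins in Angstrom.  A Unicode minus (U+2212) is accepted on
input and normalized; output always uses the ASCII hyphen.

The ``Di`` magnitude column is advisory: published tables print rounded
values, so magnitudes are always recomputed from the components, and a
disagreement beyond printed-rounding tolerance (0.002 Debye) attaches a
warning rather than silently altering the input.

Bundled fixtures hold the published PM3 (restricted Hartree-Fock) and
Amber dipole moments for one coil (6 molecules) of the L-FF and D-FF
diphenylalanine peptide nanotubes, plus the individual-molecule dipoles.
"""

from __future__ import annotations

import io
import warnings
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import CoilDipoleSet, DipoleRecord, Vec3
from .errors import TableFormatError

__all__ = [
    "read_dipole_table",
    "write_dipole_table",
    "list_fixtures",
    "fixture_path",
    "load_fixture",
    "MAGNITUDE_TOLERANCE",
]

#: printed-rounding tolerance for the advisory Di column, Debye
MAGNITUDE_TOLERANCE = 0.002

_REQUIRED_COLUMNS = ("i", "Dx", "Dy", "Dz")
_ORIGIN_COLUMNS = ("ox", "oy", "oz")

FIXTURE_NAMES = (
    "lff_pm3",
    "lff_amber",
    "dff_pm3",
    "dff_amber",
    "lff_molecule_pm3",
    "dff_molecule_pm3",
)


def _normalize_text(text: str) -> str:
    # U+2212 (minus sign) appears in published tables; U+00AD guards against
    # soft hyphens introduced by text extraction.
    return text.replace("−", "-").replace("­", "")


def read_dipole_table(path: Union[str, Path]) -> CoilDipoleSet:
    """Read a dipole TSV into a :class:`CoilDipoleSet`.

    Magnitudes are recomputed from components; an advisory ``Di`` column
    that disagrees beyond :data:`MAGNITUDE_TOLERANCE` attaches a warning to
    the returned set (and emits a ``UserWarning``) without altering input.
    """
    path = Path(path)
    text = _normalize_text(path.read_text(encoding="utf-8"))

    metadata: dict[str, str] = {}
    body_lines: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                metadata[key.strip()] = value.strip()
        elif line.strip():
            body_lines.append(line)
    if not body_lines:
        raise TableFormatError(f"{path}: no table body found")

    try:
        frame = pd.read_csv(
            io.StringIO("\n".join(body_lines)), sep="\t", float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:
        raise TableFormatError(f"{path}: {exc}") from exc

    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")

    numeric_cols = [
        c for c in frame.columns if c in _REQUIRED_COLUMNS + ("Di",) + _ORIGIN_COLUMNS
    ]
    for col in numeric_cols:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[converted.isna() & frame[col].notna()]
        if len(bad):
            row = int(bad[0]) + 2  # 1-based, after the header row
            raise TableFormatError(
                f"{path}: non-numeric value {frame[col][bad[0]]!r} "
                f"in column '{col}', row {row}"
            )
        if converted.isna().any():
            row = int(frame.index[converted.isna()][0]) + 2
            raise TableFormatError(f"{path}: empty cell in column '{col}', row {row}")
        frame[col] = converted

    indices = frame["i"].astype(int).tolist()
    if len(set(indices)) != len(indices):
        dupes = sorted({i for i in indices if indices.count(i) > 1})
        raise TableFormatError(f"{path}: duplicate molecule index(es) {dupes}")

    has_origin = all(c in frame.columns for c in _ORIGIN_COLUMNS)
    table_warnings: list[str] = []
    records = []
    for _, row in frame.iterrows():
        components = Vec3(float(row["Dx"]), float(row["Dy"]), float(row["Dz"]), "debye")
        if "Di" in frame.columns:
            stated = float(row["Di"])
            recomputed = components.norm()
            if abs(stated - recomputed) > MAGNITUDE_TOLERANCE:
                msg = (
                    f"row i={int(row['i'])}: stated magnitude {stated} differs from "
                    f"component norm {recomputed:.3f} by more than "
                    f"{MAGNITUDE_TOLERANCE} Debye; using the recomputed value"
                )
                table_warnings.append(msg)
                warnings.warn(f"{path.name}: {msg}", stacklevel=2)
        origin = None
        if has_origin:
            origin = Vec3(float(row["ox"]), float(row["oy"]), float(row["oz"]), "angstrom")
        records.append(DipoleRecord(index=int(row["i"]), components=components, origin=origin))

    return CoilDipoleSet(
        records=records,
        method_tag=metadata.get("method", ""),
        label=metadata.get("label", ""),
        warnings=table_warnings,
    )


def write_dipole_table(coil: CoilDipoleSet, path: Union[str, Path]) -> Path:
    """Write a coil as dipole TSV; reading it back reproduces the coil exactly.

    Numbers are serialized with Python's shortest round-trip ``repr``, so the
    read-back floats are bit-identical.
    """
    path = Path(path)
    has_origin = coil.origins() is not None
    lines = []
    if coil.label:
        lines.append(f"# label={coil.label}")
    if coil.method_tag:
        lines.append(f"# method={coil.method_tag}")
    header = ["i", "Dx", "Dy", "Dz", "Di"]
    if has_origin:
        header += list(_ORIGIN_COLUMNS)
    lines.append("\t".join(header))
    for rec in coil.records:
        cells = [
            str(rec.index),
            repr(rec.components.x),
            repr(rec.components.y),
            repr(rec.components.z),
            repr(rec.magnitude),
        ]
        if has_origin:
            cells += [repr(rec.origin.x), repr(rec.origin.y), repr(rec.origin.z)]
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def list_fixtures() -> tuple[str, ...]:
    """Names of the bundled published dipole tables."""
    return FIXTURE_NAMES


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled fixture (without the .tsv suffix)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return Path(resources.files("helichir") / "fixtures" / f"{name}.tsv")


def load_fixture(name: str) -> CoilDipoleSet:
    """Load one of the bundled published dipole tables by name."""
    return read_dipole_table(fixture_path(name))
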