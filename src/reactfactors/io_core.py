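"""Readers and writers for the plain-text formats the pipeline consumes.

Formats:

* **Extended XYZ** — standard XYZ with an optional trailing ``F`` token per
  atom line marking that atom as frozen (the cluster-model convention of
  keeping peripheral capping atoms fixed).
* **Hessian** — header line ``natoms N units hartree_bohr2`` followed by the
  3N x 3N symmetric matrix, whitespace separated, row-major.
* **Tables** — CSV/TSV with unit-tagged column names (``E_el_hartree``,
  ``G_kcal``, ``NiS_dist_angstrom`` ...); on load every numeric quantity is
  converted to the internal conventions (kcal/mol, eV -> kcal/mol, e, Å,
  cm^-1) and the applied units are recorded in the table metadata.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import HARTREE_TO_KCAL, EV_TO_KCAL, mass_of


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


class SchemaError(ValueError):
    """A table is missing required columns or carries unknown unit tags."""


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

@dataclass
class Structure:
    """A molecular (cluster) geometry with optional frozen-atom flags.

    Attributes
    ----------
    symbols : element symbols, length n
    masses : atomic masses in amu, length n
    coords : Cartesian coordinates in Å, shape (n, 3)
    frozen : boolean frozen flag per atom (frozen atoms are excluded from the
        vibrational problem by Hessian projection)
    label : free-text description
    """

    symbols: list[str]
    masses: np.ndarray
    coords: np.ndarray
    frozen: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.frozen = np.asarray(self.frozen, dtype=bool)
        n = len(self.symbols)
        if not (len(self.masses) == len(self.coords) == len(self.frozen) == n):
            raise ValueError("inconsistent per-atom array lengths")
        if np.any(self.masses <= 0):
            raise ValueError("atomic masses must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.n_frozen >= n:
            raise ValueError("at least one atom must be unfrozen")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def n_frozen(self) -> int:
        return int(self.frozen.sum())

    @property
    def free_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.frozen)


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path, label: str | None = None) -> Structure:
    """Read an (extended) XYZ file.

    A trailing ``F`` token on an atom line marks the atom frozen. Masses are
    filled from the built-in isotope-averaged table.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ParseError(f"{path}: line 1: malformed atom-count line") from None
    comment = lines[1].strip() if len(lines) > 1 else ""
    symbols, coords, frozen = [], [], []
    for i in range(n):
        lineno = i + 3
        if 2 + i >= len(lines):
            raise ParseError(f"{path}: line {lineno}: expected atom line "
                             f"({n} declared, {i} found)")
        tokens = lines[2 + i].split()
        if len(tokens) < 4:
            raise ParseError(f"{path}: line {lineno}: expected 'El x y z [F]'")
        sym = tokens[0].capitalize() if len(tokens[0]) > 1 else tokens[0].upper()
        try:
            mass = mass_of(sym)
        except KeyError:
            raise ParseError(
                f"{path}: line {lineno}: unknown element symbol {tokens[0]!r}"
            ) from None
        try:
            xyz = [float(t) for t in tokens[1:4]]
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: non-numeric coordinate"
            ) from None
        symbols.append(sym)
        coords.append(xyz)
        frozen.append(len(tokens) > 4 and tokens[4].upper() == "F")
        _ = mass
    masses = np.array([mass_of(s) for s in symbols])
    return Structure(symbols, masses, np.array(coords), np.array(frozen),
                     label=label if label is not None else comment)


def write_xyz(structure: Structure, path: str | Path) -> None:
    out = [str(structure.n_atoms), structure.label]
    for sym, (x, y, z), fz in zip(structure.symbols, structure.coords,
                                  structure.frozen):
        flag = " F" if fz else ""
        out.append(f"{sym:<3s} {x:18.10f} {y:18.10f} {z:18.10f}{flag}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Hessian
# ---------------------------------------------------------------------------

def read_hessian(path: str | Path, structure: Structure) -> np.ndarray:
    """Read the plain-text Cartesian Hessian (hartree/bohr^2).

    The matrix is symmetrized on load. Asymmetry above 1e-6 before
    symmetrization triggers a warning; above 1e-3, an error.
    """
    text = Path(path).read_text().split("\n", 1)
    header = text[0].split()
    if len(header) != 4 or header[0] != "natoms" or header[2] != "units":
        raise ParseError(f"{path}: line 1: expected 'natoms N units hartree_bohr2'")
    if header[3] != "hartree_bohr2":
        raise ParseError(f"{path}: unsupported Hessian units {header[3]!r}")
    n = int(header[1])
    if n != structure.n_atoms:
        raise ParseError(
            f"{path}: header natoms {n} != structure atom count "
            f"{structure.n_atoms}")
    values = np.fromstring(text[1] if len(text) > 1 else "", sep=" ")
    dim = 3 * n
    if values.size != dim * dim:
        raise ParseError(
            f"{path}: expected {dim * dim} matrix elements for 3N={dim}, "
            f"found {values.size}")
    h = values.reshape(dim, dim)
    asym = np.max(np.abs(h - h.T)) if dim else 0.0
    if asym > 1e-3:
        raise ParseError(f"{path}: Hessian asymmetry {asym:.2e} exceeds 1e-3")
    if asym > 1e-6:
        warnings.warn(f"{path}: Hessian asymmetry {asym:.2e} > 1e-6; "
                      "symmetrizing", stacklevel=2)
    return 0.5 * (h + h.T)


def write_hessian(hessian: np.ndarray, path: str | Path) -> None:
    n3 = hessian.shape[0]
    if hessian.shape != (n3, n3) or n3 % 3:
        raise ValueError("Hessian must be square with dimension 3N")
    buf = io.StringIO()
    buf.write(f"natoms {n3 // 3} units hartree_bohr2\n")
    np.savetxt(buf, hessian, fmt="%.12e")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

#: unit-tag suffix -> (canonical suffix, factor to internal unit)
_UNIT_TAGS: dict[str, tuple[str, float]] = {
    "hartree": ("kcal", HARTREE_TO_KCAL),
    "ev": ("kcal", EV_TO_KCAL),
    "kcal": ("kcal", 1.0),
    "kj": ("kcal", 1.0 / 4.184),
    "cm1": ("cm1", 1.0),
    "e": ("e", 1.0),
    "angstrom": ("angstrom", 1.0),
    "volt": ("volt", 1.0),
    "kelvin": ("kelvin", 1.0),
    "bar": ("bar", 1.0),
}

#: schema name -> canonical columns required after unit coercion
_SCHEMAS: dict[str, list[str]] = {
    "ledger": ["species", "E_el_kcal"],
    "charges": ["atom"],
    "orbitals": ["model", "orbital", "p_C_pct", "p_S_pct"],
    "bonds": ["model", "NiS_dist_angstrom", "NiN_dist_angstrom"],
    "modes": ["frequency_cm1"],
}


@dataclass
class TabularFile:
    """A validated table with explicit per-column units."""

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)
    schema: str = ""

    def __post_init__(self) -> None:
        for col in self.data.columns:
            self.units.setdefault(col, _infer_unit(col))


def _infer_unit(column: str) -> str:
    tail = column.rsplit("_", 1)[-1].lower()
    if tail in _UNIT_TAGS:
        return _UNIT_TAGS[tail][0]
    if tail == "pct":
        return "percent"
    return "none"


def _coerce_units(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, str]]:
    """Convert unit-tagged numeric columns to internal units, renaming them."""
    units: dict[str, str] = {}
    renames: dict[str, str] = {}
    for col in df.columns:
        parts = col.rsplit("_", 1)
        tail = parts[-1].lower()
        if len(parts) == 2 and tail in _UNIT_TAGS:
            canonical, factor = _UNIT_TAGS[tail]
            new = f"{parts[0]}_{canonical}"
            if not pd.api.types.is_numeric_dtype(df[col]):
                try:
                    df[col] = pd.to_numeric(df[col])
                except (ValueError, TypeError):
                    raise SchemaError(
                        f"column {col!r} carries unit tag {tail!r} but is "
                        "not numeric") from None
            if factor != 1.0:
                df[col] = df[col] * factor
            renames[col] = new
            units[new] = canonical
        else:
            units[col] = _infer_unit(col)
    return df.rename(columns=renames), units


def read_table(path: str | Path, schema: str) -> TabularFile:
    """Read and validate a delimited table against a named schema.

    Delimiter (comma/tab) is autodetected. Unit-tagged columns are converted
    to internal conventions; missing required columns raise ``SchemaError``.
    """
    if schema not in _SCHEMAS:
        raise SchemaError(
            f"unknown schema {schema!r}; choose from {sorted(_SCHEMAS)}")
    df = pd.read_csv(path, sep=None, engine="python")
    df, units = _coerce_units(df)
    missing = [c for c in _SCHEMAS[schema] if c not in df.columns
               and not _schema_column_present(schema, c, df)]
    if missing:
        raise SchemaError(
            f"{path}: schema {schema!r} missing required column(s): "
            + ", ".join(missing))
    if schema == "charges":
        probe_cols = [c for c in df.columns if c.startswith("qP_")]
        if not probe_cols:
            raise SchemaError(f"{path}: charges schema needs qP_<value> columns")
        for c in probe_cols:
            units[c] = "e"
    bad = [c for c, u in units.items()
           if u == "none" and pd.api.types.is_float_dtype(df[c])
           and any(k in c.lower() for k in ("energy", "_g", "g_", "deltag"))]
    if bad:
        raise SchemaError(
            f"{path}: energy-like column(s) without unit tag: {', '.join(bad)}")
    return TabularFile(df, units, schema)


def _schema_column_present(schema: str, required: str, df: pd.DataFrame) -> bool:
    # `label` is accepted as an alias for `species`/`model` key columns
    if required in ("species", "model", "atom"):
        return "label" in df.columns
    return False


def write_table(table: TabularFile | pd.DataFrame, path: str | Path) -> None:
    df = table.data if isinstance(table, TabularFile) else table
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False)


__all__ = [
    "Structure", "TabularFile", "ParseError", "SchemaError",
    "read_xyz", "write_xyz", "read_hessian", "write_hessian",
    "read_table", "write_table",
]
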