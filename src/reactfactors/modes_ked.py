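"""Normal-mode analysis with frozen-atom projection and kinetic-energy
distribution (KED).

The KED of atom *i* in normal mode α is the fraction of the mode's kinetic
energy carried by that atom,

    KED_iα = m_i |r_iα|^2 / Σ_k m_k |r_kα|^2 ,

where r_iα is atom *i*'s Cartesian displacement 3-vector within the mode and
m_i its mass. The statistic is scale invariant in the displacement vector,
lies in [0, 1] and sums to 1 over atoms within each mode. For transition
states, the KED of the single imaginary-frequency ("reactive") mode summed
over a fragment (e.g. the nascent CH3 radical) quantifies how ballistically
that fragment departs.

Cluster models that keep peripheral capping atoms fixed are handled by
orthogonal projection of the Cartesian Hessian onto the unfrozen subspace:
with f frozen atoms the vibrational problem has 3n − 3f degrees of freedom
(minima), or 3n − 3f with exactly one imaginary mode for transition states —
the 3n−24 / 3n−25 counting of an 8-frozen-atom cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import WAVENUMBER_FACTOR
from .io_core import Structure

#: modes with |wavenumber| below this (cm^-1) are treated as the numerical
#: nullspace of the projector and dropped
ZERO_MODE_CUTOFF_CM1 = 1.0

#: modes closer in frequency than this (cm^-1) are flagged degenerate: the
#: eigenvector (hence KED) is not unique within the degenerate subspace
DEGENERACY_CUTOFF_CM1 = 0.01


class ModeError(ValueError):
    pass


@dataclass
class Fragment:
    """A named set of atoms (0-based indices) within a structure."""

    name: str
    indices: list[int]

    def __post_init__(self) -> None:
        idx = list(self.indices)
        if len(set(idx)) != len(idx):
            raise ValueError(f"fragment {self.name!r}: duplicate atom indices")
        if idx and min(idx) < 0:
            raise ValueError(f"fragment {self.name!r}: negative atom index")
        self.indices = idx


@dataclass
class ModeSet:
    """Vibrational modes of a structure.

    Attributes
    ----------
    frequencies : wavenumbers in cm^-1, ascending; imaginary modes stored as
        negative values
    displacements : Cartesian displacement vectors, shape (n_modes, 3n)
        (mass-weighted-normalized convention; KED is scale invariant)
    ked : per-atom kinetic-energy fractions, shape (n_atoms, n_modes); filled
        by :func:`compute_ked`
    structure : the geometry the modes belong to
    degenerate : flag per mode marking near-degenerate frequencies
    """

    frequencies: np.ndarray
    displacements: np.ndarray
    structure: Structure
    ked: np.ndarray | None = None
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 2 or (
                self.displacements.shape[1] != 3 * self.structure.n_atoms):
            raise ValueError("displacements must have shape (n_modes, 3n)")
        if len(self.frequencies) != len(self.displacements):
            raise ValueError("frequency/displacement count mismatch")
        if self.degenerate is None:
            f = self.frequencies
            deg = np.zeros(len(f), dtype=bool)
            if len(f) > 1:
                close = np.abs(np.diff(f)) < DEGENERACY_CUTOFF_CM1
                deg[:-1] |= close
                deg[1:] |= close
            self.degenerate = deg

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)

    @property
    def is_imaginary(self) -> np.ndarray:
        """Boolean per mode; imaginary frequencies are stored negative."""
        return self.frequencies < 0.0

    @property
    def n_imaginary(self) -> int:
        return int(self.is_imaginary.sum())

    @property
    def dof_counts(self) -> tuple[int, int, int]:
        """(n_atoms, n_frozen, n_modes)."""
        return (self.structure.n_atoms, self.structure.n_frozen, self.n_modes)

    def real_frequencies(self) -> np.ndarray:
        return self.frequencies[~self.is_imaginary]

    def imaginary_mode_index(self) -> int:
        """Index of the single imaginary (reactive) mode."""
        idx = np.flatnonzero(self.is_imaginary)
        if len(idx) != 1:
            raise ModeError(
                f"expected exactly one imaginary mode, found {len(idx)}")
        return int(idx[0])


# ---------------------------------------------------------------------------
# Hessian projection
# ---------------------------------------------------------------------------

def project_frozen(hessian: np.ndarray, structure: Structure) -> np.ndarray:
    """Project the Cartesian Hessian onto the unfrozen-atom subspace.

    Rows and columns belonging to frozen-atom coordinates are zeroed; the
    result has at least 3f zero eigenvalues and frozen atoms carry exactly
    zero displacement in every retained mode.
    """
    n = structure.n_atoms
    if hessian.shape != (3 * n, 3 * n):
        raise ValueError(f"Hessian shape {hessian.shape} != (3n, 3n) for n={n}")
    if structure.n_frozen == 0:
        return hessian
    mask = np.repeat(~structure.frozen, 3).astype(float)
    return hessian * mask[:, None] * mask[None, :]


def trans_rot_projector(structure: Structure) -> np.ndarray:
    """Orthogonal projector removing rigid translations and rotations.

    Built in the mass-weighted basis from the 3 translation and up-to-3
    rotation vectors about the center of mass (linear molecules contribute
    only 2 rotations; rank deficiency is handled automatically).
    """
    n = structure.n_atoms
    m = structure.masses
    sqrt_m = np.sqrt(np.repeat(m, 3))
    com = (m[:, None] * structure.coords).sum(0) / m.sum()
    x = structure.coords - com
    vecs = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        vecs.append(t.ravel() * sqrt_m)
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        r = np.cross(x, e)  # displacement of each atom under rotation about e
        vecs.append(r.ravel() * sqrt_m)
    basis = np.array(vecs).T
    q, r = np.linalg.qr(basis)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return np.eye(3 * n) - q @ q.T


# ---------------------------------------------------------------------------
# Normal modes
# ---------------------------------------------------------------------------

def normal_modes(hessian: np.ndarray, structure: Structure, *,
                 project_trans_rot: bool = False,
                 zero_cutoff: float = ZERO_MODE_CUTOFF_CM1,
                 expect_transition_state: bool = False) -> ModeSet:
    """Diagonalize the mass-weighted Hessian and build a :class:`ModeSet`.

    Parameters
    ----------
    hessian : Cartesian Hessian in hartree/bohr^2 (already frozen-projected
        if the structure has frozen atoms — :func:`project_frozen` is applied
        here as well, which is idempotent)
    project_trans_rot : remove rigid-body translations/rotations first; OFF
        by default because frozen-framework clusters have no global motion
    zero_cutoff : |wavenumber| below which modes are discarded (cm^-1)
    expect_transition_state : if set, require exactly one imaginary mode

    Modes are sorted ascending by (signed) wavenumber, so a reactive mode
    comes first. Displacements are stored mass-weighted-normalized and
    un-mass-weighted to Cartesian for the KED (which is scale invariant).
    """
    n = structure.n_atoms
    h = project_frozen(hessian, structure)
    sqrt_m = np.sqrt(np.repeat(structure.masses, 3))
    h_mw = h / sqrt_m[:, None] / sqrt_m[None, :]
    if project_trans_rot:
        if structure.n_frozen:
            warnings.warn("trans/rot projection requested for a frozen-"
                          "framework cluster; global motion is already "
                          "removed by freezing", stacklevel=2)
        p = trans_rot_projector(structure)
        h_mw = p @ h_mw @ p
    h_mw = 0.5 * (h_mw + h_mw.T)
    # diagonalize only the free-coordinate block: the 3f frozen coordinates
    # are exact nulls of the projected matrix and never become modes
    free_cols = np.flatnonzero(np.repeat(~structure.frozen, 3))
    evals, evecs_free = np.linalg.eigh(h_mw[np.ix_(free_cols, free_cols)])
    if not np.all(np.isfinite(evals)):
        raise ModeError("non-finite eigenvalues in mass-weighted Hessian")
    wavenumbers = np.sign(evals) * WAVENUMBER_FACTOR * np.sqrt(np.abs(evals))
    keep = np.abs(wavenumbers) >= zero_cutoff
    wavenumbers = wavenumbers[keep]
    order = np.argsort(wavenumbers)
    wavenumbers = wavenumbers[order]
    vecs = np.zeros((3 * n, len(wavenumbers)))
    vecs[free_cols] = evecs_free[:, keep][:, order]
    disp = (vecs / sqrt_m[:, None]).T  # exactly zero on frozen coordinates
    modes = ModeSet(wavenumbers, disp, structure)
    if expect_transition_state and modes.n_imaginary != 1:
        raise ModeError(
            f"transition-state check failed: {modes.n_imaginary} imaginary "
            "modes (expected 1, the 3n-3f-1 real-mode convention)")
    return compute_ked(modes, structure)


# ---------------------------------------------------------------------------
# KED
# ---------------------------------------------------------------------------

def compute_ked(modes: ModeSet, structure: Structure | None = None) -> ModeSet:
    """Fill the (atoms x modes) KED matrix of a :class:`ModeSet`.

    KED_iα = m_i|r_iα|^2 / Σ_k m_k|r_kα|^2; each column sums to one.
    """
    structure = structure or modes.structure
    n = structure.n_atoms
    r2 = modes.displacements.reshape(modes.n_modes, n, 3)
    per_atom = structure.masses[None, :] * np.sum(r2 * r2, axis=2)  # modes x atoms
    totals = per_atom.sum(axis=1)
    if np.any(totals <= 0):
        bad = int(np.argmax(totals <= 0))
        raise ModeError(f"mode {bad} has zero total displacement")
    modes.ked = (per_atom / totals[:, None]).T
    return modes


def fragment_ked(modes: ModeSet, fragment: Fragment, mode_index: int) -> float:
    """Summed KED of a fragment within one mode (in [0, 1]).

    By convention the mode of interest for transition-state analysis is the
    single imaginary (reactive) mode; use
    ``modes.imaginary_mode_index()`` to locate it.
    """
    if not fragment.indices:
        raise ValueError("empty fragment")
    if modes.ked is None:
        compute_ked(modes)
    n = modes.structure.n_atoms
    if max(fragment.indices) >= n:
        raise ValueError(
            f"fragment {fragment.name!r} indexes atom "
            f"{max(fragment.indices)} but structure has {n}")
    if not -modes.n_modes <= mode_index < modes.n_modes:
        raise IndexError(f"mode index {mode_index} out of range")
    if modes.degenerate[mode_index]:
        warnings.warn(
            f"mode {mode_index} is degenerate; KED is not unique within the "
            "degenerate subspace", stacklevel=2)
    return float(modes.ked[fragment.indices, mode_index].sum())


def atom_kinetic_energies(modes: ModeSet,
                          mode_energies: np.ndarray) -> np.ndarray:
    """Aggregate per-atom kinetic energies ⟨T_i⟩ = Σ_α KED_iα ⟨T_α⟩.

    ``mode_energies`` are user-supplied per-mode kinetic energies ⟨T_α⟩ (no
    thermal-population model is assumed); typically only the reactive mode's
    KED is analysed and this aggregation is not needed.
    """
    if modes.ked is None:
        compute_ked(modes)
    t = np.asarray(mode_energies, dtype=float)
    if t.shape != (modes.n_modes,):
        raise ValueError("mode_energies must have one entry per mode")
    return modes.ked @ t


__all__ = [
    "Fragment", "ModeSet", "ModeError",
    "project_frozen", "trans_rot_projector", "normal_modes",
    "compute_ked", "fragment_ked", "atom_kinetic_energies",
    "ZERO_MODE_CUTOFF_CM1", "DEGENERACY_CUTOFF_CM1",
]
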