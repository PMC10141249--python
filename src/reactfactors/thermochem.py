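"""RRHO thermochemistry and redox potentials.

Gibbs free energies are assembled as

    G = E_el + E_ZPVE + (pV − RT ln Q),

with the zero-point vibrational energy E_ZPVE = Σ_k hc ν̃_k / 2 over real
modes and Q the rigid-rotor/harmonic-oscillator molecular partition function.
Two regimes are supported:

* ``free-molecule`` — translational, rotational and vibrational partition
  functions (ideal gas at the stated T and p, Sackur–Tetrode translations,
  classical rigid rotor);
* ``frozen-cluster`` — only the projected vibrational degrees of freedom
  enter Q (a cluster embedded in a fixed framework has no global
  translation/rotation). The pV term is retained as RT by default for
  consistency across regimes and can be set to zero.

Reduction potentials follow the absolute-potential convention

    E° = (G_ox − G_red)/F − E°_abs(reference),

with G in eV per particle (so F cancels) and the normal hydrogen electrode
at 4.28 eV as the default reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (CM1_TO_KCAL, EV_TO_KCAL, H_J, KB_J, NA,
                        NHE_ABSOLUTE_EV, R_J, R_KCAL, C_CM)
from .io_core import Structure
from .modes_ked import ModeSet

REGIMES = ("free-molecule", "frozen-cluster")

_J_PER_MOL_TO_KCAL = 1.0 / (4.184 * 1000.0)


@dataclass
class LedgerRow:
    """One species in a free-energy ledger (all energies kcal/mol)."""

    label: str
    E_el: float
    E_zpve: float
    thermal: float  # pV - RT ln Q
    T: float
    p: float
    regime: str
    G: float = field(init=False)

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        self.G = self.E_el + self.E_zpve + self.thermal


class FreeEnergyLedger:
    """Per-species Gibbs free-energy bookkeeping.

    Rows satisfy G = E_el + E_ZPVE + thermal identically; lookups are by
    species label.
    """

    def __init__(self, rows: list[LedgerRow] | None = None):
        self._rows: dict[str, LedgerRow] = {}
        for row in rows or []:
            self.add(row)

    def add(self, row: LedgerRow) -> None:
        self._rows[row.label] = row

    def __contains__(self, label: str) -> bool:
        return label in self._rows

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self):
        return iter(self._rows.values())

    def g(self, label: str) -> float:
        try:
            return self._rows[label].G
        except KeyError:
            raise KeyError(
                f"ledger has no species {label!r}; present: "
                + ", ".join(sorted(self._rows))) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"species": r.label, "E_el_kcal": r.E_el,
              "E_zpve_kcal": r.E_zpve, "thermal_kcal": r.thermal,
              "G_kcal": r.G, "T_kelvin": r.T, "p_bar": r.p,
              "regime": r.regime} for r in self._rows.values()])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FreeEnergyLedger":
        ledger = cls()
        label_col = "species" if "species" in df.columns else "label"
        for _, r in df.iterrows():
            ledger.add(LedgerRow(
                label=str(r[label_col]), E_el=float(r["E_el_kcal"]),
                E_zpve=float(r.get("E_zpve_kcal", 0.0)),
                thermal=float(r.get("thermal_kcal", 0.0)),
                T=float(r.get("T_kelvin", 298.0)),
                p=float(r.get("p_bar", 1.0)),
                regime=str(r.get("regime", "frozen-cluster"))))
        return ledger


# ---------------------------------------------------------------------------
# RRHO pieces
# ---------------------------------------------------------------------------

def zpve(modes: ModeSet) -> float:
    """Zero-point vibrational energy Σ hc ν̃ / 2 over real modes (kcal/mol)."""
    return float(0.5 * CM1_TO_KCAL * modes.real_frequencies().sum())


def _vibrational_terms(wavenumbers: np.ndarray, T: float) -> tuple[float, float]:
    """(thermal internal energy, entropy) of harmonic oscillators.

    Energy excludes the ZPVE (referenced to the vibrational ground state).
    Returns (kcal/mol, J mol^-1 K^-1).
    """
    if len(wavenumbers) == 0:
        return 0.0, 0.0
    theta = H_J * C_CM * wavenumbers / KB_J  # vibrational temperatures, K
    x = theta / T
    with np.errstate(over="ignore"):  # x >> 1: terms correctly underflow to 0
        expm1 = np.expm1(x)
        u = R_J * np.sum(theta / expm1)  # J/mol
        s = R_J * np.sum(x / expm1 - np.log1p(-np.exp(-x)))
    return u * _J_PER_MOL_TO_KCAL, float(s)


def translational_entropy(mass_amu: float, T: float, p_bar: float) -> float:
    """Sackur–Tetrode entropy of an ideal gas (J mol^-1 K^-1)."""
    m = mass_amu * 1e-3 / NA  # kg per molecule
    p = p_bar * 1e5
    q_over_n = (2.0 * np.pi * m * KB_J * T / H_J**2) ** 1.5 * KB_J * T / p
    return R_J * (np.log(q_over_n) + 2.5)


def _rotational_terms(structure: Structure, T: float,
                      sigma: float = 1.0) -> tuple[float, float]:
    """(thermal internal energy kcal/mol, entropy J mol^-1 K^-1) of a
    classical rigid rotor; handles linear molecules and single atoms."""
    x = structure.coords * 1e-10
    m = structure.masses * 1e-3 / NA
    com = (m[:, None] * x).sum(0) / m.sum()
    x = x - com
    inertia = np.zeros((3, 3))
    for mi, xi in zip(m, x):
        inertia += mi * (np.dot(xi, xi) * np.eye(3) - np.outer(xi, xi))
    moments = np.sort(np.linalg.eigvalsh(inertia))
    tiny = 1e-46  # kg m^2; below this a principal moment is treated as zero
    if moments[-1] < tiny:  # single atom: no rotation
        return 0.0, 0.0
    if moments[0] < tiny:  # linear
        i_b = moments[-1]
        q_rot = 8.0 * np.pi**2 * i_b * KB_J * T / (sigma * H_J**2)
        u = R_J * T
        s = R_J * (np.log(q_rot) + 1.0)
    else:
        q_rot = (np.sqrt(np.pi) / sigma) * (
            8.0 * np.pi**2 * KB_J * T / H_J**2) ** 1.5 * np.sqrt(
            moments[0] * moments[1] * moments[2])
        u = 1.5 * R_J * T
        s = R_J * (np.log(q_rot) + 1.5)
    return u * _J_PER_MOL_TO_KCAL, float(s)


def thermal_correction(modes: ModeSet, structure: Structure, T: float = 298.0,
                       p: float = 1.0, regime: str = "frozen-cluster", *,
                       sigma: float = 1.0,
                       include_pv: bool = True) -> float:
    """The pV − RT ln Q term of the Gibbs assembly (kcal/mol).

    Computed as H_thermal − T·S with H_thermal = U_thermal + pV; the
    vibrational part is referenced to the vibrational ground state (the ZPVE
    is carried separately by :func:`zpve`). In the ``frozen-cluster`` regime
    only the projected vibrational degrees of freedom contribute to Q;
    ``include_pv=False`` drops the RT pV term there.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}")
    u_vib, s_vib = _vibrational_terms(modes.real_frequencies(), T)
    u = u_vib
    s = s_vib
    pv = R_KCAL * T if include_pv else 0.0
    if regime == "free-molecule":
        u += 1.5 * R_J * T * _J_PER_MOL_TO_KCAL
        s += translational_entropy(float(structure.masses.sum()), T, p)
        u_rot, s_rot = _rotational_terms(structure, T, sigma)
        u += u_rot
        s += s_rot
        pv = R_KCAL * T
    return u + pv - T * s * _J_PER_MOL_TO_KCAL


def gibbs(E_el: float, modes: ModeSet, structure: Structure, *,
          label: str = "", T: float = 298.0, p: float = 1.0,
          regime: str = "frozen-cluster", sigma: float = 1.0,
          include_pv: bool = True) -> LedgerRow:
    """Assemble a ledger row G = E_el + E_ZPVE + (pV − RT ln Q)."""
    e_zpve = zpve(modes)
    thermal = thermal_correction(modes, structure, T, p, regime,
                                 sigma=sigma, include_pv=include_pv)
    return LedgerRow(label=label, E_el=E_el, E_zpve=e_zpve, thermal=thermal,
                     T=T, p=p, regime=regime)


# ---------------------------------------------------------------------------
# Redox potentials
# ---------------------------------------------------------------------------

@dataclass
class RedoxCouple:
    """An oxidized/reduced pair with free energies in eV per particle."""

    G_ox: float
    G_red: float
    reference: float = NHE_ABSOLUTE_EV
    label: str = ""

    def __post_init__(self) -> None:
        if self.reference <= 0:
            raise ValueError("absolute reference potential must be positive")


def redox_potential(couple: RedoxCouple) -> float:
    """Reduction potential E° = (G_ox − G_red) − E°_abs(reference), in V."""
    return (couple.G_ox - couple.G_red) - couple.reference


def et_free_energy(e_donor: float, e_acceptor: float) -> float:
    """Free energy (kcal/mol) of single-electron transfer donor → acceptor.

    ΔG_ET = −F·(E°_acceptor − E°_donor); potentials in V.
    """
    return -EV_TO_KCAL * (e_acceptor - e_donor)


__all__ = [
    "FreeEnergyLedger", "LedgerRow", "RedoxCouple", "REGIMES",
    "zpve", "thermal_correction", "translational_entropy", "gibbs",
    "redox_potential", "et_free_energy",
]
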