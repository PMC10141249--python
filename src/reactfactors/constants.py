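"""Physical constants and unit conversions.

Internal conventions used throughout the package:

* energies in kcal/mol,
* electrode potentials in V (free energies entering them in eV per particle),
* charges in elementary charge e,
* distances in Å,
* wavenumbers in cm^-1,
* Hessians on disk in hartree/bohr^2 with masses in amu.

The conversion factors below are pinned so that numbers do not drift between
modules; everything that converts units imports from here.
"""

from __future__ import annotations

import math

# -- pinned conversions (internal convention) --------------------------------
HARTREE_TO_KCAL = 627.5095          # kcal/mol per hartree
EV_TO_KCAL = 23.0605                # kcal/mol per eV
CM1_TO_KCAL = 2.85914e-3            # kcal/mol per cm^-1 (h c / N_A)
COULOMB_KCAL = 332.0637             # kcal mol^-1 Å e^-2 point-charge constant

# -- thermodynamics ----------------------------------------------------------
R_KCAL = 1.98720425864083e-3        # gas constant, kcal mol^-1 K^-1
R_J = 8.31446261815324              # gas constant, J mol^-1 K^-1
KB_J = 1.380649e-23                 # Boltzmann, J/K
H_J = 6.62607015e-34                # Planck, J s
NA = 6.02214076e23                  # Avogadro
C_CM = 2.99792458e10                # speed of light, cm/s

# Default absolute potential of the normal hydrogen electrode (eV).
NHE_ABSOLUTE_EV = 4.28

# -- CODATA atomic units used for the Hessian eigenvalue -> cm^-1 map --------
_HARTREE_J = 4.3597447222071e-18
_BOHR_M = 0.529177210903e-10
_AMU_KG = 1.66053906660e-27
BOHR_TO_ANGSTROM = _BOHR_M * 1e10

#: cm^-1 per sqrt(hartree / (bohr^2 amu)); multiply by sqrt(|eigenvalue|)
#: of the mass-weighted Hessian to obtain the harmonic wavenumber.
WAVENUMBER_FACTOR = math.sqrt(_HARTREE_J / (_AMU_KG * _BOHR_M**2)) / (
    2.0 * math.pi * C_CM
)

# Isotope-averaged standard atomic weights (amu) for elements that occur in
# cluster models of Ni-corphinoid active sites and in common test molecules.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.002602,
    "Li": 6.94, "Be": 9.0121831, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998403163, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815385, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.0983, "Ca": 40.078, "Sc": 44.955908, "Ti": 47.867,
    "V": 50.9415, "Cr": 51.9961, "Mn": 54.938044, "Fe": 55.845,
    "Co": 58.933194, "Ni": 58.6934, "Cu": 63.546, "Zn": 65.38,
    "Ga": 69.723, "Ge": 72.630, "As": 74.921595, "Se": 78.971,
    "Br": 79.904, "Kr": 83.798,
    "Rb": 85.4678, "Sr": 87.62, "Mo": 95.95, "Ru": 101.07,
    "Rh": 102.90550, "Pd": 106.42, "Ag": 107.8682, "Cd": 112.414,
    "Sn": 118.710, "I": 126.90447, "Xe": 131.293,
    "Cs": 132.90545196, "Ba": 137.327, "W": 183.84, "Re": 186.207,
    "Os": 190.23, "Ir": 192.217, "Pt": 195.084, "Au": 196.966569,
    "Hg": 200.592, "Pb": 207.2,
}


def mass_of(symbol: str) -> float:
    """Standard atomic weight (amu) for an element symbol.

    Raises ``KeyError`` with a helpful message for unknown symbols.
    """
    try:
        return ATOMIC_MASSES[symbol]
    except KeyError:
        raise KeyError(
            f"unknown element symbol {symbol!r}; known: "
            + ", ".join(sorted(ATOMIC_MASSES))
        ) from None
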