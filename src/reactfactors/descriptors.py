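"""Scalar reactivity descriptors and cross-model trend fits.

* ``f_ch3`` — the carbon-vs-sulfur asymmetry of the σ*(S–CH3) acceptor
  orbital, F_CH3 = p_C% / (p_C% + p_S%): the larger the carbon share, the
  more the reactive mode's kinetic energy concentrates on the departing
  methyl group.
* ``coulomb_differential`` — point-charge estimate of the difference in
  metal–ligand electrostatic stabilization between two models from AIM-type
  atomic charges and Ni–N distances.
* ``trend_fit`` — OLS + Pearson r for cross-model structural trends
  (Ni–N vs Ni–S distances, delocalization indices, KED vs F_CH3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import COULOMB_KCAL


@dataclass
class OrbitalComposition:
    """Percent atomic-orbital contributions to one molecular orbital.

    Percentages need not sum to 100 (projection remainder is allowed).
    """

    orbital: str
    p_C: float
    p_S: float
    model: str = ""

    def __post_init__(self) -> None:
        for name, v in (("p_C", self.p_C), ("p_S", self.p_S)):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a percentage in [0, 100]")


@dataclass
class BondDescriptorRow:
    """Per-model bond/charge descriptors (inputs, never computed here)."""

    model: str
    ni_s_dist: float        # Å
    ni_n_dist: float        # mean of the four Ni-N bonds, Å
    q_ni: float = 0.0       # e
    q_n: float = 0.0        # mean ligating-N charge, e
    di_ni_s: float = 0.0    # delocalization index
    di_ni_n: float = 0.0
    bond_order_ni_s: float = 0.0

    def __post_init__(self) -> None:
        if self.ni_s_dist <= 0 or self.ni_n_dist <= 0:
            raise ValueError("bond distances must be positive")
        if self.di_ni_s < 0 or self.di_ni_n < 0:
            raise ValueError("delocalization indices are non-negative")


def f_ch3(comp: OrbitalComposition) -> float:
    """F_CH3 = p_C / (p_C + p_S), in [0, 1]."""
    total = comp.p_C + comp.p_S
    if total <= 0:
        raise ValueError("p_C + p_S must be positive")
    return comp.p_C / total


def coulomb_differential(row_a: BondDescriptorRow, row_b: BondDescriptorRow,
                         n_bonds: int = 4) -> float:
    """Difference in point-charge Ni–N interaction between two models.

    n_bonds · k · [q_Ni·q_N/r (model a) − q_Ni·q_N/r (model b)] in kcal/mol
    with k = 332.0637 kcal Å mol⁻¹ e⁻²; negative when model a's
    electrostatic attraction is the stronger one.
    """
    if n_bonds < 1:
        raise ValueError("n_bonds must be at least 1")
    term_a = row_a.q_ni * row_a.q_n / row_a.ni_n_dist
    term_b = row_b.q_ni * row_b.q_n / row_b.ni_n_dist
    return n_bonds * COULOMB_KCAL * (term_a - term_b)


def trend_fit(x, y) -> tuple[float, float, float]:
    """OLS line and Pearson correlation → (slope, intercept, r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-D series with >= 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in trend input")
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


__all__ = ["OrbitalComposition", "BondDescriptorRow", "f_ch3",
           "coulomb_differential", "trend_fit"]
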