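"""Ligand polarization from atomic-charge response to a central point charge.

The macrocyclic ligand's electron-donation responsiveness is probed by
replacing the metal with a point charge q_P (grid 0 → 1 e in 0.1 e steps by
default) and summing the atomic-charge shifts:

    P(q_P) = Σ_i |q_i(q_P) − q_i(0)| ,

so P(0) = 0 by construction. For a linearly responding ligand P is linear in
q_P; its slope m (e per e of probe charge) ranks ligands by responsiveness.
A sum-of-squares variant is available behind ``squared=True``; the atom
subset over which i runs is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import TabularFile


@dataclass
class ChargeResponse:
    """Atomic charges q_i(q_P) tabulated over a probe-charge grid.

    Attributes
    ----------
    grid : probe charges q_P (e), strictly increasing, starting at 0
    charges : (n_atoms, n_grid) matrix of atomic charges (e)
    model : label of the ligand/model the response belongs to
    """

    grid: np.ndarray
    charges: np.ndarray
    model: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.charges = np.atleast_2d(np.asarray(self.charges, dtype=float))
        if self.grid.ndim != 1 or len(self.grid) == 0:
            raise ValueError("grid must be a non-empty 1-D array")
        if self.grid[0] != 0.0:
            raise ValueError("probe grid must start at q_P = 0")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("probe grid must be strictly increasing")
        if self.charges.shape[1] != len(self.grid):
            raise ValueError("charges must have one column per grid point")
        if not np.all(np.isfinite(self.charges)):
            raise ValueError("charges must be finite")

    @property
    def n_atoms(self) -> int:
        return self.charges.shape[0]

    @classmethod
    def from_table(cls, table: TabularFile, model: str = "") -> "ChargeResponse":
        """Build from a wide `charges`-schema table with qP_<value> columns."""
        cols = [c for c in table.data.columns if c.startswith("qP_")]
        grid = np.array([float(c[3:]) for c in cols])
        order = np.argsort(grid)
        charges = table.data[[cols[i] for i in order]].to_numpy(dtype=float)
        return cls(grid[order], charges, model=model)


def polarization_curve(response: ChargeResponse, *,
                       atoms: list[int] | None = None,
                       squared: bool = False) -> np.ndarray:
    """P(q_P) over the probe grid; returns shape (n_grid, 2) of (q_P, P).

    ``atoms`` restricts the sum to a ligand subset (default: every atom).
    """
    q = response.charges if atoms is None else response.charges[atoms]
    if q.shape[0] == 0:
        raise ValueError("empty atom subset")
    delta = q - q[:, [0]]
    p = np.sum(delta**2, axis=0) if squared else np.sum(np.abs(delta), axis=0)
    return np.column_stack([response.grid, p])


def polarization_slope(curve: np.ndarray, *,
                       intercept_mode: str = "fixed-zero"
                       ) -> tuple[float, dict[str, float]]:
    """Fit m in P ≈ m·q_P by OLS and return (m, diagnostics).

    ``intercept_mode='fixed-zero'`` (default) regresses through the origin,
    consistent with P(0) = 0 by definition; ``'free'`` also fits an
    intercept. Diagnostics carry r², the maximum residual, and the
    alternative-intercept slope for comparison.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 2 or curve.shape[0] < 3:
        raise ValueError("curve must be (n>=3, 2) array of (q_P, P)")
    if intercept_mode not in ("fixed-zero", "free"):
        raise ValueError("intercept_mode must be 'fixed-zero' or 'free'")
    x, y = curve[:, 0], curve[:, 1]

    m0 = float(np.dot(x, y) / np.dot(x, x))  # through-origin OLS
    xc = x - x.mean()
    m1 = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
    b1 = float(y.mean() - m1 * x.mean())

    if intercept_mode == "fixed-zero":
        m, b, m_alt = m0, 0.0, m1
    else:
        m, b, m_alt = m1, b1, m0
    resid = y - (m * x + b)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return m, {"intercept": b, "r2": r2,
               "max_residual": float(np.max(np.abs(resid))),
               "slope_other_intercept_mode": m_alt}


__all__ = ["ChargeResponse", "polarization_curve", "polarization_slope"]
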