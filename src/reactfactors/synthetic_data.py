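"""Synthetic generators emulating the quantum-chemistry outputs the analysis
consumes, so every stage is testable without electronic-structure software.

The generators produce:

* harmonic linear-chain structures/Hessians with closed-form spectra
  (:func:`gen_coupled_oscillator`) and random symmetric Hessians
  (:func:`gen_random_hessian`),
* transition-state mode sets whose reactive-mode fragment KED is constructed
  to an exact target share (:func:`gen_ts_mode`),
* linear atomic-charge response tables with model-specific polarization
  slopes (:func:`gen_charge_response`; presets A…E span 1.34 → 1.02 e/e),
* a five-model free-energy ledger series whose step-1/step-3 thermodynamic
  cycles close exactly on specified legs, with late transition states so the
  barrier tracks the driving force (:func:`gen_model_series`).

The default series truths are synthetic: they reproduce the qualitative
orderings of a Ni-corphinoid maturation series (barriers B > A > C > D > E,
reduction potential rising and Ni–S bond strength growing toward the native
cofactor) but are not electronic-structure results.

Every generator takes a seed and is bit-reproducible; random streams are
per-generator and independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import EV_TO_KCAL, mass_of
from .cycles import StepEnergetics, ThermoCycle, build_step1_cycle
from .io_core import Structure
from .modes_ked import Fragment, ModeSet, compute_ked
from .polarization import ChargeResponse
from .thermochem import FreeEnergyLedger, LedgerRow

#: polarization-slope presets (e per e of probe charge), most responsive
#: early-precursor ligand "A" to least responsive native-like ligand "E"
POLARIZATION_PRESETS = {"A": 1.34, "B": 1.26, "C": 1.18, "D": 1.10, "E": 1.02}

DEFAULT_PROBE_GRID = np.round(np.arange(0.0, 1.05, 0.1), 10)


# ---------------------------------------------------------------------------
# Oscillator fixtures
# ---------------------------------------------------------------------------

def gen_coupled_oscillator(n_atoms: int, masses, springs,
                           frozen: list[int] | None = None,
                           seed: int | None = None,
                           ) -> tuple[Structure, np.ndarray]:
    """Linear chain of point masses coupled by nearest-neighbour springs.

    Springs (hartree/bohr^2) act along the chain axis (x), giving n_atoms−1
    longitudinal modes with closed-form frequencies for uniform chains; the
    transverse coordinates are flat (numerical zero modes). Atoms sit 1 Å
    apart on the x axis. Deterministic; ``seed`` is accepted for interface
    uniformity.
    """
    if n_atoms < 2:
        raise ValueError("need at least 2 atoms")
    masses = np.asarray(masses, dtype=float)
    springs = np.asarray(springs, dtype=float)
    if len(masses) != n_atoms or len(springs) != n_atoms - 1:
        raise ValueError(
            f"expected {n_atoms} masses and {n_atoms - 1} springs, got "
            f"{len(masses)} and {len(springs)}")
    if np.any(springs <= 0):
        raise ValueError("spring constants must be positive")
    frozen_flags = np.zeros(n_atoms, dtype=bool)
    if frozen:
        frozen_flags[list(frozen)] = True
    coords = np.zeros((n_atoms, 3))
    coords[:, 0] = np.arange(n_atoms, dtype=float)
    structure = Structure(["C"] * n_atoms, masses, coords, frozen_flags,
                          label=f"chain n={n_atoms}")
    h = np.zeros((3 * n_atoms, 3 * n_atoms))
    for j, k in enumerate(springs):
        a, b = 3 * j, 3 * (j + 1)  # x-coordinates of neighbours
        h[a, a] += k
        h[b, b] += k
        h[a, b] -= k
        h[b, a] -= k
    return structure, h


def gen_random_hessian(n_atoms: int, seed: int,
                       frozen: list[int] | None = None,
                       scale: float = 0.3,
                       ) -> tuple[Structure, np.ndarray]:
    """Random symmetric Hessian with random masses — a stress fixture.

    Eigenvalues of either sign are allowed (negative ones surface as
    imaginary modes); KED invariants must hold regardless.
    """
    rng = np.random.default_rng(seed)
    symbols = list(rng.choice(["H", "C", "N", "O", "S", "Ni"], n_atoms))
    masses = np.array([mass_of(sym) for sym in symbols])
    coords = rng.normal(scale=2.0, size=(n_atoms, 3))
    frozen_flags = np.zeros(n_atoms, dtype=bool)
    if frozen:
        frozen_flags[list(frozen)] = True
    structure = Structure(symbols, masses, coords, frozen_flags,
                          label=f"random n={n_atoms} seed={seed}")
    a = rng.normal(scale=scale, size=(3 * n_atoms, 3 * n_atoms))
    return structure, 0.5 * (a + a.T)


# ---------------------------------------------------------------------------
# Reactive-mode fixture
# ---------------------------------------------------------------------------

def gen_ts_mode(structure: Structure, fragment: Fragment,
                target_share: float, seed: int, *,
                imaginary_frequency: float = -450.0,
                n_real_modes: int | None = None) -> ModeSet:
    """A transition-state-like mode set with exact reactive-mode fragment KED.

    The imaginary mode's mass-weighted displacement is split between the
    fragment block (norm² = target_share) and its complement
    (norm² = 1 − target_share), which fixes the fragment KED exactly; random
    orthogonal real modes fill the remaining free-atom subspace.
    """
    if not 0.0 < target_share <= 1.0:
        raise ValueError("target_share must lie in (0, 1]")
    n = structure.n_atoms
    free = set(structure.free_indices.tolist())
    frag = set(fragment.indices)
    if not frag:
        raise ValueError("empty fragment")
    if not frag <= set(range(n)):
        raise ValueError("fragment indexes atoms outside the structure")
    if frag & set(np.flatnonzero(structure.frozen).tolist()):
        raise ValueError("fragment contains frozen atoms")
    complement = free - frag
    if not complement and target_share < 1.0:
        raise ValueError(
            "fragment covers all unfrozen atoms: KED sums to 1 there, so a "
            f"target share of {target_share} is infeasible")
    rng = np.random.default_rng(seed)
    sqrt_m = np.sqrt(np.repeat(structure.masses, 3))

    def block(indices: set[int], norm: float) -> np.ndarray:
        v = np.zeros(3 * n)
        if not indices or norm == 0.0:
            return v
        cols = np.concatenate([[3 * i, 3 * i + 1, 3 * i + 2]
                               for i in sorted(indices)])
        raw = rng.normal(size=len(cols))
        v[cols] = raw / np.linalg.norm(raw) * norm
        return v

    v_imag = block(frag, np.sqrt(target_share)) + \
        block(complement, np.sqrt(1.0 - target_share))

    n_free_dof = 3 * (n - structure.n_frozen)
    max_real = n_free_dof - 1
    n_real = max_real if n_real_modes is None else n_real_modes
    if not 0 <= n_real <= max_real:
        raise ValueError(f"n_real_modes must be in [0, {max_real}]")
    free_cols = np.flatnonzero(np.repeat(~structure.frozen, 3))
    basis = rng.normal(size=(n_free_dof, n_real))
    # orthonormalize real modes against the reactive mode (mass-weighted)
    stack = np.column_stack([v_imag[free_cols], basis])
    q, _ = np.linalg.qr(stack)
    vecs_mw = np.zeros((3 * n, 1 + n_real))
    vecs_mw[free_cols, 0] = v_imag[free_cols] / np.linalg.norm(v_imag[free_cols])
    vecs_mw[free_cols, 1:] = q[:, 1:1 + n_real]
    freqs = np.concatenate([[imaginary_frequency],
                            np.linspace(100.0, 1800.0, n_real)])
    disp = (vecs_mw / sqrt_m[:, None]).T
    return compute_ked(ModeSet(freqs, disp, structure))


# ---------------------------------------------------------------------------
# Charge-response fixture
# ---------------------------------------------------------------------------

def gen_charge_response(n_atoms: int = 25, slope_truth: float | str = "E",
                        noise_sd: float = 0.0,
                        grid=None, seed: int = 0) -> ChargeResponse:
    """Linear atomic-charge response with a prescribed polarization slope.

    Per-atom response coefficients a_i (random signs and magnitudes) are
    normalized so Σ|a_i| equals ``slope_truth`` (a number, or a preset label
    from :data:`POLARIZATION_PRESETS`); Gaussian noise of ``noise_sd`` (e) is
    added to every charge except at q_P = 0 so that P(0) = 0 holds exactly.
    """
    label = ""
    if isinstance(slope_truth, str):
        label = slope_truth
        try:
            slope_truth = POLARIZATION_PRESETS[slope_truth]
        except KeyError:
            raise KeyError(
                f"unknown preset {slope_truth!r}; presets: "
                + ", ".join(POLARIZATION_PRESETS)) from None
    if slope_truth < 0:
        raise ValueError("slope_truth must be non-negative")
    grid = DEFAULT_PROBE_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty probe grid")
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=n_atoms) * rng.choice([-1.0, 1.0], n_atoms)
    denom = np.sum(np.abs(raw))
    a = raw / denom * slope_truth if slope_truth > 0 else np.zeros(n_atoms)
    q0 = rng.uniform(-0.5, 0.5, n_atoms)
    charges = q0[:, None] + a[:, None] * grid[None, :]
    if noise_sd > 0:
        noise = rng.normal(scale=noise_sd, size=charges.shape)
        noise[:, grid == 0.0] = 0.0
        charges = charges + noise
    return ChargeResponse(grid, charges, model=label)


# ---------------------------------------------------------------------------
# Model series
# ---------------------------------------------------------------------------

@dataclass
class SeriesSpec:
    """Truth values defining the synthetic five-model maturation series.

    Defaults encode the qualitative picture: the reduction potential rises
    monotonically from the early precursor to the native-like model while
    the Ni–S bond-formation leg strengthens (grows more negative), so the
    step-1 driving force and barrier fall toward the native cofactor with
    the non-monotone barrier ordering B > A > C > D > E. The substrate
    cleavage leg is model-independent; all legs close exactly.
    """

    labels: tuple[str, ...] = ("A", "B", "C", "D", "E")
    #: Ni(II)/Ni(I) reduction potentials (V), strictly increasing A → E
    e0: tuple[float, ...] = (-1.90, -1.55, -1.20, -0.85, -0.50)
    #: thiyl/thiolate reference couple of the substrate (V)
    e0_thiyl: float = -1.30
    #: model-independent S–CH3 homolysis leg (kcal/mol)
    cleavage: float = 55.0
    #: step-1 totals ΔG′_0,1 (kcal/mol); endergonic, ordering B>A>C>D>E
    totals: tuple[float, ...] = (30.5, 34.5, 24.5, 19.5, 14.5)
    #: S–S bond-formation leg of step 3 (kcal/mol)
    s_s: float = -75.0
    #: late-TS window: G_TS − G_Int drawn uniformly from this range (kcal/mol)
    ts_window: tuple[float, float] = (2.0, 5.0)
    #: reactive-mode fragment KED targets per model
    ked_ch3: tuple[float, ...] = (0.79, 0.81, 0.83, 0.85, 0.88)
    #: σ*(S–CH3) carbon fractions per model
    f_ch3: tuple[float, ...] = (0.60, 0.62, 0.65, 0.67, 0.694)
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.labels)
        if not (len(self.e0) == len(self.totals) == len(self.ked_ch3)
                == len(self.f_ch3) == k):
            raise ValueError("per-model truth arrays must match labels")
        lo, hi = self.ts_window
        if not 0 < lo < hi:
            raise ValueError("ts_window must satisfy 0 < low < high")

    @property
    def et_legs(self) -> np.ndarray:
        """ΔG′_ET per model: −F·(E°_thiyl − E°_Ni) on the kcal/mol scale."""
        return EV_TO_KCAL * (np.asarray(self.e0) - self.e0_thiyl)

    @property
    def nis_legs(self) -> np.ndarray:
        """ΔG′_NiS per model, implied by closure of the step-1 cycle."""
        return np.asarray(self.totals) - self.cleavage - self.et_legs


@dataclass
class ModelSeries:
    """Everything :func:`gen_model_series` produces for one seed."""

    spec: SeriesSpec
    ledger: FreeEnergyLedger
    energetics: StepEnergetics
    cycles: dict[str, ThermoCycle]
    bonds: pd.DataFrame
    e0: dict[str, float] = field(default_factory=dict)
    polarization_slopes: dict[str, float] = field(default_factory=dict)
    ked_ch3: dict[str, float] = field(default_factory=dict)
    f_ch3: dict[str, float] = field(default_factory=dict)


#: deterministic per-model bond/charge descriptor truths (A → E)
_BOND_TRUTHS = {
    "NiS_dist_angstrom": (2.42, 2.39, 2.36, 2.33, 2.30),
    "NiN_dist_angstrom": (1.905, 1.925, 1.945, 1.965, 1.985),
    "q_Ni_e": (1.21, 1.20, 1.19, 1.18, 1.17),
    "q_N_e": (-1.17, -1.165, -1.16, -1.155, -1.15),
    "DI_NiS": (0.70, 0.78, 0.92, 1.05, 1.18),
    "DI_NiN": (1.05, 1.00, 0.93, 0.87, 0.80),
    "bond_order_NiS": (0.75, 0.85, 0.95, 1.08, 1.20),
}

# fixed free energies of the shared (model-independent) species, kcal/mol
_SHARED_G = {"CH3SCoM": 0.0, "CH3_radical": 35.0, "SCoM_radical": 20.0,
             "SCoM_anion": 0.0, "CoBS_radical": 10.0}


def _row(label: str, g: float) -> LedgerRow:
    # arbitrary fixed split of G into components; the identity is what matters
    return LedgerRow(label=label, E_el=g - 8.0, E_zpve=5.0, thermal=3.0,
                     T=298.0, p=1.0, regime="frozen-cluster")


def gen_model_series(spec: SeriesSpec | None = None) -> ModelSeries:
    """Build the five-model ledger series with exactly closing cycles.

    Species free energies are constructed so that for each model the step-1
    cycle closes on the spec's legs and the step-3 cycle on their reverses
    plus the S–S leg. Transition states are placed in the late-TS window
    (G_TS − G_Int ~ U[low, high]), so ΔG‡ = ΔG_0 + window tracks the driving
    force and the barrier/driving-force regression has slope ≈ 1.
    """
    spec = spec or SeriesSpec()
    rng = np.random.default_rng(spec.seed)
    et = spec.et_legs
    nis = spec.nis_legs
    ledger = FreeEnergyLedger()
    for name, g in _SHARED_G.items():
        ledger.add(_row(name, g))
    ledger.add(_row("CoMS_SCoB",
                    spec.s_s + _SHARED_G["SCoM_radical"]
                    + _SHARED_G["CoBS_radical"]))
    for m, et_m, nis_m in zip(spec.labels, et, nis):
        ledger.add(_row(f"NiI:{m}", 0.0))
        ledger.add(_row(f"NiII:{m}", et_m + _SHARED_G["SCoM_radical"]))
        ledger.add(_row(f"NiII_SCoM:{m}",
                        et_m + nis_m + _SHARED_G["SCoM_radical"]))
    window = rng.uniform(*spec.ts_window, size=len(spec.labels))
    totals = np.asarray(spec.totals)
    energetics = StepEnergetics(list(spec.labels), totals + window, totals,
                                ts_int_gap=window)
    cycles = {m: build_step1_cycle(ledger, model=m) for m in spec.labels}
    bonds = pd.DataFrame({"model": list(spec.labels), **_BOND_TRUTHS})
    return ModelSeries(
        spec=spec, ledger=ledger, energetics=energetics, cycles=cycles,
        bonds=bonds,
        e0=dict(zip(spec.labels, spec.e0)),
        polarization_slopes=dict(POLARIZATION_PRESETS),
        ked_ch3=dict(zip(spec.labels, spec.ked_ch3)),
        f_ch3=dict(zip(spec.labels, spec.f_ch3)))


# ---------------------------------------------------------------------------
# Constructed correlation fixtures
# ---------------------------------------------------------------------------

def gen_linear_leg_system(slope_nis: float = 2.8, slope_et: float = -1.8,
                          totals=(-2.0, -1.0, 0.0, 1.0, 2.0),
                          nis_intercept: float = -30.0,
                          et_intercept: float = -10.0,
                          ) -> list[ThermoCycle]:
    """Noise-free step-1 cycles whose leg-vs-total slopes are exact.

    ΔG′_NiS = slope_nis·t + c1 and ΔG′_ET = slope_et·t + c2 with the
    cleavage leg taking up the remainder; with slope_nis + slope_et = 1 the
    cleavage leg is the same constant in every model, mirroring its
    model-independence.
    """
    cycles = []
    for t in totals:
        nis = slope_nis * t + nis_intercept
        et = slope_et * t + et_intercept
        cycles.append(ThermoCycle(
            "step1", {"cleavage": t - nis - et, "ET": et, "NiS": nis},
            direct=t))
    return cycles


def gen_correlated_pairs(n: int, r_target: float, seed: int,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal (x, y) pairs with population correlation r_target."""
    if not -1.0 <= r_target <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = r_target * x + np.sqrt(1.0 - r_target**2) * rng.normal(size=n)
    return x, y


__all__ = [
    "POLARIZATION_PRESETS", "DEFAULT_PROBE_GRID", "SeriesSpec", "ModelSeries",
    "gen_coupled_oscillator", "gen_random_hessian", "gen_ts_mode",
    "gen_charge_response", "gen_model_series", "gen_linear_leg_system",
    "gen_correlated_pairs",
]
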