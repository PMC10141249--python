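# Methods

`reactfactors` analyses why a nickel-corphinoid macrocycle is (or is not) a
good catalyst for reductive S–CH3 cleavage, the rate-determining step of
enzymatic methane formation. It post-processes quantum-chemistry outputs —
geometries, Hessians, energy ledgers, atomic-charge and orbital-composition
tables — and never performs electronic-structure computation itself. This
note records the models implemented, the defaults chosen where the design
was open, and what the synthetic-data layer does and does not emulate.

## Normal modes and frozen-atom projection

Cluster models of enzyme active sites keep a handful of peripheral capping
atoms fixed. We zero the rows and columns of the Cartesian Hessian belonging
to the 3f frozen coordinates and diagonalize only the mass-weighted
free-coordinate block, so frozen atoms carry exactly zero displacement in
every mode and the vibrational problem has 3n − 3f degrees of freedom —
3n − 24 for the common 8-frozen-atom convention, or 3n − 25 real modes plus
one imaginary mode at a transition state. Rigid-body translation/rotation
(Eckart) projection is available for free molecules but off by default: a
frozen framework removes global motion already, and linear molecules are
handled by the projector's rank (one null rotation vector is dropped
automatically, so no linearity flag is needed).

Eigenvalues λ of the mass-weighted Hessian (hartree/bohr², masses in amu)
map to wavenumbers by ν̃ = sign(λ)·5140.487·√|λ| cm⁻¹ (CODATA constants);
imaginary modes are stored as negative wavenumbers so a frequency stays one
scalar. Modes with |ν̃| < 1 cm⁻¹ (configurable) are treated as the numerical
nullspace and dropped. Modes closer than 0.01 cm⁻¹ are flagged degenerate,
and fragment KED on them warns: within a degenerate subspace the
eigenvectors — hence the KED — are defined only up to rotation.

## Kinetic energy distribution (KED)

For mode α with Cartesian atomic displacements r_iα,

    KED_iα = m_i |r_iα|² / Σ_k m_k |r_kα|² ∈ [0, 1],  Σ_i KED_iα = 1.

The statistic is invariant to displacement scaling; vectors are stored
mass-weighted-normalized. For transition states only the single
imaginary-frequency (reactive) mode is analysed; its KED summed over the
nascent methyl fragment measures how ballistically CH3 departs. Aggregation
over modes, ⟨T_i⟩ = Σ_α KED_iα⟨T_α⟩, is provided as a plain dot product with
user-supplied per-mode kinetic energies — no thermal-population model is
assumed, because none is defined for the nonequilibrium situations the
statistic targets.

## RRHO thermochemistry

Gibbs free energies are assembled as G = E_el + E_ZPVE + (pV − RT ln Q),
with E_ZPVE = Σ hc ν̃/2 over real modes and the thermal term computed as
H_thermal − T·S. Defaults: T = 298.0 K, p = 1 bar (298.15 K selectable).
Two regimes:

* **free-molecule** — Sackur–Tetrode translations, classical rigid rotor
  (symmetry number default 1), harmonic vibrations referenced to the
  vibrational ground state; pV = RT.
* **frozen-cluster** — only the projected vibrational degrees of freedom
  enter Q. Whether an embedded cluster should carry a pV work term is a
  convention; we retain pV = RT by default for cross-regime consistency and
  expose `include_pv=False` to drop it. Relative free energies between
  same-regime species are unaffected either way.

No quasi-harmonic damping of low frequencies is applied: plain RRHO is the
model, and softening it would change the very trends being analysed.

Unit conversions are pinned package-wide (1 hartree = 627.5095 kcal/mol,
1 eV = 23.0605 kcal/mol, 1 cm⁻¹ = 2.85914×10⁻³ kcal/mol, Coulomb constant
332.0637 kcal·Å·mol⁻¹·e⁻²) so numbers cannot drift between modules.

## Redox potentials

E° = (G_ox − G_red) − E°_abs(reference) with free energies in eV per
particle (the Faraday constant cancels on that scale) and the normal
hydrogen electrode at 4.28 eV as default absolute reference. The electron's
free energy and solvation are absorbed into the reference, the standard
absolute-potential convention. ∂E°/∂G_ox = +1 V/eV and ∂E°/∂G_red = −1 V/eV
by construction, which the tests verify by finite differences.

## Thermodynamic cycles

Step 1 is decomposed over isolated species into substrate S–CH3 homolysis
(model-independent), Ni(I)→thiyl electron transfer, and Ni(II)–thiolate bond
formation; step 3 into Ni–S cleavage, thiolate→Ni(II) electron transfer and
S–S bond formation. Closure (Σ legs = direct ΔG from the ledger corners) is
an exact state-function identity and is enforced to 1e−9 kcal/mol. The ET
leg relates to potentials by ΔG′_ET = F·E°(Ni) − F·E°(thiyl/thiolate); the
thiyl reference couple is a ledger input, never computed. Cycles are built
from singlet-ground-state Ni(II) corners by default; since corner identity
is carried by ledger labels, a triplet-corner variant is just a different
ledger, and the correlation machinery is unchanged.

Cross-model regressions are unweighted OLS. Because the cleavage leg is
model-independent, the slopes of ΔG′_NiS and ΔG′_ET against the total
ΔG′_0,1 sum to one; a slope pair like (2.8, −1.8) therefore means the Ni–S
bond-strength term dominates the redox term by a factor ≈ 1.5 while the two
act in opposite directions. The "−1.8-type" number is reported on the
kcal/mol scale of ΔG′_ET; divided by F it is equivalently the slope of E°
versus the total.

## Ligand polarization

The ligand's responsiveness to the charge of the coordinated metal is
probed by tabulated atomic charges q_i(q_P) against a central point charge
on a 0→1 e grid in 0.1 e steps. We use P(q_P) = Σ_i |q_i(q_P) − q_i(0)|,
the simplest form consistent with linear printed curves and slopes of order
one per unit probe charge; a sum-of-squares variant sits behind
`squared=True` and the atom subset is configurable. The slope is fit by OLS
through the origin (P(0) = 0 holds by definition); the free-intercept fit
is reported alongside as a diagnostic for offset-contaminated input.

## Synthetic-data layer

The generators produce inputs with the structural properties the analysis
assumes, so every stage is testable without electronic-structure software:

* linear spring chains with closed-form spectra, and random symmetric
  Hessians (either-sign eigenvalues) for invariant stress tests;
* transition-state mode sets whose reactive-mode fragment KED is built to an
  exact target by splitting the mass-weighted displacement norm between
  fragment and complement;
* linear charge responses with per-atom coefficients normalized to a target
  slope (presets A…E: 1.34, 1.26, 1.18, 1.10, 1.02 e/e) plus Gaussian
  charge noise (default case 0.005 e) everywhere except q_P = 0;
* a five-model free-energy ledger series whose cycles close exactly on
  specified legs.

The default series truths encode the qualitative maturation picture: the
reduction potential rises monotonically (−1.90 → −0.50 V against a fixed
thiyl couple at −1.30 V), the Ni–S formation leg strengthens monotonically,
the cleavage leg is constant at 55 kcal/mol, step-1 totals are endergonic
(30.5, 34.5, 24.5, 19.5, 14.5 kcal/mol for A…E), and transition states sit
2–5 kcal/mol above the following intermediate, so barriers track driving
forces with slope ≈ 1 and the barrier ordering B > A > C > D > E is
guaranteed for every seed (the total-energy gaps exceed the 3 kcal/mol
maximum jitter of the TS window). These numbers are synthetic constructions
chosen once for realism of orderings and magnitudes; they are not
electronic-structure results, and nothing downstream fits to them other
than by recovering them. All randomness flows through per-generator
`numpy` Generators, so outputs are bit-reproducible per seed.

What the generators do **not** emulate: anharmonicity, mode mixing between
fragment and framework at real transition states, nonlinear charge
responses, solvation or spin-state effects, and any correlation structure
between noise terms. Passing tests therefore demonstrate correctness of the
analysis operations and estimators under the stated models — not the
accuracy of any electronic-structure protocol on real cofactors.

## Problem sizes and numerical choices

Tests and the acceptance script run on desk-scale problems chosen as the
smallest sizes that exercise every code path: ≤10-atom Hessians (hundreds of
random draws), 25-atom/11-point charge tables, five-model series, and
1000-ledger closure sweeps. The acceptance script averages stochastic
targets over 12 replicate generations spawned from the user seed, because a
single five-model draw scatters the barrier/driving-force slope by up to
~0.12 purely through the prescribed TS-window randomness. Tolerances:
closure and algebraic identities at 1e−9–1e−12; eigen-solver-dependent
comparisons at 1e−8–1e−10; entropy closed forms at 0.1%.

## Known limitations

* Orbital compositions, AIM charges, delocalization indices and bond orders
  are consumed as tabulated inputs; the package cannot validate their
  provenance.
* The Coulomb differential is a bare point-charge estimate (no dielectric
  screening, mean Ni–N distance per model).
* KED within degenerate mode pairs is basis-dependent; the warning is the
  only mitigation.
* The frozen-cluster pV convention is a documented choice, not a derived
  result.
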