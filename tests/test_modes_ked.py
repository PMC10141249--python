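"""Normal-mode analysis and kinetic-energy-distribution properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reactfactors import (Fragment, ModeSet, Structure, compute_ked,
                          fragment_ked, normal_modes, project_frozen)
from reactfactors import atom_kinetic_energies
from reactfactors.constants import WAVENUMBER_FACTOR
from reactfactors.modes_ked import ModeError
from reactfactors import synthetic_data as synth


def brute_force_ked(masses, cartesian_displacement):
    """Direct per-atom kinetic-energy fraction, written independently."""
    n = len(masses)
    num = [masses[i] * sum(cartesian_displacement[3 * i + j] ** 2
                           for j in range(3)) for i in range(n)]
    total = sum(num)
    return [v / total for v in num]


class TestProjection:
    def test_frozen_rows_and_columns_zeroed(self):
        s, h = synth.gen_random_hessian(3, seed=1, frozen=[2])
        hp = project_frozen(h, s)
        assert np.all(hp[6:, :] == 0) and np.all(hp[:, 6:] == 0)
        # untouched free block
        np.testing.assert_array_equal(hp[:6, :6], h[:6, :6])

    def test_projected_hessian_gains_zero_eigenvalues(self):
        s, h = synth.gen_random_hessian(5, seed=2, frozen=[0, 4])
        hp = project_frozen(h, s)
        evals = np.linalg.eigvalsh(hp)
        assert np.sum(np.abs(evals) < 1e-12) >= 6

    def test_no_frozen_atoms_is_identity(self):
        s, h = synth.gen_random_hessian(3, seed=3)
        assert project_frozen(h, s) is h

    @pytest.mark.parametrize("ts", [False, True])
    def test_cluster_dof_counts_match_convention(self, ts):
        """f=8 gives 3n-24 real modes for minima, 3n-25 + 1 imaginary for TS."""
        n, f = 10, 8
        rng = np.random.default_rng(7)
        s, _ = synth.gen_random_hessian(n, seed=7, frozen=list(range(2, 10)))
        free = 3 * (n - f)
        q = np.linalg.qr(rng.normal(size=(free, free)))[0]
        evals = rng.uniform(0.05, 0.8, free)
        if ts:
            evals[0] = -0.2
        block = q @ np.diag(evals) @ q.T
        h = np.zeros((3 * n, 3 * n))
        free_idx = np.flatnonzero(np.repeat(~s.frozen, 3))
        h[np.ix_(free_idx, free_idx)] = block
        modes = normal_modes(h, s, expect_transition_state=ts)
        assert modes.n_modes == 3 * n - 24
        assert modes.n_imaginary == (1 if ts else 0)
        if ts:
            assert len(modes.real_frequencies()) == 3 * n - 25

    def test_multiple_imaginary_fails_ts_check(self):
        s, h = synth.gen_random_hessian(4, seed=9)
        with pytest.raises(ModeError, match="imaginary"):
            normal_modes(h, s, expect_transition_state=True)


class TestFrequencies:
    @pytest.mark.parametrize("m, k", [(1.0, 0.37), (12.0, 0.5), (2.5, 0.05)])
    def test_homonuclear_diatomic_closed_form(self, m, k):
        s, h = synth.gen_coupled_oscillator(2, [m, m], [k])
        modes = normal_modes(h, s)
        assert modes.n_modes == 1
        expected = WAVENUMBER_FACTOR * math.sqrt(k / (m / 2.0))
        assert modes.frequencies[0] == pytest.approx(expected, rel=1e-6)

    def test_uniform_triatomic_stretch_ratio(self):
        """Free equal-mass chain: the two stretches are in ratio 1 : sqrt(3)."""
        s, h = synth.gen_coupled_oscillator(3, [12.0] * 3, [0.4, 0.4])
        modes = normal_modes(h, s)
        assert modes.n_modes == 2
        assert modes.frequencies[1] / modes.frequencies[0] == \
            pytest.approx(math.sqrt(3.0), rel=1e-8)

    def test_uniform_spectral_shift(self):
        """Adding c*I in the mass-weighted basis shifts all eigenvalues by c."""
        s, h = synth.gen_random_hessian(4, seed=12)
        modes = normal_modes(h, s, zero_cutoff=0.0)
        shift = 0.05
        sqrt_m = np.sqrt(np.repeat(s.masses, 3))
        h_shifted = h + shift * np.diag(sqrt_m**2)
        modes2 = normal_modes(h_shifted, s, zero_cutoff=0.0)
        ev1 = np.sign(modes.frequencies) * (modes.frequencies /
                                            WAVENUMBER_FACTOR) ** 2
        ev2 = np.sign(modes2.frequencies) * (modes2.frequencies /
                                             WAVENUMBER_FACTOR) ** 2
        np.testing.assert_allclose(ev2, ev1 + shift, atol=1e-10)


class TestKED:
    def test_homonuclear_stretch_splits_evenly(self):
        s, h = synth.gen_coupled_oscillator(2, [1.0, 1.0], [0.3])
        modes = normal_modes(h, s)
        np.testing.assert_allclose(modes.ked[:, 0], [0.5, 0.5], atol=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_heteronuclear_closed_form_over_mass_pairs(self, seed):
        """Center-of-mass condition gives KED_i = m_j/(m_i+m_j)."""
        rng = np.random.default_rng(seed)
        m1, m2 = rng.uniform(1.0, 200.0, 2)
        s, h = synth.gen_coupled_oscillator(2, [m1, m2], [0.3])
        modes = normal_modes(h, s)
        np.testing.assert_allclose(
            modes.ked[:, 0], [m2 / (m1 + m2), m1 / (m1 + m2)], atol=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_brute_force_oracle_equivalence(self, n, seed):
        """compute_ked matches a direct evaluation on raw eigenvectors."""
        s, h = synth.gen_random_hessian(n, seed=seed)
        modes = normal_modes(h, s, zero_cutoff=0.0)
        for alpha in range(modes.n_modes):
            expected = brute_force_ked(s.masses.tolist(),
                                       modes.displacements[alpha].tolist())
            np.testing.assert_allclose(modes.ked[:, alpha], expected,
                                       atol=1e-10)

    @pytest.mark.parametrize("seed", range(100))
    def test_column_normalization_on_random_hessians(self, seed):
        s, h = synth.gen_random_hessian(4, seed=seed)
        modes = normal_modes(h, s, zero_cutoff=0.0)
        np.testing.assert_allclose(modes.ked.sum(axis=0),
                                   np.ones(modes.n_modes), atol=1e-8)
        assert np.all(modes.ked >= 0) and np.all(modes.ked <= 1 + 1e-12)

    def test_frozen_atoms_carry_exactly_zero(self):
        s, h = synth.gen_random_hessian(6, seed=4, frozen=[4, 5])
        modes = normal_modes(h, s)
        frozen_rows = modes.displacements[:, 12:]
        assert np.all(frozen_rows == 0.0)
        assert np.all(modes.ked[4:, :] == 0.0)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_invariance_of_displacements(self, scale):
        s, h = synth.gen_random_hessian(3, seed=8)
        modes = normal_modes(h, s, zero_cutoff=0.0)
        scaled = compute_ked(ModeSet(modes.frequencies,
                                     modes.displacements * scale, s))
        np.testing.assert_allclose(scaled.ked, modes.ked, atol=1e-10)

    def test_zero_displacement_mode_rejected(self):
        s, _ = synth.gen_random_hessian(2, seed=1)
        with pytest.raises(ModeError, match="zero total displacement"):
            compute_ked(ModeSet(np.array([100.0]), np.zeros((1, 6)), s))


class TestFragmentKED:
    def test_whole_system_fragment_is_one(self, ts_structure):
        frag = Fragment("all", list(range(ts_structure.n_atoms)))
        modes = synth.gen_ts_mode(ts_structure, Fragment("f", [0, 1]), 0.6,
                                  seed=2)
        assert fragment_ked(modes, frag, 0) == pytest.approx(1.0, abs=1e-12)

    def test_generator_target_share_recovered(self, ts_structure):
        frag = Fragment("CH3", [0, 1, 2, 3])
        modes = synth.gen_ts_mode(ts_structure, frag, 0.88, seed=5)
        idx = modes.imaginary_mode_index()
        assert fragment_ked(modes, frag, idx) == pytest.approx(0.88, abs=1e-9)

    def test_additivity_over_disjoint_fragments(self, ts_structure):
        modes = synth.gen_ts_mode(ts_structure, Fragment("f", [0, 1, 2]),
                                  0.7, seed=6)
        f1, f2 = Fragment("a", [0, 1]), Fragment("b", [2, 5])
        union = Fragment("ab", [0, 1, 2, 5])
        assert fragment_ked(modes, union, 0) == pytest.approx(
            fragment_ked(modes, f1, 0) + fragment_ked(modes, f2, 0),
            abs=1e-12)

    def test_empty_fragment_rejected(self, ts_structure):
        modes = synth.gen_ts_mode(ts_structure, Fragment("f", [0]), 0.5,
                                  seed=7)
        with pytest.raises(ValueError, match="empty"):
            fragment_ked(modes, Fragment("none", []), 0)

    def test_degenerate_mode_warns(self):
        s, _ = synth.gen_random_hessian(3, seed=3)
        freqs = np.array([500.0, 500.0 + 1e-3])
        rng = np.random.default_rng(0)
        disp = rng.normal(size=(2, 9))
        modes = compute_ked(ModeSet(freqs, disp, s))
        with pytest.warns(UserWarning, match="degenerate"):
            fragment_ked(modes, Fragment("f", [0]), 0)


class TestThermalAggregation:
    def test_atom_energies_are_ked_weighted_mode_energies(self, ts_structure):
        modes = synth.gen_ts_mode(ts_structure, Fragment("f", [0, 1]), 0.5,
                                  seed=9, n_real_modes=4)
        t_alpha = np.linspace(1.0, 2.0, modes.n_modes)
        t_i = atom_kinetic_energies(modes, t_alpha)
        assert t_i.sum() == pytest.approx(t_alpha.sum(), abs=1e-10)
        np.testing.assert_allclose(t_i, modes.ked @ t_alpha)
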