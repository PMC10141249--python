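"""Generator determinism, construction guarantees and trend orderings."""

import math

import numpy as np
import pytest

from reactfactors import Fragment, normal_modes
from reactfactors import synthetic_data as synth


class TestCoupledOscillator:
    def test_two_equal_masses_single_mode_even_ked(self):
        s, h = synth.gen_coupled_oscillator(2, [1.0, 1.0], [1.0])
        modes = normal_modes(h, s)
        assert modes.n_modes == 1
        np.testing.assert_allclose(modes.ked[:, 0], [0.5, 0.5], atol=1e-12)

    def test_triatomic_stretch_ratio(self):
        s, h = synth.gen_coupled_oscillator(3, [1.0] * 3, [0.2, 0.2])
        modes = normal_modes(h, s)
        assert modes.frequencies[1] / modes.frequencies[0] == \
            pytest.approx(math.sqrt(3.0), rel=1e-9)

    def test_frozen_end_removes_three_dof(self):
        s_free, h_free = synth.gen_coupled_oscillator(4, [1.0] * 4, [0.2] * 3)
        s_froz, h_froz = synth.gen_coupled_oscillator(4, [1.0] * 4, [0.2] * 3,
                                                      frozen=[3])
        free = normal_modes(h_free, s_free, zero_cutoff=0.0)
        froz = normal_modes(h_froz, s_froz, zero_cutoff=0.0)
        assert free.n_modes - froz.n_modes == 3

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(ValueError, match="masses"):
            synth.gen_coupled_oscillator(3, [1.0, 2.0], [0.1, 0.1])

    def test_hessian_is_symmetric(self):
        _, h = synth.gen_coupled_oscillator(5, [1.0] * 5, [0.3] * 4)
        np.testing.assert_array_equal(h, h.T)


class TestTSMode:
    def test_exact_target_share(self, ts_structure):
        frag = Fragment("CH3", [0, 1, 2, 3])
        modes = synth.gen_ts_mode(ts_structure, frag, 0.88, seed=1)
        idx = modes.imaginary_mode_index()
        assert modes.ked[frag.indices, idx].sum() == pytest.approx(0.88,
                                                                   abs=1e-9)
        assert modes.n_imaginary == 1

    def test_full_fragment_with_unit_share(self, ts_structure):
        frag = Fragment("all", list(range(ts_structure.n_atoms)))
        modes = synth.gen_ts_mode(ts_structure, frag, 1.0, seed=2)
        idx = modes.imaginary_mode_index()
        assert modes.ked[:, idx].sum() == pytest.approx(1.0, abs=1e-12)

    def test_infeasible_share_rejected(self, ts_structure):
        frag = Fragment("all", list(range(ts_structure.n_atoms)))
        with pytest.raises(ValueError, match="infeasible"):
            synth.gen_ts_mode(ts_structure, frag, 0.5, seed=3)

    def test_same_seed_bit_identical(self, ts_structure):
        frag = Fragment("f", [0, 1])
        a = synth.gen_ts_mode(ts_structure, frag, 0.7, seed=42)
        b = synth.gen_ts_mode(ts_structure, frag, 0.7, seed=42)
        np.testing.assert_array_equal(a.displacements, b.displacements)
        np.testing.assert_array_equal(a.frequencies, b.frequencies)

    def test_real_modes_orthogonal_to_reactive_mode(self, ts_structure):
        frag = Fragment("f", [0, 1])
        modes = synth.gen_ts_mode(ts_structure, frag, 0.7, seed=5)
        sqrt_m = np.sqrt(np.repeat(ts_structure.masses, 3))
        mw = modes.displacements * sqrt_m[None, :]
        gram = mw @ mw.T
        np.testing.assert_allclose(gram, np.eye(modes.n_modes), atol=1e-8)


class TestChargeResponse:
    def test_noise_free_preset_slope_exact(self):
        from reactfactors import polarization_curve, polarization_slope
        resp = synth.gen_charge_response(25, "E", noise_sd=0.0, seed=0)
        m, _ = polarization_slope(polarization_curve(resp))
        assert m == pytest.approx(1.02, abs=1e-9)

    def test_preset_ordering_most_to_least_responsive(self):
        slopes = [synth.POLARIZATION_PRESETS[m] for m in "ABCDE"]
        assert slopes == sorted(slopes, reverse=True)
        assert slopes[0] == 1.34 and slopes[-1] == 1.02

    def test_zero_truth_gives_noise_level_slope(self):
        from reactfactors import polarization_curve, polarization_slope
        resp = synth.gen_charge_response(25, 0.0, noise_sd=0.005, seed=1)
        m, _ = polarization_slope(polarization_curve(resp))
        assert 0.0 <= m < 0.2

    def test_same_seed_bit_identical(self):
        a = synth.gen_charge_response(10, "A", noise_sd=0.01, seed=9)
        b = synth.gen_charge_response(10, "A", noise_sd=0.01, seed=9)
        np.testing.assert_array_equal(a.charges, b.charges)

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError, match="preset"):
            synth.gen_charge_response(5, "Z", seed=0)


class TestModelSeries:
    def test_same_seed_identical_ledgers(self):
        a = synth.gen_model_series(synth.SeriesSpec(seed=3))
        b = synth.gen_model_series(synth.SeriesSpec(seed=3))
        for row_a, row_b in zip(a.ledger, b.ledger):
            assert row_a == row_b

    def test_cycles_close_on_spec_legs(self, default_series):
        spec = default_series.spec
        for m, et, nis, total in zip(spec.labels, spec.et_legs,
                                     spec.nis_legs, spec.totals):
            cycle = default_series.cycles[m]
            assert cycle.legs["cleavage"] == pytest.approx(spec.cleavage,
                                                           abs=1e-9)
            assert cycle.legs["ET"] == pytest.approx(et, abs=1e-9)
            assert cycle.legs["NiS"] == pytest.approx(nis, abs=1e-9)
            assert cycle.total == pytest.approx(total, abs=1e-9)

    def test_barrier_ordering_b_a_c_d_e(self, default_series):
        """The step-1 barrier falls along maturation: B > A > C > D > E."""
        act = dict(zip(default_series.energetics.labels,
                       default_series.energetics.dg_act))
        assert act["B"] > act["A"] > act["C"] > act["D"] > act["E"]

    def test_potentials_strictly_increase(self, default_series):
        e0 = [default_series.e0[m] for m in "ABCDE"]
        assert np.all(np.diff(e0) > 0)

    def test_nis_leg_strictly_strengthens(self, default_series):
        nis = [default_series.cycles[m].legs["NiS"] for m in "ABCDE"]
        assert np.all(np.diff(nis) < 0)

    def test_ts_window_within_late_ts_bounds(self, default_series):
        gap = default_series.energetics.ts_int_gap
        lo, hi = default_series.spec.ts_window
        assert np.all(gap >= lo) and np.all(gap <= hi)
        assert np.all(gap < 5.0 + 1e-12)

    def test_step3_total_least_negative_for_native_model(self, default_series):
        from reactfactors import build_step3_cycle
        totals = {m: build_step3_cycle(default_series.ledger, model=m).total
                  for m in "ABCDE"}
        assert totals["E"] == max(totals.values())

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError, match="ts_window"):
            synth.SeriesSpec(ts_window=(5.0, 2.0))
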