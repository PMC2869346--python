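"""Ligand occupancy, coupling modulation, and the stochastic activity update."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hextaxis import (EnergyParams, LigandEnvironment, Receptor,
                      ReceptorField, activation_probability, coupling_weight,
                      default_ligands, fractional_occupancy)
from hextaxis.receptor_field import KD_ACTIVE, TAR, update_field


class TestFractionalOccupancy:
    def test_no_ligand_no_occupancy(self):
        assert fractional_occupancy(0.0, 1e-6) == 0.0

    def test_half_saturation_at_kd(self):
        assert fractional_occupancy(1e-6, 1e-6) == pytest.approx(0.5)

    def test_active_tar_kd(self):
        # active-state MeAsp Kd of 12 uM: half occupancy at 12 uM
        assert fractional_occupancy(12e-6, KD_ACTIVE) == pytest.approx(0.5)

    @given(st.floats(1e-9, 1e-2), st.floats(1e-9, 1e-2))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_and_bounded(self, l, dl):
        f1 = fractional_occupancy(l, 1e-6)
        f2 = fractional_occupancy(l + dl, 1e-6)
        assert 0.0 <= f1 < 1.0
        assert f2 > f1

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            fractional_occupancy(-1e-9, 1e-6)
        with pytest.raises(ValueError):
            fractional_occupancy(1e-6, 0.0)


class TestCouplingWeight:
    @pytest.mark.parametrize("m", range(5))
    def test_omega_zero_always_unity(self, m):
        assert coupling_weight(m, 0.0) == 1.0

    def test_baseline_methylation_unity_any_omega(self):
        for omega in (0.0, 0.1, 0.2, 0.5):
            assert coupling_weight(2, omega) == 1.0

    def test_linear_form_at_omega_02(self):
        assert coupling_weight(4, 0.2) == pytest.approx(0.6)
        assert coupling_weight(3, 0.2) == pytest.approx(0.8)
        assert coupling_weight(0, 0.2) == pytest.approx(1.4)

    def test_strictly_decreasing_in_m_for_positive_omega(self):
        w = [coupling_weight(m, 0.2) for m in range(5)]
        assert all(a > b for a, b in zip(w, w[1:]))

    def test_clamped_nonnegative(self):
        assert coupling_weight(4, 0.9) == 0.0


class TestActivationProbability:
    def test_ground_state_half_active(self):
        # G0=0, no ligand, m=2, no neighbors: the two conformations are
        # isoenergetic
        r = Receptor((0, 0), m=2)
        p = activation_probability(r, 0.0, [], EnergyParams(g0=0.0))
        assert p == pytest.approx(0.5)

    def test_four_active_neighbors_closed_form(self):
        # dG = -600 + 4*(-700) = -3400; p = 1/(1+exp(-3400/600))
        r = Receptor((0, 0), m=2)
        params = EnergyParams(g0=-600, ej=-700, thermal_scale=600)
        p = activation_probability(r, 0.0, [(1, 2)] * 4, params)
        assert p == pytest.approx(1 / (1 + math.exp(-3400 / 600)))
        assert p == pytest.approx(0.9966, abs=1e-4)

    def test_saturating_ligand_closed_form(self):
        # dG = 2200; p = 1/(1+exp(2200/600))
        r = Receptor((0, 0), m=2)
        params = EnergyParams(g0=0.0, el=2200, thermal_scale=600)
        p = activation_probability(r, 1.0, [], params)
        assert p == pytest.approx(0.0250, abs=1e-4)

    def test_pure_function(self):
        r = Receptor((0, 0), m=3, a=-1)
        args = (r, 0.3, [(1, 2), (-1, 4)], EnergyParams(omega=0.2))
        assert activation_probability(*args) == activation_probability(*args)


def _field(mask, m=2, ligands=None, **energy):
    rtype = np.zeros(mask.n_receptors, dtype=np.int8)
    f = ReceptorField(mask, rtype, np.full(mask.n_receptors, m, np.int8))
    f.set_binding(ligands if ligands is not None else default_ligands())
    return f, EnergyParams(**energy)


class TestFieldUpdate:
    def test_forced_saturation_all_active(self, small_mask):
        f, params = _field(small_mask, g0=-1e9)
        f.a[:] = -1
        update_field(f, LigandEnvironment(), params,
                     np.random.default_rng(0))
        assert np.all(f.a == 1)

    def test_fixed_seed_bit_reproducible(self, small_mask):
        states = []
        for _ in range(2):
            f, params = _field(small_mask)
            rng = np.random.default_rng(42)
            for _ in range(50):
                update_field(f, LigandEnvironment(), params, rng)
            states.append(f.a.copy())
        assert np.array_equal(states[0], states[1])

    def test_isolated_receptor_long_run_frequency(self, small_mask):
        # with Ej=0 receptors are independent; each one's long-run active
        # fraction is its fixed p within binomial error
        f, params = _field(small_mask, g0=-600, ej=0.0)
        p = 1 / (1 + math.exp(-600 / params.thermal_scale))
        rng = np.random.default_rng(7)
        n_steps = 10_000
        active = np.zeros(f.n)
        for _ in range(n_steps):
            update_field(f, LigandEnvironment(), params, rng)
            active += f.a == 1
        freq = active / n_steps
        se = math.sqrt(p * (1 - p) / n_steps)
        assert np.all(np.abs(freq - p) < 6 * se)

    @pytest.mark.parametrize("m,conc", [(2, 0.0), (3, 2e-6), (4, 1e-5)])
    def test_independent_limit_matches_logistic(self, small_mask, m, conc):
        # Ej=0, omega=0: mean activity equals the closed-form logistic of
        # G0 + El*F + Em*(m-2), with the state-dependent Kd handled by a
        # two-state Markov chain stationary distribution
        f, params = _field(small_mask, m=m, ej=0.0)
        env = LigandEnvironment({"MeAsp": conc})
        rng = np.random.default_rng(11)
        for _ in range(500):  # burn-in
            update_field(f, env, params, rng)
        samples = []
        for _ in range(4000):
            update_field(f, env, params, rng)
            samples.append(np.mean(f.a == 1))
        mean_act = np.mean(samples)

        def p_active(kd):
            fr = conc / (conc + kd)
            dg = params.g0 + params.el * fr + params.em * (m - 2)
            return 1 / (1 + math.exp(dg / params.thermal_scale))

        # previous state picks Kd: stationary pi solves
        # pi = pi*p(kd_act) + (1-pi)*p(kd_inact)
        pa, pi_ = p_active(12e-6), p_active(1.7e-6)
        stationary = pi_ / (1 - pa + pi_)
        assert mean_act == pytest.approx(stationary, abs=0.02)

    def test_activity_monotone_in_ligand(self, small_mask):
        # steady-state activity never increases with cognate attractant
        means = []
        for conc in (0.0, 1e-6, 3e-6, 1e-5, 1e-4):
            f, params = _field(small_mask)
            env = LigandEnvironment({"MeAsp": conc})
            rng = np.random.default_rng(5)
            for _ in range(800):
                update_field(f, env, params, rng)
            samples = [np.mean(f.a == 1)]
            for _ in range(500):
                update_field(f, env, params, rng)
                samples.append(np.mean(f.a == 1))
            means.append(np.mean(samples))
        assert all(a >= b - 0.03 for a, b in zip(means, means[1:]))

    def test_default_field_baseline_above_09(self, default_mask):
        # the default doubly-methylated Tar array idles nearly all active
        rtype = np.zeros(default_mask.n_receptors, dtype=np.int8)
        f = ReceptorField(default_mask, rtype,
                          np.full(default_mask.n_receptors, 2, np.int8))
        f.set_binding(default_ligands())
        params = EnergyParams()
        rng = np.random.default_rng(1)
        for _ in range(1500):
            update_field(f, LigandEnvironment(), params, rng)
        samples = []
        for _ in range(500):
            update_field(f, LigandEnvironment(), params, rng)
            samples.append(f.mean_activity())
        assert np.mean(samples) > 0.9


class TestValidation:
    def test_methylation_bounds(self):
        with pytest.raises(ValueError):
            Receptor((0, 0), m=5)
        with pytest.raises(ValueError):
            coupling_weight(5, 0.2)

    def test_two_ligands_per_type_rejected(self, small_mask):
        from hextaxis import LigandSpec
        f, _ = _field(small_mask)
        with pytest.raises(ValueError, match="two"):
            f.set_binding([LigandSpec("A", multipliers={TAR: 1.0}),
                           LigandSpec("B", multipliers={TAR: 1.0})])

    def test_negative_environment_rejected(self):
        with pytest.raises(ValueError):
            LigandEnvironment({"MeAsp": -1.0})
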