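"""Membrane activator-inhibitor kinetics, receptor binding and motility."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from bulksurf.cellmodel import (CellRunConfig, LigandParams, MeinhardtParams,
                                MotilityParams, NoiseParams, NoiseState,
                                advance_cell_step, boundary_normal_velocity,
                                curve_mean, equilibrium_occupancy,
                                initial_cell_state, ligand_surface_reaction,
                                meinhardt_homogeneous_steady_state,
                                meinhardt_rhs, ou_noise_step,
                                run_forced_protrusion, signal_term,
                                tension_step)
from bulksurf.mesh import circle_points


def circle64(r=0.1):
    return circle_points((0.0, 0.0), r, 64)


class TestMeinhardtKinetics:
    def test_constant_activator_mean_identity(self):
        mp = MeinhardtParams()
        coords = circle64()
        a = np.full(64, 0.4)
        b = np.full(64, 0.7)
        c = np.full(64, 0.1)
        _, rb, _ = meinhardt_rhs(a, b, c, 1e-3, coords, mp)
        # <a> = a for constant a: b-equation reduces to rb (a - b)
        np.testing.assert_allclose(rb, mp.rb * (0.4 - 0.7), atol=1e-14)

    def test_no_spontaneous_activation_without_basal_rate(self):
        mp = MeinhardtParams(ba=0.0)
        coords = circle64()
        act, _, _ = meinhardt_rhs(np.zeros(64), np.ones(64), np.zeros(64),
                                  1e-3, coords, mp)
        np.testing.assert_allclose(act, 0.0, atol=1e-16)

    def test_homogeneous_steady_state_is_root(self):
        mp = MeinhardtParams()
        s = mp.ra * 0.17
        a0, b0, c0 = meinhardt_homogeneous_steady_state(mp, s)
        coords = circle64()
        ra, rb, rc = meinhardt_rhs(np.full(64, a0), np.full(64, b0),
                                   np.full(64, c0), s, coords, mp)
        assert np.abs(ra).max() < 1e-10
        assert np.abs(rb).max() < 1e-10
        assert np.abs(rc).max() < 1e-10

    def test_nonpositive_inhibitor_raises(self):
        mp = MeinhardtParams()
        with pytest.raises(ValueError):
            meinhardt_rhs(np.ones(8), np.zeros(8), np.zeros(8), 1e-3,
                          circle_points((0, 0), 1.0, 8), mp)


class TestLigandBinding:
    def test_equilibrium_occupancy_zeroes_reaction(self):
        lig = LigandParams()
        l = np.array([3.0, 5.3, 7.0, 20.0])
        ls = lig.Rtot * l / (l + lig.Kd)
        np.testing.assert_allclose(ligand_surface_reaction(l, ls, lig), 0.0,
                                   atol=1e-9 * lig.Rtot)

    def test_empty_receptors_bind_at_k1_Rtot_l(self):
        lig = LigandParams()
        got = ligand_surface_reaction(4.0, 0.0, lig)
        assert got == pytest.approx(lig.k1 * lig.Rtot * 4.0)

    def test_relaxation_to_equilibrium_matches_ode_oracle(self):
        """Brute-force mass-action ODE (fixed l) approaches Rtot*l/(l+Kd)."""
        lig = LigandParams()
        l = 6.0
        sol = solve_ivp(lambda t, y: ligand_surface_reaction(l, y, lig),
                        (0.0, 3.0), [0.0], rtol=1e-10, atol=1e-8)
        midpoint = solve_ivp(lambda t, y: ligand_surface_reaction(l, y, lig),
                             (0.0, 1.5), [0.0], rtol=1e-10, atol=1e-8)
        eq = lig.Rtot * l / (l + lig.Kd)
        # monotone approach: midpoint strictly between 0 and the equilibrium
        assert 0 < midpoint.y[0, -1] < sol.y[0, -1] < eq * 1.001

    @pytest.mark.parametrize("l,expected", [(5.3, 0.15), (7.0, 0.19)])
    def test_printed_occupancies(self, l, expected):
        assert round(float(equilibrium_occupancy(l, 30.0)), 2) == expected

    def test_half_saturation(self):
        assert equilibrium_occupancy(30.0, 30.0) == pytest.approx(0.5)


class TestMotility:
    def test_pure_tension_shrinks_circle_at_lambda_over_R(self):
        mot = MotilityParams(lam=2e-6)
        kappa = np.full(64, 1.0 / 0.1)          # convex-positive convention
        V = boundary_normal_velocity(np.zeros(64), kappa, mot)
        np.testing.assert_allclose(V, -mot.lam / 0.1)

    def test_balance_is_stationary(self):
        mot = MotilityParams(lam=2e-6)
        a = np.full(64, mot.lam / (0.1 * mot.Kprot))
        V = boundary_normal_velocity(a, np.full(64, 10.0), mot)
        np.testing.assert_allclose(V, 0.0, atol=1e-18)

    def test_tension_pure_decay_at_target_area(self):
        mot = MotilityParams(lam=3e-6)
        lam1 = tension_step(mot, mot.A0, 0.0, 0.1)
        assert lam1 == pytest.approx(mot.lam * (1 - 0.1 * mot.beta_tension))

    def test_tension_rises_when_cell_too_big(self):
        mot = MotilityParams(lam=3e-6)
        grow = tension_step(mot, 1.5 * mot.A0, 0.0, 0.1)
        decay = tension_step(mot, mot.A0, 0.0, 0.1)
        assert grow > decay

    def test_euler_matches_ode_oracle_for_frozen_inputs(self):
        mot = MotilityParams(lam=3e-6)
        A, dAdt = 1.2 * mot.A0, 0.0

        def rhs(t, y):
            lam = y[0]
            return [mot.lambda0 * lam * (A - mot.A0 + dAdt)
                    / (mot.A0 * (lam + mot.lambda0)) - mot.beta_tension * lam]
        ref = solve_ivp(rhs, (0, 10.0), [mot.lam], rtol=1e-10).y[0, -1]
        lam = mot.lam
        dt = 0.05
        m = MotilityParams(lam=lam)
        for _ in range(200):
            m = MotilityParams(lam=tension_step(m, A, dAdt, dt))
        assert m.lam == pytest.approx(ref, rel=5 * dt)


class TestNoise:
    def test_zero_volatility_relaxes_to_mean(self):
        p = NoiseParams(theta=0.5, mu=0.3, sigma=0.0)
        st = NoiseState(1.0, p, np.random.default_rng(0))
        for _ in range(2000):
            st = ou_noise_step(st, 0.05)
        assert st.eta == pytest.approx(0.3, abs=1e-6)

    def test_stationary_moments(self):
        p = NoiseParams(theta=0.1, mu=0.0, sigma=0.05 * np.sqrt(0.2))
        st = NoiseState(0.0, p, np.random.default_rng(7))
        dt = 0.5
        vals = np.empty(100_000)
        for i in range(len(vals)):
            st = ou_noise_step(st, dt)
            vals[i] = st.eta
        vals = vals[2000:]                       # discard burn-in
        sd_exact = np.sqrt(p.sigma ** 2 / (2 * p.theta) )
        se = sd_exact / np.sqrt(len(vals) / (1.0 / (p.theta * dt)))
        assert abs(vals.mean() - p.mu) < 3 * se
        assert abs(vals.std() - sd_exact) / sd_exact < 0.1

    def test_seeded_replay_deterministic(self):
        p = NoiseParams()
        a = NoiseState(0.0, p, np.random.default_rng(3))
        b = NoiseState(0.0, p, np.random.default_rng(3))
        for _ in range(50):
            a = ou_noise_step(a, 0.1)
            b = ou_noise_step(b, 0.1)
        assert a.eta == b.eta


class TestSignal:
    def test_reference_value(self):
        assert signal_term(np.array([0.15]), 0.0, 2e-2)[0] == pytest.approx(3e-3)

    def test_uniform_occupancy_uniform_signal(self):
        s = signal_term(np.full(16, 0.17), 0.05, 2e-2)
        assert np.ptp(s) == 0.0

    def test_floor_at_zero(self):
        s = signal_term(np.array([0.1]), -0.1, 2e-2)
        assert s[0] == 0.0


class TestCoupledStep:
    @pytest.fixture(scope="class")
    def small_cfg(self):
        return CellRunConfig(n_steps=5, seed=0, ns_membrane=48, h_far=0.05,
                             h_membrane=0.02, noise_on=False, perturbation=0.0)

    def test_initial_occupancy_band_and_gradient(self, small_cfg):
        lig, mein, mot = LigandParams(), MeinhardtParams(), MotilityParams()
        st = initial_cell_state(lig, mein, mot, small_cfg)
        Ro = st.ls / lig.Rtot
        assert 0.14 < Ro.min() < Ro.max() < 0.20
        g = st.mesh.loop_coords(0)
        front = Ro[np.argmax(g[:, 0])]
        back = Ro[np.argmin(g[:, 0])]
        assert front - back == pytest.approx(0.04, abs=0.01)

    def test_frozen_membrane_uniform_field_stays_uniform(self, small_cfg):
        """No membrane motion and no gradient: nothing perturbs the ligand,
        so l stays uniform and ls at equilibrium."""
        lig, mein, mot = LigandParams(gradient=0.0), MeinhardtParams(), MotilityParams()
        st = initial_cell_state(lig, mein, mot, small_cfg, gradient_on=False)
        l0, ls0 = st.l.copy(), st.ls.copy()
        for _ in range(3):
            st = advance_cell_step(st, lig, mein, mot, small_cfg,
                                   gradient_on=False, frozen_membrane=True)
        np.testing.assert_allclose(st.l, l0, rtol=1e-9)
        np.testing.assert_allclose(st.ls, ls0, rtol=1e-9)

    def test_occupancy_stays_in_bounds(self, small_cfg):
        lig, mein, mot = LigandParams(), MeinhardtParams(), MotilityParams()
        st = initial_cell_state(lig, mein, mot, small_cfg)
        for _ in range(5):
            st = advance_cell_step(st, lig, mein, mot, small_cfg)
            assert st.ls.min() >= 0.0
            assert st.ls.max() <= lig.Rtot

    def test_meinhardt_steady_state_stationary_on_fixed_circle(self, small_cfg):
        """Homogeneous kinetics at the fixed point stay put to high accuracy
        when the membrane is frozen and the signal is constant."""
        lig = LigandParams(gradient=0.0)
        mein, mot = MeinhardtParams(), MotilityParams()
        st = initial_cell_state(lig, mein, mot, small_cfg, gradient_on=False)
        a0 = st.a.copy()
        for _ in range(5):
            st = advance_cell_step(st, lig, mein, mot, small_cfg,
                                   gradient_on=False, frozen_membrane=True)
        assert np.abs(st.a - a0).max() < 1e-8
        assert np.ptp(st.a) < 1e-10


class TestSelfGeneratedGradientMechanism:
    def test_protrusion_dilutes_complex(self):
        dev, _ = run_forced_protrusion(retract=False)
        assert dev < -1e-6

    def test_retraction_enriches_complex(self):
        dev, _ = run_forced_protrusion(retract=True)
        assert dev > 1e-6
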