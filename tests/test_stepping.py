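"""Predictor / Crank-Nicolson / corrector scheme and the per-step algorithm."""

import numpy as np
import pytest

from bulksurf.assembly import FieldState, ReactionSpec, mesh_velocity
from bulksurf.mesh import DomainSpec, generate_initial_mesh
from bulksurf.stepping import (MovingMeshModel, NewtonConfig, SimulationConfig,
                               SimulationState, advance_one_step,
                               assemble_level, correct_surface,
                               far_field_defect, predict_surface, step_bulk_cn)
from bulksurf.verification import DiscExactSolution, dispersion_root


@pytest.fixture(scope="module")
def disc_ops(disc_mesh_h01):
    return assemble_level(disc_mesh_h01, ReactionSpec(D=1.0, Ds=1.0))


@pytest.fixture(scope="module")
def disc_ops_nodiff(disc_mesh_h01):
    return assemble_level(disc_mesh_h01, ReactionSpec(D=1.0, Ds=0.0))


def boundary_cos(mesh):
    g = mesh.loop_coords(0)
    return np.cos(np.arctan2(g[:, 1], g[:, 0]))


class TestPredictor:
    def test_stationary_no_reaction_identity(self, disc_mesh_h01, disc_ops_nodiff):
        cs = boundary_cos(disc_mesh_h01)
        out = predict_surface(disc_ops_nodiff, disc_ops_nodiff,
                              np.zeros(disc_mesh_h01.node_count), cs, 1e-2)
        np.testing.assert_allclose(out, cs, atol=1e-12)

    def test_pure_decay_backward_euler_algebra(self, disc_mesh_h01, disc_ops_nodiff):
        # h explicit: Cs~ = (1 - r dt) Cs exactly
        cs = boundary_cos(disc_mesh_h01)
        out = predict_surface(disc_ops_nodiff, disc_ops_nodiff,
                              np.zeros(disc_mesh_h01.node_count), cs, 1e-2,
                              h=lambda y: -0.3 * y)
        np.testing.assert_allclose(out, (1 - 0.3e-2) * cs, atol=1e-12)

    def test_circle_heat_eigenmode_decay(self, disc_mesh_h01, disc_ops):
        # cos(theta) is the eigenmode of the circle Laplace-Beltrami with
        # eigenvalue -1; one BE step gives the factor 1/(1 + dt) + O(h^2)
        cs = boundary_cos(disc_mesh_h01)
        dt = 1e-2
        out = predict_surface(disc_ops, disc_ops,
                              np.zeros(disc_mesh_h01.node_count), cs, dt)
        np.testing.assert_allclose(out, cs / (1 + dt), atol=2e-4)


class TestBulkCN:
    def test_exact_mass_conservation(self, disc_mesh_h01, disc_ops, rng):
        C0 = rng.random(disc_mesh_h01.node_count)
        spec = ReactionSpec(D=1.0, Ds=1.0)      # f = g = 0
        ops = assemble_level(disc_mesh_h01, spec)
        C1 = step_bulk_cn(ops, ops, C0, boundary_cos(disc_mesh_h01),
                          boundary_cos(disc_mesh_h01), 1e-2)
        one = np.ones(disc_mesh_h01.node_count)
        m0 = one @ (ops.M @ C0)
        assert abs(one @ (ops.M @ C1) - m0) < 1e-12 * abs(m0)

    def test_linear_reaction_newton_single_iteration(self, disc_mesh_h01, rng):
        spec = ReactionSpec(D=1.0, Ds=1.0, f=lambda c: -c,
                            df=lambda c: -np.ones_like(c))
        ops = assemble_level(disc_mesh_h01, spec)
        C0 = rng.random(disc_mesh_h01.node_count)
        # with maxit=2 the second iteration only verifies convergence
        C1 = step_bulk_cn(ops, ops, C0, np.zeros(disc_mesh_h01.boundary_node_count),
                          np.zeros(disc_mesh_h01.boundary_node_count), 1e-2,
                          newton=NewtonConfig(maxit=2))
        assert np.all(np.isfinite(C1))

    def test_ale_motion_conserves_mass(self, disc_mesh_h01, rng):
        """Pure mesh motion with u = w and f = g = 0: the conservative
        formulation keeps total bulk mass exactly."""
        interior = np.setdiff1d(np.arange(disc_mesh_h01.node_count),
                                np.concatenate(disc_mesh_h01.boundary_loops))
        p1 = disc_mesh_h01.phys_coords.copy()
        p1[interior] += 2e-3 * rng.standard_normal((len(interior), 2))
        dt = 1e-3
        w = mesh_velocity(disc_mesh_h01.phys_coords, p1, dt).nodal
        spec = ReactionSpec(D=1.0, Ds=1.0)
        u_g = w[disc_mesh_h01.boundary_loops[0]]
        ops0 = assemble_level(disc_mesh_h01, spec, w_nodal=w, u_gamma=u_g)
        ops1 = assemble_level(disc_mesh_h01.with_phys(p1), spec,
                              w_nodal=w, u_gamma=u_g)
        C0 = rng.random(disc_mesh_h01.node_count)
        cs = np.zeros(disc_mesh_h01.boundary_node_count)
        C1 = step_bulk_cn(ops0, ops1, C0, cs, cs, dt)
        one = np.ones(disc_mesh_h01.node_count)
        m0 = one @ (ops0.M @ C0)
        m1 = one @ (ops1.M @ C1)
        assert abs(m1 - m0) < 1e-11 * abs(m0)


class TestCorrector:
    def test_no_reaction_stationary_identity(self, disc_mesh_h01, disc_ops_nodiff):
        cs = boundary_cos(disc_mesh_h01)
        out = correct_surface(disc_ops_nodiff, disc_ops_nodiff,
                              np.zeros(disc_mesh_h01.node_count),
                              np.zeros(disc_mesh_h01.node_count), cs, cs, 1e-2)
        np.testing.assert_allclose(out, cs, atol=1e-12)

    def test_richardson_order_two(self, disc_mesh_h01, disc_ops):
        """Surface heat equation: predictor+corrector error vs dt halving
        shows ratio ~4 (order 2)."""
        cs0 = boundary_cos(disc_mesh_h01)
        zero = np.zeros(disc_mesh_h01.node_count)
        T = 0.08
        results = {}
        for dt in (1e-2, 5e-3, 2.5e-3):
            cs = cs0.copy()
            for _ in range(int(round(T / dt))):
                cst = predict_surface(disc_ops, disc_ops, zero, cs, dt)
                cs = correct_surface(disc_ops, disc_ops, zero, zero, cs, cst, dt)
            results[dt] = cs
        e1 = np.abs(results[1e-2] - results[2.5e-3]).max()
        e2 = np.abs(results[5e-3] - results[2.5e-3]).max()
        # e1 ~ err(dt) - err(dt/4), e2 ~ err(dt/2) - err(dt/4): ratio (1-1/16)/(1/4-1/16) = 5
        assert e1 / e2 == pytest.approx(5.0, rel=0.35)


class TestConservationWithBinding:
    def test_bulk_plus_surface_mass_exact_on_disc(self, disc_mesh_h01, rng):
        """Nonlinear receptor binding only transfers mass between bulk and
        surface: the combined total is conserved exactly on a stationary
        mesh without a far field."""
        Rtot, k1, km1 = 100.0, 1.0 / 30.0, 1.0
        spec = ReactionSpec(
            D=1.0, Ds=1e-3,
            g=lambda c, cs: k1 * (Rtot - cs) * c - km1 * cs,
            dg_dc=lambda c, cs: k1 * (Rtot - cs))
        ops = assemble_level(disc_mesh_h01, spec)
        C0 = 5.0 + rng.random(disc_mesh_h01.node_count)
        Cs0 = 10.0 * rng.random(disc_mesh_h01.boundary_node_count)
        one = np.ones(disc_mesh_h01.node_count)
        one_s = np.ones(disc_mesh_h01.boundary_node_count)
        total0 = one @ (ops.M @ C0) + one_s @ (ops.surf.Ms @ Cs0)
        dt = 0.05
        Cs_t = predict_surface(ops, ops, C0, Cs0, dt)
        C1 = step_bulk_cn(ops, ops, C0, Cs0, Cs_t, dt)
        Cs1 = correct_surface(ops, ops, C0, C1, Cs0, Cs_t, dt)
        total1 = one @ (ops.M @ C1) + one_s @ (ops.surf.Ms @ Cs1)
        assert abs(total1 - total0) < 1e-10 * abs(total0)

    def test_far_field_defect_accounts_mass_change(self, cell_annulus_mesh, rng):
        """With Dirichlet far-field rows the combined mass changes exactly by
        the replaced rows' defect (the discrete far-field flux)."""
        mesh = cell_annulus_mesh
        Rtot, k1, km1 = 1e5, 1.0 / 30.0, 1.0
        spec = ReactionSpec(
            D=10.0, Ds=1e-6,
            g=lambda c, cs: k1 * (Rtot - cs) * c - km1 * cs,
            dg_dc=lambda c, cs: k1 * (Rtot - cs))
        ops = assemble_level(mesh, spec)
        p = mesh.phys_coords
        C0 = 5.3 + 8.5 * (p[:, 0] + 0.1)
        g = mesh.loop_coords(0)
        lg = 5.3 + 8.5 * (g[:, 0] + 0.1)
        Cs0 = Rtot * lg / (lg + 30.0) * (1 + 0.05 * rng.random(len(g)))
        far = mesh.boundary_loops[1]
        vals = 5.3 + 8.5 * (p[far, 0] + 0.1)
        dt = 0.1
        Cs_t = predict_surface(ops, ops, C0, Cs0, dt)
        C1 = step_bulk_cn(ops, ops, C0, Cs0, Cs_t, dt, dirichlet=(far, vals))
        Cs1 = correct_surface(ops, ops, C0, C1, Cs0, Cs_t, dt)
        one = np.ones(mesh.node_count)
        one_s = np.ones(len(g))
        d_total = (one @ (ops.M @ C1) + one_s @ (ops.surf.Ms @ Cs1)) \
            - (one @ (ops.M @ C0) + one_s @ (ops.surf.Ms @ Cs0))
        flux = far_field_defect(ops, ops, C0, C1, Cs0, Cs_t, dt, far)
        assert d_total == pytest.approx(flux, abs=1e-8 * max(1.0, abs(d_total)))


class TestStabilityProbe:
    def test_huge_time_step_stays_bounded(self, disc_mesh_h01):
        """dt = 0.1 is enormous against the diffusive scale; the implicit
        treatment keeps the iteration bounded."""
        sol = DiscExactSolution(dispersion_root())
        p = disc_mesh_h01.phys_coords
        spec = ReactionSpec(D=1.0, Ds=1.0, g=lambda c, cs: c - cs,
                            dg_dc=lambda c, cs: np.ones_like(c))
        ops = assemble_level(disc_mesh_h01, spec)
        C = sol.bulk(p[:, 0], p[:, 1], 0.0)
        g = disc_mesh_h01.loop_coords(0)
        Cs = sol.surface(np.arctan2(g[:, 1], g[:, 0]), 0.0)
        c0 = np.abs(C).max()
        for _ in range(10):
            Cs_t = predict_surface(ops, ops, C, Cs, 0.1)
            C = step_bulk_cn(ops, ops, C, Cs, Cs_t, 0.1)
            Cs = correct_surface(ops, ops, C, C, Cs, Cs_t, 0.1)
        assert np.abs(C).max() < 2.0 * c0
        assert np.abs(Cs).max() < 2.0 * c0


class TestAdvanceOneStep:
    def test_zero_velocity_zero_reaction_noop(self, disc_mesh_h01, rng):
        model = MovingMeshModel(spec=ReactionSpec(D=1.0, Ds=0.0),
                                boundary_law=None, move_mesh=False)
        C0 = rng.random(disc_mesh_h01.node_count)
        Cs0 = rng.random(disc_mesh_h01.boundary_node_count)
        st = SimulationState(disc_mesh_h01, FieldState(C0.copy(), Cs0.copy()))
        cfg = SimulationConfig(dt=1e-2, n_steps=1)
        out = advance_one_step(st, model, cfg)
        # no diffusion on the surface, no bulk sink except diffusion of C:
        # the mesh must be untouched and Cs exactly preserved
        np.testing.assert_array_equal(out.mesh.phys_coords, disc_mesh_h01.phys_coords)
        np.testing.assert_allclose(out.fields.Cs, Cs0, atol=1e-12)
        assert out.remesh_count == 0
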