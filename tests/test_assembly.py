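"""Finite element operator assembly on bulk mesh and membrane curve."""

import numpy as np
import pytest

from bulksurf.assembly import (ALEVelocity, ReactionSpec, assemble_bulk,
                               assemble_surface, coupling_vectors,
                               mesh_velocity, surface_reaction_load)
from bulksurf.mesh import TriMesh, triangle_signed_areas
from bulksurf.stepping import assemble_level


class TestMeshVelocity:
    def test_identical_coords_zero(self, disc_mesh_h01):
        w = mesh_velocity(disc_mesh_h01.phys_coords, disc_mesh_h01.phys_coords, 0.1)
        assert not np.any(w.nodal)

    def test_rigid_translation(self, disc_mesh_h01):
        delta = np.array([0.3, 0.0])
        w = mesh_velocity(disc_mesh_h01.phys_coords,
                          disc_mesh_h01.phys_coords + delta, 0.1)
        np.testing.assert_allclose(w.nodal,
                                   np.broadcast_to(delta / 0.1, w.nodal.shape),
                                   atol=1e-12)

    def test_small_rotation_speed(self, disc_mesh_h01):
        eps = 1e-4
        R = np.array([[np.cos(eps), -np.sin(eps)], [np.sin(eps), np.cos(eps)]])
        p0 = disc_mesh_h01.phys_coords
        w = mesh_velocity(p0, p0 @ R.T, 1.0)
        speed = np.linalg.norm(w.nodal, axis=1)
        r = np.linalg.norm(p0, axis=1)
        mask = r > 0.1
        np.testing.assert_allclose(speed[mask], eps * r[mask], rtol=1e-3)

    def test_mismatched_shapes_raise(self, disc_mesh_h01):
        with pytest.raises(ValueError):
            mesh_velocity(disc_mesh_h01.phys_coords,
                          disc_mesh_h01.phys_coords[:-1], 0.1)


class TestBulkAssembly:
    def test_single_triangle_mass_matrix(self):
        coords = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 3.0]])
        m = TriMesh(coords, coords.copy(), np.array([[0, 1, 2]]), [np.arange(3)])
        M, K, B, _ = assemble_bulk(m, None, ReactionSpec())
        area = 3.0
        expect = area / 12.0 * np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]])
        np.testing.assert_allclose(M.toarray(), expect, atol=1e-14)

    def test_stiffness_annihilates_constants(self, disc_mesh_h01):
        _, K, _, _ = assemble_bulk(disc_mesh_h01, None, ReactionSpec(D=2.5))
        assert np.abs(K @ np.ones(disc_mesh_h01.node_count)).max() < 1e-12

    def test_zero_velocity_gives_zero_B(self, disc_mesh_h01):
        w = ALEVelocity(np.zeros_like(disc_mesh_h01.phys_coords))
        _, _, B, _ = assemble_bulk(disc_mesh_h01, w, ReactionSpec())
        assert B.nnz == 0

    def test_B_row_sums_vanish(self, disc_mesh_h01, rng):
        # 1'B = 0 (gradients of the partition of unity): the property behind
        # exact mass conservation under ALE motion
        w = ALEVelocity(rng.standard_normal(disc_mesh_h01.phys_coords.shape))
        _, _, B, _ = assemble_bulk(disc_mesh_h01, w, ReactionSpec())
        col = np.ones(disc_mesh_h01.node_count) @ B
        assert np.abs(col).max() < 1e-12

    def test_mass_total_equals_area_and_length(self, disc_mesh_h01):
        ops = assemble_level(disc_mesh_h01, ReactionSpec())
        one = np.ones(disc_mesh_h01.node_count)
        area = triangle_signed_areas(disc_mesh_h01.phys_coords,
                                     disc_mesh_h01.triangles).sum()
        assert one @ (ops.M @ one) == pytest.approx(area, abs=1e-12)
        ones_s = np.ones(disc_mesh_h01.boundary_node_count)
        g = disc_mesh_h01.loop_coords(0)
        length = np.linalg.norm(np.roll(g, -1, axis=0) - g, axis=1).sum()
        assert ones_s @ (ops.surf.Ms @ ones_s) == pytest.approx(length, abs=1e-12)

    def test_reaction_load_quadrature_exact_for_linear_f(self, disc_mesh_h01):
        # f(c) = 2c with linear c: F_i = 2 * (M c)_i exactly
        spec = ReactionSpec(f=lambda c: 2.0 * c, df=lambda c: 2.0 * np.ones_like(c))
        p = disc_mesh_h01.phys_coords
        c = 1.0 + p[:, 0] - 0.5 * p[:, 1]
        M, _, _, F = assemble_bulk(disc_mesh_h01, None, spec, C=c)
        np.testing.assert_allclose(F, 2.0 * (M @ c), atol=1e-12)


class TestSurfaceAssembly:
    def test_uniform_segment_mass(self):
        # square membrane: each segment contributes (l/6)[[2,1],[1,2]]
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        m = TriMesh(coords, coords.copy(),
                    np.array([[0, 1, 2], [0, 2, 3]]), [np.arange(4)])
        surf = assemble_surface(m, None, None, ReactionSpec(Ds=1.0))
        Ms = surf.Ms.toarray()
        assert Ms[0, 0] == pytest.approx(2 * 2.0 / 6.0)   # two adjacent segments
        assert Ms[0, 1] == pytest.approx(1.0 / 6.0)

    def test_surface_stiffness_annihilates_constants(self, disc_mesh_h01):
        surf = assemble_level(disc_mesh_h01, ReactionSpec(Ds=3.0)).surf
        ns = disc_mesh_h01.boundary_node_count
        assert np.abs(surf.Ks @ np.ones(ns)).max() < 1e-12

    def test_u_equals_w_kills_advection(self, disc_mesh_h01, rng):
        g = disc_mesh_h01.loop_coords(0)
        u = rng.standard_normal(g.shape)
        surf = assemble_surface(disc_mesh_h01, u, u, ReactionSpec())
        assert surf.As.nnz == 0
        assert surf.A_bulk.nnz == 0

    def test_advection_operators_nonzero_when_u_differs(self, disc_mesh_h01, rng):
        g = disc_mesh_h01.loop_coords(0)
        u = rng.standard_normal(g.shape)
        surf = assemble_surface(disc_mesh_h01, u, None, ReactionSpec())
        assert surf.As.nnz > 0
        assert surf.A_bulk.nnz > 0

    def test_coupling_vector_total_is_curve_integral(self, disc_mesh_h01):
        # sum_i Ds_i = int g ds by the partition of unity; for g = 1 this is
        # the membrane length
        spec = ReactionSpec(g=lambda c, cs: np.ones_like(c),
                            dg_dc=lambda c, cs: np.zeros_like(c))
        surf = assemble_level(disc_mesh_h01, spec).surf
        ns = disc_mesh_h01.boundary_node_count
        Dv, Dsv = coupling_vectors(surf, spec, np.zeros(disc_mesh_h01.node_count),
                                   np.zeros(ns))
        assert Dsv.sum() == pytest.approx(surf.total_length(), rel=1e-12)
        assert Dv.sum() == pytest.approx(surf.total_length(), rel=1e-12)

    def test_surface_reaction_load_linear(self, disc_mesh_h01, rng):
        surf = assemble_level(disc_mesh_h01, ReactionSpec()).surf
        cs = rng.random(disc_mesh_h01.boundary_node_count)
        H = surface_reaction_load(surf, lambda y: -0.25 * y, cs)
        np.testing.assert_allclose(H, -0.25 * (surf.Ms @ cs), atol=1e-12)


class TestGeometricConservation:
    def test_discrete_reynolds_identity(self, disc_mesh_h01, rng):
        """(1'M^{n+1}v - 1'M^n v)/dt matches int v div(w) on the midpoint
        mesh to O(dt)."""
        import bulksurf.assembly as A
        interior = np.setdiff1d(np.arange(disc_mesh_h01.node_count),
                                np.concatenate(disc_mesh_h01.boundary_loops))
        p1 = disc_mesh_h01.phys_coords.copy()
        p1[interior] += 1e-3 * rng.standard_normal((len(interior), 2))
        dt = 1e-3
        w = mesh_velocity(disc_mesh_h01.phys_coords, p1, dt)
        spec = ReactionSpec()
        M0, _, _, _ = assemble_bulk(disc_mesh_h01, None, spec)
        M1, _, _, _ = assemble_bulk(disc_mesh_h01.with_phys(p1), None, spec)
        v = rng.random(disc_mesh_h01.node_count)
        one = np.ones(disc_mesh_h01.node_count)
        lhs = (one @ (M1 @ v) - one @ (M0 @ v)) / dt
        mid = disc_mesh_h01.with_phys(0.5 * (disc_mesh_h01.phys_coords + p1))
        grads, areas = A._phys_gradients(mid)
        divw = np.einsum("ekd,ekd->e", w.nodal[mid.triangles], grads)
        rhs = (divw * v[mid.triangles].mean(axis=1) * areas).sum()
        assert lhs == pytest.approx(rhs, abs=dt * max(1.0, abs(rhs)))
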