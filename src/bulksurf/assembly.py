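"""P1 finite element operators for the conservative ALE bulk-surface system.

Assembles, on the current physical mesh, the matrices and vectors of the
semi-discrete system

    d/dt (M C)  + [K + A - B] C + D(C, Cs) = F(C)          (bulk)
    d/dt (Ms Cs) + [Ks + As] Cs = Ds(C, Cs) + H(Cs)        (surface)

with   M_ij  = int_Omega  phi_i phi_j,
       K_ij  = D int_Omega grad phi_i . grad phi_j,
       B_ij  = -int_Omega (w . grad phi_i) phi_j,
       A_ij  = int_Gamma [(u - w) . n] phi_i phi_j,
       D_i   = int_Gamma [g(c, cs) - (u . n) c] phi_i,
       F_i   = int_Omega f(c) phi_i,
and the curve analogues (Ms, Ks with the arc-length gradient, As with the
tangential divergence of (u - w), Ds from g and H from h).  Mass and
stiffness products of P1 functions are integrated exactly; nonlinear
reaction integrands use a 3-point (bulk) / 2-point Gauss (curve) rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp

from .mesh import TriMesh


@dataclass
class FieldState:
    """Nodal bulk (C) and surface (Cs) concentrations at one time level."""

    C: np.ndarray
    Cs: np.ndarray
    t: float = 0.0

    def copy(self) -> "FieldState":
        return FieldState(self.C.copy(), self.Cs.copy(), self.t)


@dataclass
class ReactionSpec:
    """Kinetics of one coupled bulk-surface pair.

    f(c): bulk reaction rate; g(c, cs): surface reaction / flux coupling;
    h(cs): surface-only reaction.  ``df`` and ``dg_dc`` are the derivatives
    needed by the Newton solve of the bulk Crank-Nicolson step.
    """

    D: float = 1.0
    Ds: float = 1.0
    f: Callable | None = None
    df: Callable | None = None
    g: Callable | None = None
    dg_dc: Callable | None = None
    h: Callable | None = None

    def __post_init__(self):
        if self.D < 0 or self.Ds < 0:
            raise ValueError("diffusion coefficients must be nonnegative")


@dataclass
class ALEVelocity:
    """Nodal mesh velocity, piecewise constant over the time slab."""

    w: np.ndarray

    @property
    def nodal(self) -> np.ndarray:
        return self.w


def mesh_velocity(coords_n: np.ndarray, coords_np1: np.ndarray, dt: float) -> ALEVelocity:
    """Discrete ALE velocity (x^{n+1} - x^n) / dt, node-wise; no smoothing."""
    coords_n = np.asarray(coords_n, float)
    coords_np1 = np.asarray(coords_np1, float)
    if coords_n.shape != coords_np1.shape:
        raise ValueError("mismatched meshes: node counts differ")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return ALEVelocity((coords_np1 - coords_n) / dt)


# ---------------------------------------------------------------------------
# bulk assembly
# ---------------------------------------------------------------------------

_MHAT = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
# 3-point rule at edge midpoints: exact for quadratics
_QP_BARY = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5]])


def _phys_gradients(mesh: TriMesh):
    """Per-element physical P1 basis gradients and triangle areas."""
    tri = mesh.triangles
    p = mesh.phys_coords
    p0, p1, p2 = p[tri[:, 0]], p[tri[:, 1]], p[tri[:, 2]]
    e1 = p1 - p0
    e2 = p2 - p0
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    area = 0.5 * det
    g = np.empty((len(tri), 3, 2))
    g[:, 1, 0] = e2[:, 1] / det
    g[:, 1, 1] = -e2[:, 0] / det
    g[:, 2, 0] = -e1[:, 1] / det
    g[:, 2, 1] = e1[:, 0] / det
    g[:, 0] = -g[:, 1] - g[:, 2]
    return g, area


def _scatter(loc: np.ndarray, tri: np.ndarray, n: int) -> sp.csr_matrix:
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    return sp.csr_matrix((loc.ravel(), (rows, cols)), shape=(n, n))


def assemble_bulk(mesh: TriMesh, w: ALEVelocity | None, spec: ReactionSpec,
                  C: np.ndarray | None = None):
    """Bulk mass, stiffness and ALE matrices, and the reaction load F(C).

    Returns (M, K, B, F) with F None when spec.f is None.  A and the coupling
    vector D live on the membrane rows and are assembled by
    :func:`assemble_surface`.
    """
    tri = mesh.triangles
    n = mesh.node_count
    grads, area = _phys_gradients(mesh)

    M_loc = area[:, None, None] * _MHAT
    M = _scatter(M_loc, tri, n)

    K_loc = spec.D * area[:, None, None] * np.einsum("eik,ejk->eij", grads, grads)
    K = _scatter(K_loc, tri, n)

    if w is None or not np.any(w.nodal):
        B = sp.csr_matrix((n, n))
    else:
        W = w.nodal[tri]                       # (E,3,2)
        # B_loc[i,j] = -grad(phi_i) . sum_k W_k Mhat[k,j] * area
        T = np.einsum("ekd,kj->ejd", W, _MHAT)  # (E,3(j),2)
        B_loc = -np.einsum("eid,ejd->eij", grads, T) * area[:, None, None]
        B = _scatter(B_loc, tri, n)

    F = None
    if spec.f is not None and C is not None:
        cq = C[tri] @ _QP_BARY.T               # (E,3q) values at quadrature pts
        fq = spec.f(cq)
        # F_i = sum_q (area/3) f(c_q) phi_i(q)
        F_loc = (area[:, None] / 3.0) * (fq @ _QP_BARY)   # (E,3)
        F = np.zeros(n)
        np.add.at(F, tri.ravel(), F_loc.ravel())
    return M, K, B, F


def bulk_reaction_load(mesh: TriMesh, spec: ReactionSpec, C: np.ndarray) -> np.ndarray:
    """F(C) alone (quadrature of f(c_h) phi_i)."""
    tri = mesh.triangles
    grads, area = _phys_gradients(mesh)
    cq = C[tri] @ _QP_BARY.T
    fq = spec.f(cq)
    F_loc = (area[:, None] / 3.0) * (fq @ _QP_BARY)
    F = np.zeros(mesh.node_count)
    np.add.at(F, tri.ravel(), F_loc.ravel())
    return F


def bulk_reaction_jacobian(mesh: TriMesh, spec: ReactionSpec, C: np.ndarray) -> sp.csr_matrix:
    """d F / d C: quadrature of f'(c_h) phi_i phi_j."""
    tri = mesh.triangles
    grads, area = _phys_gradients(mesh)
    cq = C[tri] @ _QP_BARY.T
    dfq = spec.df(cq)                           # (E,3q)
    loc = np.einsum("eq,qi,qj->eij", dfq, _QP_BARY, _QP_BARY) * (area[:, None, None] / 3.0)
    return _scatter(loc, tri, mesh.node_count)


# ---------------------------------------------------------------------------
# surface (membrane curve) assembly
# ---------------------------------------------------------------------------

_G2 = np.array([0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)])  # 2-pt Gauss on [0,1]


@dataclass
class SurfaceOperators:
    """Periodic 1D P1 operators on the membrane polygon plus bulk couplings."""

    Ms: sp.csr_matrix
    Ks: sp.csr_matrix
    As: sp.csr_matrix
    A_bulk: sp.csr_matrix            # membrane rows of the bulk boundary matrix
    loop: np.ndarray                 # bulk node indices along the loop
    seg_len: np.ndarray
    # geometry cached for load evaluations
    _coords: np.ndarray = field(repr=False, default=None)
    _u: np.ndarray = field(repr=False, default=None)
    _w: np.ndarray = field(repr=False, default=None)
    _n_bulk: int = 0

    def total_length(self) -> float:
        return float(self.seg_len.sum())


def _loop_segments(coords):
    nxt = np.roll(np.arange(len(coords)), -1)
    vec = coords[nxt] - coords
    L = np.linalg.norm(vec, axis=1)
    tang = vec / L[:, None]
    norm = np.column_stack([tang[:, 1], -tang[:, 0]])
    return nxt, vec, L, tang, norm


def _periodic_scatter(vals_loc, ns):
    """Scatter (S,2,2) segment blocks into a periodic 1D P1 csr matrix."""
    i = np.arange(ns)
    j = np.roll(i, -1)
    rows = np.concatenate([i, i, j, j])
    cols = np.concatenate([i, j, i, j])
    data = np.concatenate([vals_loc[:, 0, 0], vals_loc[:, 0, 1],
                           vals_loc[:, 1, 0], vals_loc[:, 1, 1]])
    return sp.csr_matrix((data, (rows, cols)), shape=(ns, ns))


def assemble_surface(mesh: TriMesh, u_gamma: np.ndarray | None,
                     w_gamma: np.ndarray | None, spec: ReactionSpec,
                     loop_index: int = 0) -> SurfaceOperators:
    """Assemble the curve operators Ms, Ks, As and the bulk boundary matrix A.

    ``u_gamma`` and ``w_gamma`` are the material and mesh velocities at the
    membrane nodes (None means zero).  The tangential divergence of (u - w)
    on the polygon is the arc-length derivative of its tangential component,
    segment-wise constant.
    """
    loop = mesh.boundary_loops[loop_index]
    coords = mesh.phys_coords[loop]
    ns = len(loop)
    if ns < 3:
        raise ValueError("membrane loop must be closed with >= 3 nodes")
    nxt, vec, L, tang, norm = _loop_segments(coords)

    Ms = _periodic_scatter(L[:, None, None] * np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0, ns)
    Ks = _periodic_scatter(spec.Ds / L[:, None, None] * np.array([[1.0, -1.0], [-1.0, 1.0]]), ns)

    v = None
    if u_gamma is not None or w_gamma is not None:
        u_ = np.zeros((ns, 2)) if u_gamma is None else np.asarray(u_gamma, float)
        w_ = np.zeros((ns, 2)) if w_gamma is None else np.asarray(w_gamma, float)
        v = u_ - w_

    if v is None or not np.any(v):
        As = sp.csr_matrix((ns, ns))
        A_bulk = sp.csr_matrix((mesh.node_count, mesh.node_count))
    else:
        v1 = v
        v2 = v[nxt]
        p1 = (v1 * tang).sum(axis=1)            # tangential component at ends
        p2 = (v2 * tang).sum(axis=1)
        div = (p2 - p1) / L                      # segment-wise tangential divergence
        loc = div[:, None, None] * L[:, None, None] * np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0
        # advection: [(u-w) . grad_G phi_j] phi_i, grad_G phi_1 = -t/L, phi_2 = +t/L
        I1 = L * (2.0 * p1 + p2) / 6.0          # int (v.t) phi_1 ds
        I2 = L * (p1 + 2.0 * p2) / 6.0
        adv = np.empty((ns, 2, 2))
        adv[:, 0, 0] = -I1 / L
        adv[:, 0, 1] = I1 / L
        adv[:, 1, 0] = -I2 / L
        adv[:, 1, 1] = I2 / L
        As = _periodic_scatter(loc + adv, ns)

        q1 = (v1 * norm).sum(axis=1)
        q2 = (v2 * norm).sum(axis=1)
        # 2-point Gauss of [(u-w).n] phi_i phi_j on each segment
        blocks = np.zeros((ns, 2, 2))
        for gp in _G2:
            qv = (1 - gp) * q1 + gp * q2
            phi = np.array([1 - gp, gp])
            blocks += 0.5 * L[:, None, None] * qv[:, None, None] * \
                np.outer(phi, phi)[None]
        rows = np.concatenate([loop, loop, loop[nxt], loop[nxt]])
        cols = np.concatenate([loop, loop[nxt], loop, loop[nxt]])
        data = np.concatenate([blocks[:, 0, 0], blocks[:, 0, 1],
                               blocks[:, 1, 0], blocks[:, 1, 1]])
        A_bulk = sp.csr_matrix((data, (rows, cols)),
                               shape=(mesh.node_count, mesh.node_count))

    return SurfaceOperators(Ms, Ks, As, A_bulk, loop.copy(), L,
                            _coords=coords,
                            _u=(None if u_gamma is None else np.asarray(u_gamma, float)),
                            _w=(None if w_gamma is None else np.asarray(w_gamma, float)),
                            _n_bulk=mesh.node_count)


def _gauss_assemble(L, fvals_at_gauss):
    """Accumulate int f phi_i ds per segment from Gauss-point values -> (S,2)."""
    out = np.zeros((len(L), 2))
    for k, gp in enumerate(_G2):
        out[:, 0] += 0.5 * L * fvals_at_gauss[k] * (1 - gp)
        out[:, 1] += 0.5 * L * fvals_at_gauss[k] * gp
    return out


def coupling_vectors(surf: SurfaceOperators, spec: ReactionSpec,
                     C: np.ndarray, Cs: np.ndarray):
    """(D_vec, Ds_vec): bulk rows of int[g - (u.n) c] phi ds and int g phi ds.

    The fields c|Gamma, cs and u are interpolated P1 along each segment and g
    is evaluated at the 2-point Gauss nodes of the interpolants.
    """
    ns = len(surf.loop)
    nxt = np.roll(np.arange(ns), -1)
    cG = C[surf.loop]
    L = surf.seg_len
    coords = surf._coords
    vecs = coords[nxt] - coords
    tang = vecs / L[:, None]
    norm = np.column_stack([tang[:, 1], -tang[:, 0]])
    if surf._u is not None and np.any(surf._u):
        u1 = (surf._u * norm).sum(axis=1)
        u2 = (surf._u[nxt] * norm).sum(axis=1)
    else:
        u1 = u2 = np.zeros(ns)

    gq, dq = [], []
    for gp in _G2:
        cq = (1 - gp) * cG + gp * cG[nxt]
        csq = (1 - gp) * Cs + gp * Cs[nxt]
        unq = (1 - gp) * u1 + gp * u2
        gval = spec.g(cq, csq)
        gq.append(gval)
        dq.append(gval - unq * cq)
    gs = _gauss_assemble(L, gq)
    Ds_vec = np.zeros(ns)
    np.add.at(Ds_vec, np.arange(ns), gs[:, 0])
    np.add.at(Ds_vec, nxt, gs[:, 1])

    ds = _gauss_assemble(L, dq)
    Dloc = np.zeros(ns)
    np.add.at(Dloc, np.arange(ns), ds[:, 0])
    np.add.at(Dloc, nxt, ds[:, 1])
    D_vec = np.zeros(surf._n_bulk)
    D_vec[surf.loop] = Dloc
    return D_vec, Ds_vec


def coupling_jacobian(surf: SurfaceOperators, spec: ReactionSpec,
                      C: np.ndarray, Cs: np.ndarray) -> sp.csr_matrix:
    """d D_vec / d C on the membrane rows: int [dg/dc - (u.n)] phi_i phi_j ds."""
    ns = len(surf.loop)
    nxt = np.roll(np.arange(ns), -1)
    cG = C[surf.loop]
    L = surf.seg_len
    coords = surf._coords
    vecs = coords[nxt] - coords
    tang = vecs / L[:, None]
    norm = np.column_stack([tang[:, 1], -tang[:, 0]])
    if surf._u is not None and np.any(surf._u):
        u1 = (surf._u * norm).sum(axis=1)
        u2 = (surf._u[nxt] * norm).sum(axis=1)
    else:
        u1 = u2 = np.zeros(ns)
    blocks = np.zeros((ns, 2, 2))
    for gp in _G2:
        cq = (1 - gp) * cG + gp * cG[nxt]
        csq = (1 - gp) * Cs + gp * Cs[nxt]
        kv = spec.dg_dc(cq, csq) - ((1 - gp) * u1 + gp * u2)
        phi = np.array([1 - gp, gp])
        blocks += 0.5 * L[:, None, None] * kv[:, None, None] * np.outer(phi, phi)[None]
    rows = np.concatenate([surf.loop, surf.loop, surf.loop[nxt], surf.loop[nxt]])
    cols = np.concatenate([surf.loop, surf.loop[nxt], surf.loop, surf.loop[nxt]])
    data = np.concatenate([blocks[:, 0, 0], blocks[:, 0, 1],
                           blocks[:, 1, 0], blocks[:, 1, 1]])
    return sp.csr_matrix((data, (rows, cols)), shape=(surf._n_bulk, surf._n_bulk))


def surface_reaction_load(surf: SurfaceOperators, h: Callable,
                          Cs: np.ndarray) -> np.ndarray:
    """H_i = int h(cs_h) phi_i ds, 2-point Gauss with cs interpolated P1."""
    ns = len(surf.loop)
    nxt = np.roll(np.arange(ns), -1)
    hq = [h((1 - gp) * Cs + gp * Cs[nxt]) for gp in _G2]
    hs = _gauss_assemble(surf.seg_len, hq)
    H = np.zeros(ns)
    np.add.at(H, np.arange(ns), hs[:, 0])
    np.add.at(H, nxt, hs[:, 1])
    return H
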