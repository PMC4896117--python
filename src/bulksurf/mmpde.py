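"""Winslow-monitor moving-mesh PDE for the bulk (interior) nodes.

Interior nodes of the physical mesh are moved by a gradient-flow moving-mesh
PDE whose steady state equidistributes the Winslow monitor matrix
G = diag(M, M): writing the physical coordinates x(xi, eta) over the fixed
computational (reference) triangulation, the semi-discrete equations read

    (tau / P) dx/dt = a x_xixi + b x_xieta + c x_etaeta + d x_xi + e x_eta,

with coefficients built from the P1 map gradients and the monitor M.  The
equation is discretised with linear Galerkin elements on the reference mesh
and a backward Euler step whose coefficients are lagged at the old time level;
boundary node positions (from the curve solver) enter as Dirichlet data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TriMesh, TangledMeshError, triangle_signed_areas


@dataclass
class MonitorField:
    """Positive weight function M(x, y, t) steering mesh density."""

    func: Callable[[np.ndarray, np.ndarray, float], np.ndarray]

    def nodal(self, mesh: TriMesh, t: float) -> np.ndarray:
        p = mesh.phys_coords
        M = np.asarray(self.func(p[:, 0], p[:, 1], t), float)
        M = np.broadcast_to(M, (len(p),)).copy()
        if np.any(M <= 0):
            raise ValueError("monitor function must be positive")
        return M


def uniform_monitor() -> MonitorField:
    return MonitorField(lambda x, y, t: np.ones_like(x))


def wave_monitor(x, y, t):
    """Travelling-wave monitor 1 + sech^2((x + t - 0.7)/0.6), in (1, 2]."""
    z = np.abs((np.asarray(x) + t - 0.7) / 0.6)
    sech = 2.0 * np.exp(-z) / (1.0 + np.exp(-2.0 * z))
    return 1.0 + sech ** 2


def wave_monitor_field() -> MonitorField:
    return MonitorField(lambda x, y, t: wave_monitor(x, y, t))


@dataclass
class MMPDECoefficients:
    """Coefficients of the moving-mesh equation and the map Jacobian.

    ``ca .. ce`` are element-wise values (used for inspection and for the
    first-order terms); ``ca_n, cb_n, cc_n`` are area-weighted nodal
    recoveries of the second-order coefficients.  The recovered fields matter
    because the operator is in non-divergence form: the weak form contains
    (a v)_xi, so the in-element gradient of a contributes and dropping it
    (element-constant coefficients) turns the first-order remainder
    antidiffusive.
    """

    ca: np.ndarray
    cb: np.ndarray
    cc: np.ndarray
    cd: np.ndarray
    ce: np.ndarray
    J: np.ndarray
    ca_n: np.ndarray | None = None
    cb_n: np.ndarray | None = None
    cc_n: np.ndarray | None = None


def _p1_ref_gradients(mesh: TriMesh):
    """Per-element gradients of the P1 basis w.r.t. reference coordinates.

    Returns (grads, ref_areas): grads[e, i, :] = (d phi_i/d xi, d phi_i/d eta).
    """
    tri = mesh.triangles
    xi = mesh.ref_coords
    p0, p1, p2 = xi[tri[:, 0]], xi[tri[:, 1]], xi[tri[:, 2]]
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


def _map_gradients(mesh: TriMesh, grads):
    """Element-wise x_xi, x_eta, y_xi, y_eta of the discrete ALE map."""
    tri = mesh.triangles
    x = mesh.phys_coords[:, 0][tri]          # (E,3)
    y = mesh.phys_coords[:, 1][tri]
    x_xi = (x * grads[:, :, 0]).sum(axis=1)
    x_eta = (x * grads[:, :, 1]).sum(axis=1)
    y_xi = (y * grads[:, :, 0]).sum(axis=1)
    y_eta = (y * grads[:, :, 1]).sum(axis=1)
    return x_xi, x_eta, y_xi, y_eta


def _recover_elem_to_nodes(mesh: TriMesh, elem_vals: np.ndarray,
                           ref_areas: np.ndarray) -> np.ndarray:
    """Area-weighted recovery of an element-wise field to the nodes."""
    tri = mesh.triangles
    acc = np.zeros(mesh.node_count)
    wts = np.zeros(mesh.node_count)
    for i in range(3):
        np.add.at(acc, tri[:, i], elem_vals * ref_areas)
        np.add.at(wts, tri[:, i], ref_areas)
    return acc / wts


def _recovered_ref_gradient(mesh: TriMesh, nodal: np.ndarray, grads, ref_areas):
    """Area-weighted nodal recovery of the reference-coordinate gradient."""
    tri = mesh.triangles
    vals = nodal[tri]                         # (E,3)
    gx = (vals * grads[:, :, 0]).sum(axis=1)  # element-wise d/dxi
    gy = (vals * grads[:, :, 1]).sum(axis=1)
    acc = np.zeros((mesh.node_count, 2))
    wts = np.zeros(mesh.node_count)
    for i in range(3):
        np.add.at(acc[:, 0], tri[:, i], gx * ref_areas)
        np.add.at(acc[:, 1], tri[:, i], gy * ref_areas)
        np.add.at(wts, tri[:, i], ref_areas)
    return acc / wts[:, None]


def mmpde_coefficients(mesh: TriMesh, monitor: MonitorField, t: float) -> MMPDECoefficients:
    """Element-wise coefficients a..e and Jacobian J of the map x(xi)."""
    grads, ref_areas = _p1_ref_gradients(mesh)
    x_xi, x_eta, y_xi, y_eta = _map_gradients(mesh, grads)
    J = x_xi * y_eta - x_eta * y_xi
    if np.any(J <= 0):
        raise TangledMeshError("non-positive map Jacobian")
    Mn = monitor.nodal(mesh, t)
    Me = Mn[mesh.triangles].mean(axis=1)
    gM = _recovered_ref_gradient(mesh, Mn, grads, ref_areas)
    gMe = gM[mesh.triangles].mean(axis=1)     # (E,2): (M_xi, M_eta)
    M_xi, M_eta = gMe[:, 0], gMe[:, 1]

    g11 = x_eta ** 2 + y_eta ** 2
    g12 = x_xi * x_eta + y_xi * y_eta
    g22 = x_xi ** 2 + y_xi ** 2
    ca = g11 / (Me * J ** 2)
    cb = -2.0 * g12 / (Me * J ** 2)
    cc = g22 / (Me * J ** 2)
    cd = (M_xi * g11 - M_eta * g12) / (Me * J) ** 2
    ce = (-M_xi * g12 + M_eta * g22) / (Me * J) ** 2
    return MMPDECoefficients(
        ca, cb, cc, cd, ce, J,
        ca_n=_recover_elem_to_nodes(mesh, ca, ref_areas),
        cb_n=_recover_elem_to_nodes(mesh, cb, ref_areas),
        cc_n=_recover_elem_to_nodes(mesh, cc, ref_areas))


def mmpde_step(mesh: TriMesh, boundary_positions: np.ndarray,
               monitor: MonitorField, t: float, dt: float, tau: float = 1e-4,
               P: Callable[[np.ndarray], np.ndarray] | None = None) -> TriMesh:
    """One backward-Euler step of the bulk moving-mesh equation.

    ``boundary_positions`` gives the new physical positions of all boundary
    nodes (concatenated in boundary-loop order) and is imposed as Dirichlet
    data.  Coefficients are evaluated on the old mesh at time t.  ``P`` maps
    element monitor values to the balancing factor (default 1/M, giving a
    spatially uniform adaptation time scale).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    coef = mmpde_coefficients(mesh, monitor, t)
    grads, ref_areas = _p1_ref_gradients(mesh)
    tri = mesh.triangles
    n = mesh.node_count

    Mn = monitor.nodal(mesh, t)
    Me = Mn[tri].mean(axis=1)
    P_e = (1.0 / Me) if P is None else np.asarray(P(Me), float)

    # second-order terms with P1 coefficient fields: the weak form keeps the
    # coefficients inside the test-function derivative, (a v)_xi etc., so each
    # element contributes both a mean-coefficient stiffness part and a
    # coefficient-gradient part  x_xi . (a_xi v) -> grad(a)|_e * int(phi_i)
    gxi = grads[:, :, 0]
    geta = grads[:, :, 1]
    tri_ = tri
    a_n, b_n, c_n = coef.ca_n[tri_], coef.cb_n[tri_], coef.cc_n[tri_]   # (E,3)
    a_bar, b_bar, c_bar = a_n.mean(axis=1), b_n.mean(axis=1), c_n.mean(axis=1)
    a_xi = (a_n * gxi).sum(axis=1)
    b_xi = (b_n * gxi).sum(axis=1)
    b_eta = (b_n * geta).sum(axis=1)
    c_eta = (c_n * geta).sum(axis=1)
    A_loc = (a_bar[:, None, None] * gxi[:, :, None] * gxi[:, None, :]
             + c_bar[:, None, None] * geta[:, :, None] * geta[:, None, :]
             + 0.5 * b_bar[:, None, None] * (gxi[:, :, None] * geta[:, None, :]
                                             + geta[:, :, None] * gxi[:, None, :]))
    A_loc *= ref_areas[:, None, None]
    # coefficient-gradient part: rows i get int(phi_i) = A/3 times
    # (a_xi x_xi + c_eta x_eta + (b/2)_eta x_xi + (b/2)_xi x_eta)
    gc = (a_xi[:, None] * gxi + 0.5 * b_eta[:, None] * gxi
          + c_eta[:, None] * geta + 0.5 * b_xi[:, None] * geta)   # (E,3): per trial j
    G_loc = gc[:, None, :] * (ref_areas / 3.0)[:, None, None] * np.ones((1, 3, 1))
    A_loc = A_loc + G_loc
    # convection terms -(d x_xi + e x_eta) . v
    C_loc = -(coef.cd[:, None, None] * gxi[:, None, :]
              + coef.ce[:, None, None] * geta[:, None, :]) \
        * (ref_areas / 3.0)[:, None, None] * np.ones((1, 3, 1))
    # scaled consistent mass (tau / (P dt))
    Mhat = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
    M_loc = (tau / (P_e * dt))[:, None, None] * ref_areas[:, None, None] * Mhat

    loc = M_loc + A_loc + C_loc
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    mass = sp.csr_matrix((M_loc.ravel(), (rows, cols)), shape=(n, n))

    rhs = np.column_stack([mass @ mesh.phys_coords[:, 0],
                           mass @ mesh.phys_coords[:, 1]])

    bidx = np.concatenate(mesh.boundary_loops)
    bpos = np.asarray(boundary_positions, float)
    if bpos.shape != (len(bidx), 2):
        raise ValueError("boundary_positions must match boundary node count")
    # Dirichlet row replacement, done at the COO stage for speed
    is_bnd = np.zeros(n, bool)
    is_bnd[bidx] = True
    vals = loc.ravel()
    keep = ~is_bnd[rows]
    lhs = sp.csr_matrix(
        (np.concatenate([vals[keep], np.ones(len(bidx))]),
         (np.concatenate([rows[keep], bidx]), np.concatenate([cols[keep], bidx]))),
        shape=(n, n)).tocsc()
    rhs[bidx] = bpos

    lu = spla.splu(lhs)
    new_phys = np.column_stack([lu.solve(rhs[:, 0]), lu.solve(rhs[:, 1])])
    if np.any(triangle_signed_areas(new_phys, tri) <= 0):
        raise TangledMeshError("mesh tangled after moving-mesh step")
    return mesh.with_phys(new_phys)
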