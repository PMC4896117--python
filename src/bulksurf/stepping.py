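"""Three-step temporal scheme and the per-step moving-mesh algorithm.

Each time step advances the coupled bulk-surface pair with

1. a semi-implicit backward-Euler *predictor* for the surface species
   (diffusion and mesh-movement terms implicit, reactions and coupling
   explicit),
2. a Crank-Nicolson step for the bulk species, nonlinear in C^{n+1} through
   the reaction F and the coupling D (solved by Newton with the analytic
   Jacobian), the new coupling being evaluated at the *predicted* surface
   values, and
3. a linear Crank-Nicolson *correction* for the surface species that
   restores second-order temporal accuracy.

The full moving-mesh algorithm interleaves these solves with the curve
update, the bulk moving-mesh step and quality-triggered remeshing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import assembly as asm
from . import curve as cv
from . import mesh as msh
from . import mmpde as mm

logger = logging.getLogger(__name__)


class SolverError(Exception):
    pass


class NewtonNonConvergenceError(SolverError):
    def __init__(self, history):
        super().__init__(f"Newton iteration did not converge; residual history {history}")
        self.history = history


@dataclass
class NewtonConfig:
    tol: float = 1e-10           # max-norm of the update
    maxit: int = 20


@dataclass
class SimulationConfig:
    """Time stepping and solver tolerances for a run."""

    dt: float
    n_steps: int
    newton: NewtonConfig = field(default_factory=NewtonConfig)
    angle_tol: float = 10.0      # degrees; remesh below this
    tau_bulk: float = 1e-4
    tau_curve: float = 1e-4
    seed: int = 0
    output_every: int = 0

    @property
    def T(self) -> float:
        return self.dt * self.n_steps


@dataclass
class LevelOperators:
    """All operators assembled on the mesh of one time level."""

    mesh: msh.TriMesh
    M: sp.csr_matrix
    K: sp.csr_matrix
    B: sp.csr_matrix
    surf: asm.SurfaceOperators
    spec: asm.ReactionSpec

    @property
    def L(self) -> sp.csr_matrix:
        """K + A - B of the semi-discrete bulk system."""
        return self.K + self.surf.A_bulk - self.B


def material_velocity_gamma(w_gamma: np.ndarray,
                            loop_coords: np.ndarray) -> np.ndarray:
    """Material membrane velocity from the node velocity: u = (w . n) n.

    Membrane nodes move with the curve scheme's velocity V n + B t, but the
    tangential part B t is mesh redistribution, not material motion; only the
    normal component transports the surface species.  The discrete normals of
    the current membrane polygon are used for the projection.
    """
    curve = cv.CurveState(loop_coords)
    un = (w_gamma * curve.normals).sum(axis=1)
    return un[:, None] * curve.normals


def assemble_level(mesh: msh.TriMesh, spec: asm.ReactionSpec,
                   w_nodal: np.ndarray | None = None,
                   u_gamma: np.ndarray | None = None) -> LevelOperators:
    w = None if w_nodal is None else asm.ALEVelocity(np.asarray(w_nodal, float))
    M, K, B, _ = asm.assemble_bulk(mesh, w, spec)
    w_g = None if w is None else w.nodal[mesh.boundary_loops[0]]
    surf = asm.assemble_surface(mesh, u_gamma, w_g, spec)
    return LevelOperators(mesh, M, K, B, surf, spec)


# ---------------------------------------------------------------------------
# the three solves
# ---------------------------------------------------------------------------

def predict_surface(ops_n: LevelOperators, ops_np1: LevelOperators,
                    C_n: np.ndarray, Cs_n: np.ndarray, dt: float,
                    h: Callable | None = None, lhs_solver=None) -> np.ndarray:
    """Backward-Euler surface predictor.

    Solves [Ms^{n+1} + dt (Ks^{n+1} + As^{n+1})] Cs~ =
           Ms^n Cs^n + dt [Ds(C^n, Cs^n) + H(Cs^n)].
    """
    s1, s0 = ops_np1.surf, ops_n.surf
    rhs = s0.Ms @ Cs_n
    if ops_n.spec.g is not None:
        _, Ds0 = asm.coupling_vectors(s0, ops_n.spec, C_n, Cs_n)
        rhs = rhs + dt * Ds0
    if h is not None:
        rhs = rhs + dt * asm.surface_reaction_load(s0, h, Cs_n)
    if lhs_solver is not None:
        return lhs_solver(rhs)
    lhs = (s1.Ms + dt * (s1.Ks + s1.As)).tocsc()
    return spla.spsolve(lhs, rhs)


def step_bulk_cn(ops_n: LevelOperators, ops_np1: LevelOperators,
                 C_n: np.ndarray, Cs_n: np.ndarray, Cs_tilde: np.ndarray,
                 dt: float, newton: NewtonConfig = NewtonConfig(),
                 dirichlet: tuple[np.ndarray, np.ndarray] | None = None,
                 lhs_solver=None) -> np.ndarray:
    """Crank-Nicolson bulk step, Newton in C^{n+1}.

    Solves [M + dt/2 L]^{n+1} C^{n+1} = [M - dt/2 L]^n C^n
         + dt/2 [F(C^{n+1}) + F(C^n) - D(C^{n+1}, Cs~) - D(C^n, Cs^n)]
    with L = K + A - B.  ``dirichlet = (rows, values)`` replaces far-field
    rows after assembly.  ``lhs_solver`` optionally supplies a prefactorised
    solve for the (constant) Jacobian of a linear problem.
    """
    spec = ops_np1.spec
    Amat = (ops_np1.M + 0.5 * dt * ops_np1.L).tocsr()
    rhs = (ops_n.M - 0.5 * dt * ops_n.L) @ C_n
    if spec.f is not None:
        rhs = rhs + 0.5 * dt * asm.bulk_reaction_load(ops_n.mesh, spec, C_n)
    if spec.g is not None:
        D0, _ = asm.coupling_vectors(ops_n.surf, spec, C_n, Cs_n)
        rhs = rhs - 0.5 * dt * D0

    rows = vals = None
    if dirichlet is not None:
        rows, vals = dirichlet
        mask = np.zeros(ops_np1.mesh.node_count, bool)
        mask[rows] = True

    def residual(C):
        r = Amat @ C - rhs
        if spec.f is not None:
            r = r - 0.5 * dt * asm.bulk_reaction_load(ops_np1.mesh, spec, C)
        if spec.g is not None:
            D1, _ = asm.coupling_vectors(ops_np1.surf, spec, C, Cs_tilde)
            r = r + 0.5 * dt * D1
        if rows is not None:
            r[rows] = C[rows] - vals
        return r

    def jacobian(C):
        J = Amat
        if spec.df is not None:
            J = J - 0.5 * dt * asm.bulk_reaction_jacobian(ops_np1.mesh, spec, C)
        if spec.dg_dc is not None:
            J = J + 0.5 * dt * asm.coupling_jacobian(ops_np1.surf, spec, C, Cs_tilde)
        if rows is not None:
            J = J.tocsr()
            keep = ~mask[J.tocoo().row]
            coo = J.tocoo()
            J = sp.csr_matrix(
                (np.concatenate([coo.data[keep], np.ones(len(rows))]),
                 (np.concatenate([coo.row[keep], rows]),
                  np.concatenate([coo.col[keep], rows]))),
                shape=J.shape)
        return J.tocsc()

    C = C_n.copy()
    history = []
    for it in range(newton.maxit):
        r = residual(C)
        if lhs_solver is not None:
            dC = lhs_solver(-r)
        else:
            dC = spla.spsolve(jacobian(C), -r)
        C = C + dC
        upd = float(np.max(np.abs(dC)))
        history.append(upd)
        if upd < newton.tol:
            return C
    raise NewtonNonConvergenceError(history)


def correct_surface(ops_n: LevelOperators, ops_np1: LevelOperators,
                    C_n: np.ndarray, C_np1: np.ndarray,
                    Cs_n: np.ndarray, Cs_tilde: np.ndarray, dt: float,
                    h: Callable | None = None, lhs_solver=None) -> np.ndarray:
    """Linear Crank-Nicolson correction restoring second order on the surface.

    Solves [Ms + dt/2 (Ks + As)]^{n+1} Cs^{n+1} = [Ms - dt/2 (Ks + As)]^n Cs^n
         + dt/2 [Ds(C^{n+1}, Cs~) + Ds(C^n, Cs^n) + H(Cs~) + H(Cs^n)].
    """
    s1, s0 = ops_np1.surf, ops_n.surf
    rhs = (s0.Ms - 0.5 * dt * (s0.Ks + s0.As)) @ Cs_n
    if ops_n.spec.g is not None:
        _, Ds1 = asm.coupling_vectors(s1, ops_np1.spec, C_np1, Cs_tilde)
        _, Ds0 = asm.coupling_vectors(s0, ops_n.spec, C_n, Cs_n)
        rhs = rhs + 0.5 * dt * (Ds1 + Ds0)
    if h is not None:
        rhs = rhs + 0.5 * dt * (asm.surface_reaction_load(s1, h, Cs_tilde)
                                + asm.surface_reaction_load(s0, h, Cs_n))
    if lhs_solver is not None:
        return lhs_solver(rhs)
    lhs = (s1.Ms + 0.5 * dt * (s1.Ks + s1.As)).tocsc()
    return spla.spsolve(lhs, rhs)


def far_field_defect(ops_n: LevelOperators, ops_np1: LevelOperators,
                     C_n: np.ndarray, C_np1: np.ndarray,
                     Cs_n: np.ndarray, Cs_tilde: np.ndarray,
                     dt: float, rows: np.ndarray) -> float:
    """Net discrete far-field influx: the defect of the replaced Dirichlet rows.

    Summing the unmodified CN equations over all rows gives exact conservation
    of the combined bulk + surface mass; the replaced far-field rows break the
    identity by exactly the mass exchanged with the far field, so the combined
    mass change over the step equals the value returned here.
    """
    spec = ops_np1.spec
    r = (ops_np1.M + 0.5 * dt * ops_np1.L) @ C_np1 \
        - (ops_n.M - 0.5 * dt * ops_n.L) @ C_n
    if spec.f is not None:
        r = r - 0.5 * dt * (asm.bulk_reaction_load(ops_np1.mesh, spec, C_np1)
                            + asm.bulk_reaction_load(ops_n.mesh, spec, C_n))
    if spec.g is not None:
        D1, _ = asm.coupling_vectors(ops_np1.surf, spec, C_np1, Cs_tilde)
        D0, _ = asm.coupling_vectors(ops_n.surf, spec, C_n, Cs_n)
        r = r + 0.5 * dt * (D1 + D0)
    return float(r[rows].sum())


# ---------------------------------------------------------------------------
# full per-step algorithm
# ---------------------------------------------------------------------------

@dataclass
class MovingMeshModel:
    """Problem description consumed by :func:`advance_one_step`.

    ``boundary_law(state) -> (alpha, beta)`` gives the per-node coefficients
    of the curve's normal velocity V = alpha*kappa + beta;
    ``curve_monitor(points, t)`` and ``bulk_monitor`` steer the meshes;
    ``spec`` the reaction pair; ``h`` the surface-only reaction;
    ``far_field(points, t)`` Dirichlet values on the outer loop (or None).
    """

    spec: asm.ReactionSpec
    boundary_law: Callable | None = None
    curve_monitor: Callable | None = None
    bulk_monitor: mm.MonitorField = field(default_factory=mm.uniform_monitor)
    h: Callable | None = None
    far_field: Callable | None = None
    curve_params: cv.CurveFlowParams = field(default_factory=cv.CurveFlowParams)
    use_correction: bool = True
    move_mesh: bool = True


@dataclass
class SimulationState:
    mesh: msh.TriMesh
    fields: asm.FieldState
    t: float = 0.0
    remesh_count: int = 0


def _curve_state(mesh: msh.TriMesh, model: MovingMeshModel, t: float) -> cv.CurveState:
    pts = mesh.loop_coords(0)
    mon = None
    if model.curve_monitor is not None:
        mon = np.asarray(model.curve_monitor(pts, t), float)
    return cv.CurveState(pts, mon)


def advance_one_step(state: SimulationState, model: MovingMeshModel,
                     config: SimulationConfig, _retry: bool = False) -> SimulationState:
    """One full step of the moving-mesh ALE algorithm.

    (1a) normal velocity coefficients from the model's boundary law;
    (1b) curve advance; (1c) monitor; (1d) bulk moving-mesh step;
    (1e) quality test with remesh-and-redo; (2a) ALE velocity;
    (2b) predictor / Crank-Nicolson / corrector solves.
    """
    mesh_n = state.mesh
    dt = config.dt
    t_n = state.t
    C_n, Cs_n = state.fields.C, state.fields.Cs

    # (1) update the physical mesh
    if model.boundary_law is not None:
        curve_n = _curve_state(mesh_n, model, t_n)
        alpha, beta = model.boundary_law(state, curve_n)
        cp = model.curve_params
        cp = cv.CurveFlowParams(alpha=alpha, beta=beta, tau=cp.tau, P=cp.P,
                                picard_tol=cp.picard_tol,
                                picard_maxit=cp.picard_maxit,
                                picard_relax=cp.picard_relax)
        curve_np1 = cv.advance_curve(curve_n, cp, dt)
        new_gamma = curve_np1.positions
    else:
        new_gamma = mesh_n.loop_coords(0)

    moving = model.move_mesh and (model.boundary_law is not None
                                  or model.bulk_monitor is not None)
    if moving:
        bpos = [new_gamma] + [mesh_n.loop_coords(i)
                              for i in range(1, len(mesh_n.boundary_loops))]
        mesh_np1 = mm.mmpde_step(mesh_n, np.vstack(bpos), model.bulk_monitor,
                                 t_n, dt, tau=config.tau_bulk)
    else:
        mesh_np1 = mesh_n

    # (1e) quality test -> remesh and redo once
    if msh.min_triangle_angle(mesh_np1) < config.angle_tol:
        if _retry:
            raise msh.MeshError("mesh quality below tolerance after remeshing")
        logger.info("remeshing at t=%.6g (min angle %.2f deg)", t_n,
                    msh.min_triangle_angle(mesh_np1))
        new_mesh, bulk, surf = msh.remesh(mesh_n, {"C": C_n}, {"Cs": Cs_n},
                                          seed=config.seed)
        new_state = SimulationState(new_mesh,
                                    asm.FieldState(bulk["C"], surf["Cs"], t_n),
                                    t_n, state.remesh_count + 1)
        return advance_one_step(new_state, model, config, _retry=True)

    # (2) update the finite element solutions
    w_nodal = asm.mesh_velocity(mesh_n.phys_coords, mesh_np1.phys_coords, dt).nodal \
        if moving else None
    u_gamma = None
    if w_nodal is not None:
        loop = mesh_np1.boundary_loops[0]
        u_gamma = material_velocity_gamma(w_nodal[loop], mesh_np1.phys_coords[loop])

    ops_n = assemble_level(mesh_n, model.spec,
                           w_nodal=w_nodal, u_gamma=u_gamma)
    ops_np1 = assemble_level(mesh_np1, model.spec,
                             w_nodal=w_nodal, u_gamma=u_gamma)

    Cs_tilde = predict_surface(ops_n, ops_np1, C_n, Cs_n, dt, h=model.h)

    dirichlet = None
    if model.far_field is not None and len(mesh_np1.boundary_loops) > 1:
        rows = mesh_np1.boundary_loops[1]
        vals = model.far_field(mesh_np1.phys_coords[rows], t_n + dt)
        dirichlet = (rows, np.asarray(vals, float))

    C_np1 = step_bulk_cn(ops_n, ops_np1, C_n, Cs_n, Cs_tilde, dt,
                         newton=config.newton, dirichlet=dirichlet)
    if model.use_correction:
        Cs_np1 = correct_surface(ops_n, ops_np1, C_n, C_np1, Cs_n, Cs_tilde,
                                 dt, h=model.h)
    else:
        Cs_np1 = Cs_tilde

    return SimulationState(mesh_np1, asm.FieldState(C_np1, Cs_np1, t_n + dt),
                           t_n + dt, state.remesh_count)
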