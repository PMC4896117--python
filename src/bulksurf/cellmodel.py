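"""Cell migration and chemotaxis on an evolving membrane.

A pseudopod-centred activator-inhibitor system (after Meinhardt) lives on the
closed membrane curve: a local autocatalytic activator a, a rapidly
redistributed global inhibitor b, and a local inhibitor c,

    a_t + div_G(u a) = Da lap_G a + s (a^2/b + ba) / ((sc + c)(1 + sa a^2)) - ra a,
    b_t + div_G(u b) = Db lap_G b - rb b + rb <a>_G,
    c_t + div_G(u c) = Dc lap_G c + bc a - rc c,

where <a>_G is the curve-average of a.  The membrane moves with normal
velocity V = Kprot a - lambda(t) kappa (protrusion proportional to activator,
retraction by cortical tension), with the tension factor lambda controlled by
an area-regulating ODE.  An extracellular ligand l diffuses in the annulus
around the cell and binds membrane receptors,

    l_t = D lap l,      ls_t + div_G(u ls) = Ds lap_G ls + g(l, ls),
    g(l, ls) = k1 (Rtot - ls) l - k-1 ls,

the same g acting (with the windshield advective correction) as the flux of l
through the membrane.  The fractional receptor occupancy Ro = ls / Rtot
drives the activator through the signal s = ra (eta + Ro), with eta a
mean-reverting (Ornstein-Uhlenbeck) intrinsic noise.

All parameters are nondimensional; defaults reproduce the reference
parameter table, with the receptor dissociation constant fixed at Kd = 30
(the value consistent with the quoted front/back occupancies 0.19/0.15).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize as sopt
import scipy.sparse.linalg as spla

from . import assembly as asm
from . import curve as cv
from . import mesh as msh
from . import mmpde as mm
from . import stepping as stp

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class MeinhardtParams:
    ra: float = 2e-2       # activator decay rate
    ba: float = 1e-1       # basal activator production
    sa: float = 5e-4       # autocatalysis saturation
    Da: float = 4e-7       # activator diffusion
    rb: float = 3e-2       # global inhibitor production & decay
    Db: float = 4e-5       # global inhibitor diffusion
    bc: float = 7e-3       # local inhibitor production
    rc: float = 1.3e-2     # local inhibitor decay
    Dc: float = 2.8e-6     # local inhibitor diffusion
    sc: float = 2e-1       # Michaelis-Menten constant

    def __post_init__(self):
        for name in ("ra", "ba", "sa", "Da", "rb", "Db", "bc", "rc", "Dc", "sc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class MotilityParams:
    Kprot: float = 1e-5        # protrusion velocity per unit activator
    lambda0: float = 2e-6      # cortical tension factor (ODE scale)
    beta_tension: float = 2e-2  # cortical tension decay
    A0: float = np.pi * 0.1 ** 2  # prescribed cell area
    lam: float = 2e-6          # current tension state lambda(t)


@dataclass
class LigandParams:
    D: float = 10.0            # bulk ligand diffusion
    Ds_ligand: float = 1e-6    # receptor-ligand complex surface diffusion
    k_minus1: float = 1.0      # dissociation rate
    Kd: float = 30.0           # dissociation constant k-1/k1 (authoritative)
    k1: float | None = None    # association rate; default k-1/Kd
    total_receptors: float = 7e4   # 2 pi r0 Rtot
    r0: float = 0.1
    rf: float = 0.3
    l0: float = 5.3            # far-field value at the cell centre height
    gradient: float = 8.5      # linear gradient slope

    def __post_init__(self):
        if self.k1 is None:
            self.k1 = self.k_minus1 / self.Kd

    @property
    def Rtot(self) -> float:
        return self.total_receptors / (2.0 * np.pi * self.r0)

    def far_field(self, points: np.ndarray, t: float) -> np.ndarray:
        """Lab-frame initial/far-field ligand l(x, y) = l0 + gradient (x + r0)."""
        return self.l0 + self.gradient * (points[:, 0] + self.r0)


@dataclass
class NoiseParams:
    theta: float = 0.1         # mean-reversion rate
    mu: float = 0.0            # long-run mean
    sigma: float = 0.05 * np.sqrt(2 * 0.1)  # stationary sd 0.05


@dataclass
class NoiseState:
    eta: float
    params: NoiseParams
    rng: np.random.Generator


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def curve_mean(values: np.ndarray, coords: np.ndarray) -> float:
    """Curve-length-weighted mean by trapezoidal arc quadrature."""
    seg = np.linalg.norm(np.roll(coords, -1, axis=0) - coords, axis=1)
    w = 0.5 * (seg + np.roll(seg, 1))
    return float((values * w).sum() / w.sum())


def meinhardt_rhs(a, b, c, s, coords, params: MeinhardtParams):
    """Nodal reaction terms of the three membrane species.

    Returns (ra_terms, rb_terms, rc_terms); the global-inhibitor equation
    couples to the curve mean of the activator.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    if np.any(b <= 0):
        raise ValueError("global inhibitor must stay positive (singular kinetics)")
    if np.any(c + params.sc <= 0):
        raise ValueError("local inhibitor + sc must stay positive")
    act = s * (a ** 2 / b + params.ba) / ((params.sc + c) * (1.0 + params.sa * a ** 2)) \
        - params.ra * a
    abar = curve_mean(a, coords)
    inh_b = -params.rb * b + params.rb * abar
    inh_c = params.bc * a - params.rc * c
    return act, inh_b, inh_c


def meinhardt_homogeneous_steady_state(params: MeinhardtParams, s: float):
    """Spatially homogeneous fixed point (a*, b*, c*) for constant signal s.

    At the fixed point b* = a* and c* = (bc/rc) a*; a* solves the remaining
    scalar equation by bracketed root-finding.
    """
    def f(a):
        c = params.bc / params.rc * a
        return s * (a + params.ba) / ((params.sc + c) * (1.0 + params.sa * a ** 2)) \
            - params.ra * a
    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
    a_star = sopt.brentq(f, 1e-12, hi, xtol=1e-14)
    return a_star, a_star, params.bc / params.rc * a_star


def ligand_surface_reaction(l_on_gamma, ls, params: LigandParams):
    """Mass-action binding g = k1 (Rtot - ls) l - k-1 ls."""
    return params.k1 * (params.Rtot - np.asarray(ls)) * np.asarray(l_on_gamma) \
        - params.k_minus1 * np.asarray(ls)


def equilibrium_occupancy(l, Kd):
    """Fractional receptor occupancy at binding equilibrium: l / (l + Kd)."""
    l = np.asarray(l, float)
    return l / (l + Kd)


def boundary_normal_velocity(a_vec, kappa_vec, params: MotilityParams):
    """V = Kprot a - lambda kappa (kappa positive on a convex cell)."""
    return params.Kprot * np.asarray(a_vec) - params.lam * np.asarray(kappa_vec)


def tension_step(params: MotilityParams, A: float, dA_dt: float, dt: float) -> float:
    """Explicit Euler step of the cortical tension ODE.

    d lambda/dt = lambda0 lambda (A - A0 + dA/dt) / (A0 (lambda + lambda0))
                  - beta lambda.
    """
    lam = params.lam
    rhs = params.lambda0 * lam * (A - params.A0 + dA_dt) \
        / (params.A0 * (lam + params.lambda0)) - params.beta_tension * lam
    new = lam + dt * rhs
    if new < 0:
        logger.warning("tension clamped at 0 (was %.3e)", new)
        new = 0.0
    return new


def ou_noise_step(state: NoiseState, dt: float) -> NoiseState:
    """Euler-Maruyama step of d eta = theta (mu - eta) dt + sigma dW."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = state.params
    eta = state.eta + p.theta * (p.mu - state.eta) * dt \
        + p.sigma * np.sqrt(dt) * state.rng.standard_normal()
    return NoiseState(float(eta), p, state.rng)


def signal_term(Ro_vec, eta, ra):
    """Signal s = ra (eta + Ro), floored at 0."""
    s = ra * (eta + np.asarray(Ro_vec, float))
    if np.any(s < 0):
        logger.debug("signal floored at 0 at %d nodes", int((s < 0).sum()))
        s = np.maximum(s, 0.0)
    return s


# ---------------------------------------------------------------------------
# coupled simulation
# ---------------------------------------------------------------------------

@dataclass
class CellRunConfig:
    dt: float = 0.1
    n_steps: int = 2000
    seed: int = 0
    ns_membrane: int = 80
    h_far: float = 0.035
    h_membrane: float = 0.012
    tau_bulk: float = 1e-2
    tau_curve: float = 1e-2
    angle_tol: float = 10.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    noise_on: bool = True
    perturbation: float = 0.05      # relative seed perturbation of the activator
    record_every: int = 10


@dataclass
class CellState:
    mesh: msh.TriMesh
    l: np.ndarray
    ls: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    lam: float
    noise: NoiseState
    t: float = 0.0
    remesh_count: int = 0
    prev_area: float | None = None


@dataclass
class CellTrajectory:
    times: list = field(default_factory=list)
    centroid: list = field(default_factory=list)
    area: list = field(default_factory=list)
    lam: list = field(default_factory=list)
    min_angle: list = field(default_factory=list)
    bulk_mass: list = field(default_factory=list)      # total ligand in the window
    membrane_length: list = field(default_factory=list)
    remesh_count: list = field(default_factory=list)
    membrane: list = field(default_factory=list)   # optional per-record profiles

    def as_arrays(self):
        return (np.asarray(self.times), np.asarray(self.centroid),
                np.asarray(self.area), np.asarray(self.lam))


def _membrane_centroid(mesh: msh.TriMesh) -> np.ndarray:
    g = mesh.loop_coords(0)
    seg = np.linalg.norm(np.roll(g, -1, axis=0) - g, axis=1)
    w = 0.5 * (seg + np.roll(seg, 1))
    return (g * w[:, None]).sum(axis=0) / w.sum()


def initial_cell_state(ligand: LigandParams, mein: MeinhardtParams,
                       mot: MotilityParams, cfg: CellRunConfig,
                       gradient_on: bool = True) -> CellState:
    """Build the annulus mesh and equilibrium initial fields.

    a, b, c start at the homogeneous steady state for the mean signal with a
    seeded relative perturbation of a; ls starts at local binding
    equilibrium; l at the lab-frame far-field formula.
    """
    lig = ligand if gradient_on else replace(ligand, gradient=0.0)
    spec = msh.DomainSpec("annulus_cell_in_circle", h=cfg.h_far, r0=lig.r0,
                          rf=lig.rf, h_min=cfg.h_membrane,
                          ns_inner=cfg.ns_membrane)
    mesh = msh.generate_initial_mesh(spec, seed=cfg.seed)
    p = mesh.phys_coords
    l = lig.far_field(p, 0.0)
    gamma = mesh.loop_coords(0)
    l_gamma = lig.far_field(gamma, 0.0)
    Ro = equilibrium_occupancy(l_gamma, lig.Kd)
    ls = Ro * lig.Rtot

    rng = np.random.default_rng(cfg.seed)
    s_mean = mein.ra * float(Ro.mean())
    a0, b0, c0 = meinhardt_homogeneous_steady_state(mein, s_mean)
    ns = len(gamma)
    a = a0 * (1.0 + cfg.perturbation * rng.standard_normal(ns))
    noise = NoiseState(0.0, cfg.noise if cfg.noise_on
                       else replace(cfg.noise, sigma=0.0), rng)
    return CellState(mesh, l, ls, np.maximum(a, 0.0),
                     np.full(ns, b0), np.full(ns, c0),
                     mot.lambda0, noise,
                     prev_area=abs(msh.polygon_area(gamma)))


def _surface_spec(Ds: float) -> asm.ReactionSpec:
    return asm.ReactionSpec(D=0.0, Ds=Ds)


def advance_cell_step(state: CellState, ligand: LigandParams,
                      mein: MeinhardtParams, mot: MotilityParams,
                      cfg: CellRunConfig, gradient_on: bool = True,
                      frozen_membrane: bool = False,
                      forced_beta: np.ndarray | None = None,
                      _retry: bool = False) -> CellState:
    """One full coupled step (membrane motion, mesh, ligand, kinetics).

    ``forced_beta`` overrides the protrusion part of the normal velocity
    (used by the scripted protrusion/retraction diagnostics).
    """
    dt = cfg.dt
    mesh_n = state.mesh
    lig = ligand if gradient_on else replace(ligand, gradient=0.0)

    # (1a-b) membrane motion: V = alpha*kappa_discrete + beta with
    # alpha = lambda (tension; discrete curvature is negative on convex loops,
    # so a positive alpha retracts) and beta = Kprot * a (protrusion).
    gamma_n = mesh_n.loop_coords(0)
    if frozen_membrane:
        new_gamma = gamma_n
    else:
        curve_n = cv.CurveState(gamma_n)
        beta = mot.Kprot * state.a if forced_beta is None else forced_beta
        params = cv.CurveFlowParams(alpha=state.lam, beta=beta,
                                    tau=cfg.tau_curve)
        curve_np1 = cv.advance_curve(curve_n, params, dt)
        new_gamma = curve_np1.positions

    # (1c-d) bulk mesh update
    if frozen_membrane:
        mesh_np1 = mesh_n
    else:
        bpos = np.vstack([new_gamma] + [mesh_n.loop_coords(i)
                                        for i in range(1, len(mesh_n.boundary_loops))])
        mesh_np1 = mm.mmpde_step(mesh_n, bpos, mm.uniform_monitor(),
                                 state.t, dt, tau=cfg.tau_bulk)

    # (1e) quality test -> remesh (recentring the far-field window) and redo
    if msh.min_triangle_angle(mesh_np1) < cfg.angle_tol:
        if _retry:
            raise msh.MeshError("mesh quality below tolerance after remeshing")
        state = _remesh_state(state, lig, cfg)
        return advance_cell_step(state, ligand, mein, mot, cfg,
                                 gradient_on=gradient_on,
                                 frozen_membrane=frozen_membrane,
                                 forced_beta=forced_beta, _retry=True)

    # (2a) ALE velocity; the material membrane velocity is the normal part of
    # the node velocity (the tangential slide is mesh redistribution)
    moving = not frozen_membrane
    w_nodal = asm.mesh_velocity(mesh_n.phys_coords, mesh_np1.phys_coords, dt).nodal \
        if moving else None
    u_gamma = None
    w_gamma = None
    if moving:
        loop = mesh_np1.boundary_loops[0]
        w_gamma = w_nodal[loop]
        u_gamma = stp.material_velocity_gamma(w_gamma, mesh_np1.phys_coords[loop])

    # (2b-i) ligand pair (l, ls)
    lig_spec = asm.ReactionSpec(
        D=lig.D, Ds=lig.Ds_ligand,
        g=lambda c_, cs_: lig.k1 * (lig.Rtot - cs_) * c_ - lig.k_minus1 * cs_,
        dg_dc=lambda c_, cs_: lig.k1 * (lig.Rtot - cs_),
    )
    ops_n = stp.assemble_level(mesh_n, lig_spec, w_nodal=w_nodal, u_gamma=u_gamma)
    ops_np1 = stp.assemble_level(mesh_np1, lig_spec, w_nodal=w_nodal, u_gamma=u_gamma)
    ls_tilde = stp.predict_surface(ops_n, ops_np1, state.l, state.ls, dt)
    rows = mesh_np1.boundary_loops[1]
    dirichlet = (rows, lig.far_field(mesh_np1.phys_coords[rows], state.t + dt))
    l_np1 = stp.step_bulk_cn(ops_n, ops_np1, state.l, state.ls, ls_tilde, dt,
                             dirichlet=dirichlet)
    ls_np1 = stp.correct_surface(ops_n, ops_np1, state.l, l_np1, state.ls,
                                 ls_tilde, dt)
    clipped = np.clip(ls_np1, 0.0, lig.Rtot)
    if not np.array_equal(clipped, ls_np1):
        logger.warning("receptor occupancy clamped to [0, Rtot] at %d nodes",
                       int((clipped != ls_np1).sum()))
    ls_np1 = clipped

    # (2b-ii) intrinsic noise and signal
    noise_np1 = ou_noise_step(state.noise, dt)
    Ro_n = state.ls / lig.Rtot
    Ro_np1 = ls_np1 / lig.Rtot
    s_n = signal_term(Ro_n, state.noise.eta, mein.ra)
    s_np1 = signal_term(Ro_np1, noise_np1.eta, mein.ra)

    # (2b-iii) Meinhardt triple: backward-Euler predictor for each species
    # with explicit reactions at time n, then the linear Crank-Nicolson
    # correction with reactions at the predicted triple.  The frozen nodal
    # reaction r enters the load as int r_h phi_i ds = Ms r.
    coords_n = mesh_n.loop_coords(0)
    coords_np1 = mesh_np1.loop_coords(0)
    surf_n = asm.assemble_surface(mesh_n, u_gamma, w_gamma, _surface_spec(1.0))
    surf_1 = asm.assemble_surface(mesh_np1, u_gamma, w_gamma, _surface_spec(1.0))

    ra_n, rb_n, rc_n = meinhardt_rhs(state.a, state.b, state.c, s_n,
                                     coords_n, mein)

    def pred(Ds, y, r_nodal):
        rhs = surf_n.Ms @ (y + dt * np.asarray(r_nodal))
        lhs = (surf_1.Ms + dt * (Ds * surf_1.Ks + surf_1.As)).tocsc()
        return spla.spsolve(lhs, rhs)

    a_t = pred(mein.Da, state.a, ra_n)
    b_t = pred(mein.Db, state.b, rb_n)
    c_t = pred(mein.Dc, state.c, rc_n)

    ra_t, rb_t, rc_t = meinhardt_rhs(np.maximum(a_t, 0.0),
                                     np.maximum(b_t, 1e-12),
                                     c_t, s_np1, coords_np1, mein)

    def corr(Ds, y_n, r_n, r_t):
        rhs = (surf_n.Ms - 0.5 * dt * (Ds * surf_n.Ks + surf_n.As)) @ y_n \
            + 0.5 * dt * (surf_n.Ms @ np.asarray(r_n) + surf_1.Ms @ np.asarray(r_t))
        lhs = (surf_1.Ms + 0.5 * dt * (Ds * surf_1.Ks + surf_1.As)).tocsc()
        return spla.spsolve(lhs, rhs)

    a_np1 = np.maximum(corr(mein.Da, state.a, ra_n, ra_t), 0.0)
    b_np1 = np.maximum(corr(mein.Db, state.b, rb_n, rb_t), 1e-12)
    c_np1 = corr(mein.Dc, state.c, rc_n, rc_t)

    # (3) tension and bookkeeping
    A_new = abs(msh.polygon_area(coords_np1))
    dA_dt = 0.0 if state.prev_area is None else (A_new - state.prev_area) / dt
    mot_state = replace(mot, lam=state.lam)
    lam_np1 = tension_step(mot_state, A_new, dA_dt, dt)

    logger.debug("step t=%.4g lam=%.3e eta=%+.3f amax=%.3f minang=%.1f",
                 state.t + dt, lam_np1, noise_np1.eta, a_np1.max(),
                 msh.min_triangle_angle(mesh_np1))
    return CellState(mesh_np1, l_np1, ls_np1, a_np1, b_np1, c_np1,
                     lam_np1, noise_np1, state.t + dt,
                     state.remesh_count, prev_area=A_new)


def _remesh_state(state: CellState, lig: LigandParams, cfg: CellRunConfig) -> CellState:
    """Remesh with the far-field circle re-centred on the membrane centroid."""
    cen = _membrane_centroid(state.mesh)
    n_out = len(state.mesh.boundary_loops[1])
    outer = msh.circle_points(cen, lig.rf, n_out)
    new_mesh, bulk, surf = msh.remesh(
        state.mesh, {"l": state.l},
        {"ls": state.ls, "a": state.a, "b": state.b, "c": state.c},
        seed=cfg.seed, outer_loop_coords=outer)
    # newly uncovered far-field nodes keep the lab-frame formula value
    logger.info("cell remesh at t=%.4g, window recentred at (%.4f, %.4f)",
                state.t, cen[0], cen[1])
    return CellState(new_mesh, bulk["l"], surf["ls"], surf["a"], surf["b"],
                     surf["c"], state.lam, state.noise, state.t,
                     state.remesh_count + 1, state.prev_area)


def run_linear_gradient(ligand: LigandParams | None = None,
                        mein: MeinhardtParams | None = None,
                        mot: MotilityParams | None = None,
                        cfg: CellRunConfig | None = None,
                        gradient_on: bool = True) -> tuple[CellTrajectory, CellState]:
    """Full coupled chemotaxis run in an (optionally zero) linear gradient."""
    ligand = ligand or LigandParams()
    mein = mein or MeinhardtParams()
    mot = mot or MotilityParams()
    cfg = cfg or CellRunConfig()
    state = initial_cell_state(ligand, mein, mot, cfg, gradient_on=gradient_on)
    traj = CellTrajectory()
    _record(traj, state)
    for n in range(cfg.n_steps):
        state = advance_cell_step(state, ligand, mein, mot, cfg,
                                  gradient_on=gradient_on)
        if (n + 1) % cfg.record_every == 0 or n == cfg.n_steps - 1:
            _record(traj, state)
    return traj, state


def run_homogeneous_field(ligand: LigandParams | None = None,
                          mein: MeinhardtParams | None = None,
                          mot: MotilityParams | None = None,
                          cfg: CellRunConfig | None = None,
                          record_profiles: bool = True) -> tuple[CellTrajectory, CellState]:
    """Chemotaxis machinery in an initially homogeneous ligand field.

    Records membrane profiles (Ro, unbound fraction, l at the membrane) for
    the self-generated-gradient diagnostics.
    """
    ligand = replace(ligand or LigandParams(), gradient=0.0)
    mein = mein or MeinhardtParams()
    mot = mot or MotilityParams()
    cfg = cfg or CellRunConfig()
    state = initial_cell_state(ligand, mein, mot, cfg, gradient_on=False)
    traj = CellTrajectory()
    _record(traj, state, ligand if record_profiles else None)
    for n in range(cfg.n_steps):
        state = advance_cell_step(state, ligand, mein, mot, cfg,
                                  gradient_on=False)
        if (n + 1) % cfg.record_every == 0 or n == cfg.n_steps - 1:
            _record(traj, state, ligand if record_profiles else None)
    return traj, state


def _record(traj: CellTrajectory, state: CellState,
            ligand: LigandParams | None = None):
    traj.times.append(state.t)
    traj.centroid.append(_membrane_centroid(state.mesh))
    g = state.mesh.loop_coords(0)
    traj.area.append(abs(msh.polygon_area(g)))
    traj.lam.append(state.lam)
    traj.min_angle.append(msh.min_triangle_angle(state.mesh))
    areas = msh.triangle_signed_areas(state.mesh.phys_coords, state.mesh.triangles)
    traj.bulk_mass.append(float((areas * state.l[state.mesh.triangles].mean(axis=1)).sum()))
    traj.membrane_length.append(float(np.linalg.norm(
        np.roll(g, -1, axis=0) - g, axis=1).sum()))
    traj.remesh_count.append(state.remesh_count)
    if ligand is not None:
        loop = state.mesh.boundary_loops[0]
        traj.membrane.append({
            "t": state.t,
            "Ro": state.ls / ligand.Rtot,
            "unbound": (ligand.Rtot - state.ls) / ligand.Rtot,
            "l_gamma": state.l[loop].copy(),
        })


def run_forced_protrusion(amplitude: float = 2e-4, n_steps: int = 20,
                          retract: bool = False,
                          cfg: CellRunConfig | None = None):
    """Scripted bump protrusion (or retraction) of an otherwise resting cell.

    Drives the membrane with a prescribed normal-velocity bump around theta=0
    in a homogeneous ligand field and reports the receptor-ligand complex
    profile: stretching a membrane segment dilutes ls locally (and
    compression enriches it) because total receptor transport is conservative.
    Returns (ls_deviation_at_bump, state): deviation of ls from the curve
    mean, normalised by the mean, within the forced segment.
    """
    ligand = LigandParams(gradient=0.0)
    mein = MeinhardtParams()
    mot = MotilityParams(Kprot=0.0)
    cfg = cfg or CellRunConfig(n_steps=n_steps, noise_on=False, perturbation=0.0)
    state = initial_cell_state(ligand, mein, mot, cfg, gradient_on=False)
    sign = -1.0 if retract else 1.0
    for _ in range(n_steps):
        gamma = state.mesh.loop_coords(0)
        cen = _membrane_centroid(state.mesh)
        th = np.arctan2(gamma[:, 1] - cen[1], gamma[:, 0] - cen[0])
        bump = np.exp(-(th / 0.5) ** 2)
        beta = sign * amplitude * bump
        state = advance_cell_step(state, ligand, mein, mot, cfg,
                                  gradient_on=False, forced_beta=beta)
    gamma = state.mesh.loop_coords(0)
    cen = _membrane_centroid(state.mesh)
    th = np.arctan2(gamma[:, 1] - cen[1], gamma[:, 0] - cen[0])
    in_bump = np.abs(th) < 0.5
    mean_ls = curve_mean(state.ls, gamma)
    dev = (state.ls[in_bump].mean() - mean_ls) / mean_ls
    return float(dev), state
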