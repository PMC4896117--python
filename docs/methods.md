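# Methods

`bulksurf` solves coupled bulk–surface reaction–diffusion systems on evolving
two-dimensional domains with P1 finite elements in a conservative arbitrary
Lagrangian–Eulerian (ALE) formulation, generating its meshes with a
moving-mesh-PDE (MMPDE) approach in the bulk and on the boundary curve. This
note records the model, the discretisation, the numerical choices that were
genuinely open, and what the shipped tests do and do not demonstrate.

## Continuous model

A bulk species c(x, t) diffuses and reacts in a moving domain Ω(t),

    ∂c/∂t = D Δc + f(c),                         x ∈ Ω(t),

and couples through the flux condition on the moving boundary Γ(t)
(n the unit normal pointing out of the enclosed region, u the material
boundary velocity)

    −D ∂c/∂n + (u·n) c = g(c|Γ, cs),

to a surface species cs(x, t) transported and diffusing on the curve,

    ∂cs/∂t + ∇Γ·(u cs) = Ds ΔΓ cs + g(c|Γ, cs) + h(cs).

The advective term (u·n) c is the "windshield" flux: a boundary advancing
into the bulk (u·n > 0) sweeps material onto itself, a retreating one sheds
it. Both equations are rewritten in conservative weak ALE form with respect
to a time-dependent map from a fixed computational domain; the test space
rides with the map, so d/dt ∫ c v dx produces the mesh-velocity divergence
terms automatically and total mass bookkeeping is exact at the discrete
level (see "Conservation structure").

## Discretisation

**Space.** P1 triangles in the bulk, periodic P1 segments on the boundary
polygon. The semi-discrete system is

    d/dt(M C)  + [K + A − B] C + D(C, Cs) = F(C),
    d/dt(Ms Cs) + [Ks + As] Cs = Ds(C, Cs) + H(Cs),

with M/Ms mass, K/Ks (Laplace–Beltrami) stiffness, B the ALE transport
matrix −∫(w·∇φi)φj, A the boundary matrix with kernel (u−w)·n, As the
tangential transport operator with the divergence ∇Γ·(u−w) taken
segment-wise as the arc-length derivative of the tangential component, and
D/Ds/H/F the coupling and reaction loads. P1×P1 products are integrated
exactly; nonlinear integrands use the 3-point edge-midpoint rule (exact for
quadratics) in the bulk and 2-point Gauss per segment on the curve, with
the field arguments interpolated to the quadrature points before the
nonlinearity is applied.

**Time.** Each step solves (i) a semi-implicit backward-Euler predictor for
the surface species (diffusion and mesh-movement implicit, reactions and
coupling explicit), (ii) a Crank–Nicolson step for the bulk species, with
the new coupling evaluated at the predicted surface values and the
nonlinearity in C^{n+1} resolved by Newton iteration with the analytic
Jacobian (max-norm update tolerance 1e-10, 20 iterations maximum; linear
problems converge in one), and (iii) a linear Crank–Nicolson correction for
the surface species. The correction is what makes the surface solution
second-order in time; disabling it (an option retained for the convergence
study) degrades the surface — and, through the coupling, the bulk — to
first order. The mesh map is interpolated linearly between time levels, so
the discrete ALE velocity w = (x^{n+1} − x^n)/Δt is piecewise constant over
each slab. The fully implicit treatment of diffusion makes the scheme
robust to time steps far above the diffusive stability scale (probed at
Δt = 0.1 on the disc benchmark).

**Material vs mesh velocity on Γ.** Boundary nodes move with the curve
scheme's velocity V n + B t, where B is the tangential mesh-redistribution
velocity. Only the normal part is material: the assembled u is the normal
projection (w·n)n of the node velocity, and the tangential slip enters
through As with kernel (u − w). This distinction is load-bearing: it is
what produces the local dilution of a surface species under membrane
stretching. Identifying u with the full node velocity would let
concentrations ride along with sliding nodes and silently delete that
mechanism.

## Mesh generation and movement

**Initial meshes** come from a distmesh-style relaxation: boundary polygons
are sampled exactly on the analytic curves (equal arc length, or
equidistributed against a monitor when one is active at t = 0) and held
fixed, interior points start on a hexagonal lattice thinned to a graded
target edge-length field h(x), and bar forces with Delaunay retriangulation
relax the interior. Produced meshes have minimum angles of 28–36° at the
tested resolutions. For cell runs the edge length is graded linearly from
h_min at the membrane to h_far at the outer circle.

**Bulk MMPDE.** Interior nodes follow the gradient flow of the Winslow
functional with monitor matrix diag(M, M): written for the physical
coordinates over the fixed reference triangulation,

    (τ/P) ∂x/∂t = a x_ξξ + b x_ξη + c x_ηη + d x_ξ + e x_η,

with the coefficients built from the P1 map gradients, J = det of the map,
and the monitor. One backward-Euler step with coefficients lagged at t_n is
a linear solve per component; boundary positions from the curve scheme are
Dirichlet data. Two implementation points matter:

- the operator is in *non-divergence* form; the weak form keeps the
  coefficients inside the test-function derivative, (a v̂)_ξ. Treating
  a, b, c as element-wise constants drops their in-element gradients and
  makes the leftover first-order term antidiffusive — the mesh then
  corrugates and tangles within a dozen steps. The assembly therefore uses
  area-weighted nodal recoveries of a, b, c so their P1 gradients
  contribute.
- monitor derivatives M_ξ, M_η in the d, e coefficients come from an
  area-weighted nodal recovery of M's reference-coordinate gradient.

The balancing factor is P = 1/M (element value), equalising the adaptation
time scale across the domain; with P ≡ 1 the printed form is recovered.
With M ≡ 1 and the initial (reference = physical) mesh, the identity map is
an exact fixed point, and with a fixed boundary the iteration settles to a
harmonic-type steady mesh.

**Boundary curve.** The closed curve moves with normal velocity
V = α κ + β while nodes redistribute tangentially by equidistribution of a
monitor-weighted arc length, B = (P/τ)(M‖x_σ‖)_σ. Central differences on a
uniform periodic parameter grid and a fully implicit first-order step give
a coupled nonlinear system; each Picard sweep freezes the geometry
(tangents, normals, chord lengths) at the previous iterate and solves the
normal-direction and tangential-direction rows as one sparse 2Ns system.
The iteration stops when the max-norm inter-iterate displacement falls
below TOL = 1e-9 (configurable). For large tangential slides the
fixed-point map acquires complex eigenvalues near ±1.5i; the sweep
therefore under-relaxes (ω → 0.25) once an update grows, and if the budget
(300 sweeps) is still exhausted the step is retried as two half steps of
the same scheme (depth-limited).

Orientation convention: every loop is stored counterclockwise around the
region it encloses and the discrete normal (t2, −t1) points away from that
region. The discrete curvature x_σσ·n/‖x_σ‖² is then negative on a convex
loop, so α > 0 shrinks a circle with dA/dt = −2πα exactly as mean curvature
flow requires; the cell model's tension term −λκ (κ positive-convex) maps
onto α = λ.

**Quality control and remeshing.** After each mesh update the minimum
triangle angle is measured; below `angle_tol` (default 10°, configurable —
the criterion is standard, the tolerance a package choice) the domain is
remeshed with the current boundary polygons held fixed, bulk fields
transferred by barycentric interpolation, surface fields by periodic
arc-length interpolation, and the time step redone. The sizing field
carried into a remesh is the *area-based* local length
sqrt(4·mean incident area/√3) with boundary nodes pinned to their segment
lengths; carrying mean edge lengths instead would bake the accumulated
shear into the new mesh and triggers near-continuous remeshing.

## Verification problems

**Disc benchmark.** Heat flow in the unit disc coupled to a surface species
on the circle through −∂c/∂n = c − cs, with cs_t = ΔΓcs + c − cs. The
separable solution c = J1(kr)e^{−k²t}cosθ, cs = J1(k)/(2−k²)e^{−k²t}cosθ
requires k J1'(k)(2−k²) = J1(k)(k²−1); the smallest positive root,
k = 1.177706027, is found by bracketed root-finding (Brent) on [0.5, 1.4]
with J1' = J0 − J1/k. Spatial study: h ∈ {0.2, 0.1, 0.05, 0.025},
Δt = 1e-3, T = 1, max nodal error at T against the exact solution;
both fields show slopes ≈ 2.0. Temporal study: fixed h ≈ 0.05 mesh,
Δt ∈ {8, 4, 2, 1}×1e-3. On this mesh the spatial error floor (≈5e-4) is
comparable to the temporal error, so the temporal error is measured against
a same-mesh reference computed at Δt_min/8; this isolates the temporal
order (≈2.1 bulk, ≈2.0 surface; surface ≈1.0 with the correction step
disabled). These problem sizes are the package's own desk-scale choices.

**Mean-curvature-flow demo.** The ellipse 4x² + 16y² = 1 (enclosed area
π/8) shrinks by curvature flow (α = 0.75) inside a unit far-field circle
while bulk and boundary meshes adapt to the travelling-wave monitor
1 + sech²((x + t − 0.7)/0.6); τ = 1e-4 for both MMPDEs, Δt = 1e-3,
t ∈ [0, 0.07], 72 boundary nodes and h = 0.033 in the bulk (≈3800
elements). The enclosed polygon area tracks A(0) − 2παt within 1.3% at
t ≤ 0.05, the boundary nodes re-equidistribute arc length after the wave
passes, and the run needs two remeshings at angle_tol = 10°. Boundary
nodes are initialised equidistributed against the t = 0 monitor: starting
from plain arc-length spacing, the first step performs tangential slides of
order 10% of the curve length along straight tangent lines and cuts ≈3% of
the enclosed area — node motion is polygonal, so large slides cut corners.

## Cell migration application

Membrane-bound activator–inhibitor kinetics (activator a with saturating
autocatalysis, fast global inhibitor b coupling through the curve mean of
a, slow local inhibitor c), protrusion V = Kprot·a − λ(t)κ, cortical
tension λ(t) regulated by an explicit-Euler ODE that penalises area
deviation from A0, and an extracellular ligand l in a moving annular window
(r0 = 0.1, rf = 3r0) binding membrane receptors with
g = k1(Rtot − ls)l − k−1·ls. Receptor occupancy Ro = ls/Rtot drives the
activator through s = ra(η + Ro), with η a scalar Ornstein–Uhlenbeck noise
(θ = 0.1, μ = 0, σ chosen for stationary s.d. 0.05; Euler–Maruyama, seeded;
per-node noise available). The dissociation constant is taken as Kd = 30
with k−1 = 1 (so k1 = 1/30): the parameter table's k1 = 130 contradicts the
quoted Kd and the front/back occupancies 0.19/0.15, which only follow from
Kd = 30; the table value remains available in the config. Receptor totals
are quoted as 2πr0·Rtot = 7e4, so nodal Rtot = 7e4/(2πr0); occupancy is
scale-free.

Sequencing per step: curve advance (α = λ, β = Kprot·a, arc-length curve
monitor), bulk MMPDE (uniform monitor — the mesh is instead graded toward
the membrane at generation time; both monitors are configurable), quality
test, then ligand pair (predictor/CN/corrector, far-field Dirichlet rows
re-evaluated from the static lab-frame formula), then the three membrane
species with the same predictor/corrector machinery (reactions explicit,
evaluated at the predicted triple in the correction), then λ and η updates.
At remesh events the annular window is re-centred on the membrane centroid
(translating it every step would cost a remesh per step; between remeshes
the window simply rides with the mesh).

Initial data: a, b, c at the homogeneous fixed point for the membrane-mean
signal (b* = a*, c* = (bc/rc)a*, a* by bracketed root-finding), a then
perturbed by 5% seeded relative noise; ls at local binding equilibrium
Rtot·l/(l + Kd); l at the lab-frame field. Default resolution: 80 membrane
nodes, bulk edge length graded 0.012 → 0.035 (≈1100 elements), Δt = 0.1,
τ = 1e-2 for both MMPDEs. These are desk-scale sizes; the membrane spacing
(≈8e-3) resolves the activator decay length sqrt(Da/ra) ≈ 4.5e-3 only
marginally, which coarsens individual pseudopods but preserves the
directed-migration statistics the tests assert.

## Conservation structure

With the printed operator signs, 1ᵀB = 0 (gradients of the partition of
unity) and 1ᵀK = 0, so on a stationary mesh with f = g = 0 total bulk mass
is conserved to round-off per step; under pure ALE mesh motion with u = w
on Γ conservation is again exact — the moving mass matrix and B cancel by
construction. With binding kinetics on, the coupling loads transfer exactly
∫g between bulk and surface (the same quadrature appears on both sides), so
combined bulk + surface ligand mass is conserved to solver tolerance on a
closed domain, and with far-field Dirichlet rows the combined mass changes
by exactly the defect of the replaced rows, which the package exposes as
the discrete far-field flux.

## What the tests show — and what they do not

The synthetic configurations exercise the numerics under the model's
stated conditions: exact-solution convergence on a stationary disc, the
geometric area law on a strongly deforming annulus, conservation
identities, and the chemotaxis model's qualitative behaviours (directional
drift up a shallow gradient across seeds, symmetric runs staying centred,
protrusion-induced local dilution of bound receptor and
retraction-induced enrichment). They do not calibrate the cell model
against measured cell tracks, and the scaled-down runs (2,000 steps of
Δt = 0.1 versus the reference experiments' 5×10⁵) sample the early,
pattern-forming phase of migration rather than long-run persistent walks;
remeshing counts at these scales (0–2 per run) support the robustness
claim only as an order of magnitude.

## Known limitations

- The curve scheme is first-order in time; near curve collapse (|κ| large)
  its O(Δt)·|V̇| error dominates, and the shrinking-circle benchmark at
  Δt = 1e-3 tracks the analytic radius to ~0.5% rather than machine-level.
- The Winslow steady mesh itself degrades in quality under large
  accumulated deformation of the hole boundary (the map from the fixed
  reference annulus becomes strongly sheared); remeshing, not the MMPDE, is
  the recovery mechanism, exactly as the step algorithm prescribes.
- Topological change of the membrane (splitting/merging), open curves,
  anisotropic monitors and 3D are out of scope.
- The pointwise strong residual of the P1 scheme does not converge (normal
  for P1); consistency holds in the weak sense, which is what the
  verification suite probes.
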