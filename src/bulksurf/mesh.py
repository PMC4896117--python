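"""Triangulated-domain data structures, mesh generation and interpolation.

The physical domain is covered by a triangulation that is the image of a fixed
reference ("computational") triangulation under a piecewise-linear,
orientation-preserving map: each node carries both reference coordinates
``ref_coords`` and physical coordinates ``phys_coords``.  Between remeshing
events the reference coordinates and the connectivity never change; only
``phys_coords`` move.

Meshes are generated by a distmesh-style algorithm: boundary nodes are placed
exactly on the (polygonal) boundary loops and held fixed while interior nodes
relax under edge "bar" forces toward a target edge-length field, with a
Delaunay retriangulation whenever nodes have drifted far enough.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy.spatial import Delaunay, cKDTree


class MeshError(Exception):
    """Base class for mesh failures."""


class InvalidDomainError(MeshError):
    """Degenerate geometry specification (e.g. r0 >= rf)."""


class MeshGenerationError(MeshError):
    """The mesher failed to produce a valid triangulation."""


class TangledMeshError(MeshError):
    """A triangle with non-positive signed area was produced."""


class LocationError(MeshError):
    """A query point could not be located inside the mesh."""


# ---------------------------------------------------------------------------
# basic geometry
# ---------------------------------------------------------------------------

def triangle_signed_areas(coords: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Signed area of each triangle (positive for counterclockwise)."""
    p0 = coords[triangles[:, 0]]
    e1 = coords[triangles[:, 1]] - p0
    e2 = coords[triangles[:, 2]] - p0
    return 0.5 * (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])


def polygon_area(loop_coords: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (positive if CCW).

    The last point must *not* repeat the first.  Fewer than three points give 0.
    """
    p = np.asarray(loop_coords, dtype=float)
    if len(p) < 3:
        return 0.0
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def min_triangle_angle(mesh: "TriMesh") -> float:
    """Minimum interior angle (degrees) over all physical triangles.

    Returns 0 for a tangled mesh (any non-positive signed area), signalling
    that remeshing is required.
    """
    tri = mesh.triangles
    if len(tri) == 0:
        raise MeshError("empty mesh")
    if np.any(triangle_signed_areas(mesh.phys_coords, tri) <= 0.0):
        return 0.0
    p = mesh.phys_coords
    a = p[tri[:, 1]] - p[tri[:, 0]]
    b = p[tri[:, 2]] - p[tri[:, 1]]
    c = p[tri[:, 0]] - p[tri[:, 2]]
    la = np.linalg.norm(a, axis=1)
    lb = np.linalg.norm(b, axis=1)
    lc = np.linalg.norm(c, axis=1)
    # law of cosines at each vertex
    def ang(u, v, lu, lv):
        cosv = np.clip(-(u * v).sum(axis=1) / (lu * lv), -1.0, 1.0)
        return np.arccos(cosv)
    angs = np.column_stack([ang(c, a, lc, la), ang(a, b, la, lb), ang(b, c, lb, lc)])
    return float(np.degrees(angs.min()))


# ---------------------------------------------------------------------------
# domain specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainSpec:
    """Geometry + resolution for initial mesh generation.

    kind: "disc", "annulus_ellipse_in_circle" or "annulus_cell_in_circle".

    For the disc, ``r0`` is its radius (centre ``centre``).  For the annuli,
    ``r0`` parameterises the inner curve (cell radius; ignored for the ellipse,
    which is the fixed curve 4x^2 + 16y^2 = 1) and ``rf`` the outer circle.
    ``h`` is the target edge length; ``h_min`` enables radial grading of the
    edge length from ``h_min`` at the inner curve to ``h`` at the far field.
    ``ns_inner`` optionally fixes the number of nodes on the inner curve.
    """

    kind: str
    h: float
    r0: float = 1.0
    rf: float = 0.0
    centre: tuple[float, float] = (0.0, 0.0)
    h_min: float | None = None
    ns_inner: int | None = None

    def __post_init__(self):
        if self.kind not in ("disc", "annulus_ellipse_in_circle", "annulus_cell_in_circle"):
            raise InvalidDomainError(f"unknown domain kind {self.kind!r}")
        if self.h <= 0:
            raise InvalidDomainError("h must be positive")
        if self.kind != "disc":
            if self.rf <= 0:
                raise InvalidDomainError("annulus requires rf > 0")
            if self.kind == "annulus_cell_in_circle" and not (self.rf > self.r0 > 0):
                raise InvalidDomainError("annulus requires rf > r0 > 0")


@dataclass
class TriMesh:
    """Reference + physical triangulation pair realising the discrete ALE map.

    boundary_loops[0] is the active curve Gamma (disc boundary or inner
    membrane loop); boundary_loops[1], when present, is the outer far-field
    circle.  Every loop is stored counterclockwise around the region it
    encloses, so the discrete normal (t2, -t1) points away from that region.
    """

    ref_coords: np.ndarray
    phys_coords: np.ndarray
    triangles: np.ndarray
    boundary_loops: list[np.ndarray] = field(default_factory=list)

    @property
    def node_count(self) -> int:
        return len(self.phys_coords)

    @property
    def boundary_node_count(self) -> int:
        return len(self.boundary_loops[0])

    def loop_coords(self, which: int = 0) -> np.ndarray:
        return self.phys_coords[self.boundary_loops[which]]

    def copy(self) -> "TriMesh":
        return TriMesh(self.ref_coords.copy(), self.phys_coords.copy(),
                       self.triangles.copy(),
                       [l.copy() for l in self.boundary_loops])

    def validate(self) -> None:
        for name, coords in (("reference", self.ref_coords), ("physical", self.phys_coords)):
            if np.any(triangle_signed_areas(coords, self.triangles) <= 0.0):
                raise TangledMeshError(f"non-positive triangle area in {name} coordinates")

    def with_phys(self, new_phys: np.ndarray) -> "TriMesh":
        m = TriMesh(self.ref_coords, np.asarray(new_phys, float),
                    self.triangles, self.boundary_loops)
        m.validate()
        return m


# ---------------------------------------------------------------------------
# signed distance helpers (polygon-based, used by the mesher)
# ---------------------------------------------------------------------------

def _point_segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(P,) min distance from each point to polyline segments a[i]->b[i]."""
    ab = b - a                                     # (S,2)
    ap = pts[:, None, :] - a[None, :, :]           # (P,S,2)
    denom = (ab * ab).sum(axis=1)                  # (S,)
    tpar = np.clip((ap * ab[None]).sum(axis=2) / np.maximum(denom, 1e-300), 0.0, 1.0)
    closest = a[None] + tpar[:, :, None] * ab[None]
    d = np.linalg.norm(pts[:, None, :] - closest, axis=2)
    return d.min(axis=1)


def _polygon_signed_distance(pts: np.ndarray, loop: np.ndarray) -> np.ndarray:
    """Signed distance to a closed polygon: negative inside."""
    a = loop
    b = np.roll(loop, -1, axis=0)
    d = _point_segment_distance(pts, a, b)
    inside = _MplPath(loop).contains_points(pts)
    return np.where(inside, -d, d)


def domain_signed_distance(pts: np.ndarray, outer: np.ndarray,
                           holes: Sequence[np.ndarray] = ()) -> np.ndarray:
    """Signed distance to the domain outer \\ holes: negative inside."""
    d = _polygon_signed_distance(pts, outer)
    for hole in holes:
        d = np.maximum(d, -_polygon_signed_distance(pts, hole))
    return d


# ---------------------------------------------------------------------------
# boundary curve sampling
# ---------------------------------------------------------------------------

def circle_points(centre, r, n, phase=0.0) -> np.ndarray:
    th = phase + 2 * np.pi * np.arange(n) / n
    return np.column_stack([centre[0] + r * np.cos(th), centre[1] + r * np.sin(th)])


def equidistribute_on_polyline(dense: np.ndarray, n: int,
                               weight: np.ndarray | None = None) -> np.ndarray:
    """Pick n points along a dense closed polyline equidistributing w * ds.

    With ``weight`` None this is plain arc-length equidistribution; otherwise
    the integral of the (nodal) weight along the curve is split into n equal
    parts, which is the steady state of the tangential moving-mesh equation.
    """
    closed = np.vstack([dense, dense[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    if weight is None:
        w_seg = seg
    else:
        w = np.concatenate([np.asarray(weight, float), [weight[0]]])
        w_seg = 0.5 * (w[:-1] + w[1:]) * seg
    W = np.concatenate([[0.0], np.cumsum(w_seg)])
    targets = W[-1] * np.arange(n) / n
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_t = np.interp(targets, W, s)
    out = np.empty((n, 2))
    for k in range(2):
        out[:, k] = np.interp(s_t, s, closed[:, k])
    return out


def ellipse_points(n: int, a: float = 0.5, b: float = 0.25) -> np.ndarray:
    """n points on x^2/a^2 + y^2/b^2 = 1, equidistributed in arc length."""
    phi = np.linspace(0.0, 2 * np.pi, 4096, endpoint=False)
    x = np.column_stack([a * np.cos(phi), b * np.sin(phi)])
    seg = np.linalg.norm(np.diff(np.vstack([x, x[:1]]), axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = total * np.arange(n) / n
    phi_ext = np.concatenate([phi, [2 * np.pi]])
    phit = np.interp(targets, s, phi_ext)
    return np.column_stack([a * np.cos(phit), b * np.sin(phit)])


# ---------------------------------------------------------------------------
# distmesh-style polygon-domain mesher
# ---------------------------------------------------------------------------

def mesh_polygon_domain(outer: np.ndarray,
                        holes: Sequence[np.ndarray] = (),
                        h: float = 0.1,
                        h_func: Callable[[np.ndarray], np.ndarray] | None = None,
                        max_iter: int = 80,
                        seed: int = 0) -> TriMesh:
    """Mesh the region inside ``outer`` and outside each polygon in ``holes``.

    The boundary polygon vertices become mesh nodes and are never moved, so
    the discrete boundary of the produced mesh is exactly the given polygons.
    ``h_func`` (defaults to the constant ``h``) is the target edge length.
    """
    rng = np.random.default_rng(seed)
    outer = np.asarray(outer, float)
    holes = [np.asarray(hl, float) for hl in holes]
    if h_func is None:
        h_func = lambda p: np.full(len(p), h)

    fixed = np.vstack([outer] + list(holes))
    n_fixed = len(fixed)

    # --- seed interior candidates on a hexagonal lattice, rejection-thinned
    lo = outer.min(axis=0) - h
    hi = outer.max(axis=0) + h
    h_seed = float(np.min(h_func(fixed)))
    xs = np.arange(lo[0], hi[0] + h_seed, h_seed)
    ys = np.arange(lo[1], hi[1] + h_seed * np.sqrt(3) / 2, h_seed * np.sqrt(3) / 2)
    X, Y = np.meshgrid(xs, ys)
    X[1::2] += h_seed / 2
    cand = np.column_stack([X.ravel(), Y.ravel()])
    d = domain_signed_distance(cand, outer, holes)
    cand = cand[d < -0.5 * h_seed]          # keep well inside; boundary is fixed
    if len(cand):
        hv = h_func(cand)
        keep = rng.random(len(cand)) < (h_seed / hv) ** 2
        cand = cand[keep]
        # drop interior candidates that crowd fixed boundary nodes
        if len(cand):
            dfix, _ = cKDTree(fixed).query(cand)
            cand = cand[dfix > 0.6 * h_func(cand)]
    pts = np.vstack([fixed, cand])

    geps = 1e-3 * h_seed
    deltat = 0.2
    Fscale = 1.2
    tri = None
    last_retri = None

    def _triangulate(p):
        t = Delaunay(p).simplices
        cent = p[t].mean(axis=1)
        t = t[domain_signed_distance(cent, outer, holes) < -geps]
        return t

    for it in range(max_iter):
        if last_retri is None or np.max(np.linalg.norm(pts - last_retri, axis=1)) > 0.1 * h_seed:
            tri = _triangulate(pts)
            last_retri = pts.copy()
            edges = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
            edges = np.unique(np.sort(edges, axis=1), axis=0)
        vec = pts[edges[:, 0]] - pts[edges[:, 1]]
        L = np.linalg.norm(vec, axis=1)
        mid = 0.5 * (pts[edges[:, 0]] + pts[edges[:, 1]])
        hm = h_func(mid)
        L0 = hm * Fscale * np.sqrt((L ** 2).sum() / (hm ** 2).sum())
        Fmag = np.maximum(L0 - L, 0.0)
        Fvec = (Fmag / np.maximum(L, 1e-300))[:, None] * vec
        force = np.zeros_like(pts)
        np.add.at(force, edges[:, 0], Fvec)
        np.add.at(force, edges[:, 1], -Fvec)
        force[:n_fixed] = 0.0
        pts = pts + deltat * force
        # pull escaped interior points back inside
        d = domain_signed_distance(pts[n_fixed:], outer, holes)
        out = d > -geps
        if np.any(out):
            idx = np.nonzero(out)[0] + n_fixed
            deps = np.sqrt(np.finfo(float).eps) * h_seed
            for k in idx:
                p = pts[k:k + 1]
                dk = domain_signed_distance(p, outer, holes)[0]
                gx = (domain_signed_distance(p + [[deps, 0]], outer, holes)[0] - dk) / deps
                gy = (domain_signed_distance(p + [[0, deps]], outer, holes)[0] - dk) / deps
                g = np.hypot(gx, gy)
                pts[k] -= (dk + 0.5 * h_seed) * np.array([gx, gy]) / max(g, 1e-12)

    tri = _triangulate(pts)

    # drop unused points (candidates that ended up in no triangle)
    used = np.zeros(len(pts), bool)
    used[:n_fixed] = True
    used[tri.ravel()] = True
    remap = -np.ones(len(pts), int)
    remap[used] = np.arange(used.sum())
    pts = pts[used]
    tri = remap[tri]

    # enforce CCW triangles
    areas = triangle_signed_areas(pts, tri)
    flip = areas < 0
    tri[flip] = tri[flip][:, [0, 2, 1]]
    if np.any(triangle_signed_areas(pts, tri) <= 0.0):
        raise MeshGenerationError("mesher produced a degenerate triangle")

    # boundary loops: first all holes (inner curves), then the outer loop,
    # reordered so loops[0] is the active curve Gamma.
    loops = []
    offset = len(outer)
    for hl in holes:
        loops.append(np.arange(offset, offset + len(hl)))
        offset += len(hl)
    loops.append(np.arange(len(outer)))
    if not holes:
        loops = [np.arange(len(outer))]

    # verify each boundary edge is present in the triangulation
    edge_set = set()
    for t in ((0, 1), (1, 2), (2, 0)):
        for e in zip(tri[:, t[0]].tolist(), tri[:, t[1]].tolist()):
            edge_set.add(frozenset(e))
    for loop in loops:
        for i, j in zip(loop.tolist(), np.roll(loop, -1).tolist()):
            if frozenset((i, j)) not in edge_set:
                raise MeshGenerationError("boundary edge missing from triangulation")

    mesh = TriMesh(pts.copy(), pts.copy(), tri, loops)
    mesh.validate()
    return mesh


def generate_initial_mesh(spec: DomainSpec, seed: int = 0) -> TriMesh:
    """Generate the initial mesh for a configured domain.

    Boundary nodes lie on the analytic curves to round-off; the reference
    coordinates are initialised equal to the physical coordinates (the
    computational domain is the initial physical domain).
    """
    cx, cy = spec.centre
    if spec.kind == "disc":
        n_b = max(8, int(round(2 * np.pi * spec.r0 / spec.h)))
        outer = circle_points(spec.centre, spec.r0, n_b)
        return mesh_polygon_domain(outer, [], spec.h, seed=seed)

    if spec.kind == "annulus_ellipse_in_circle":
        # inner curve: ellipse 4x^2 + 16y^2 = 1 (semi-axes 0.5, 0.25)
        per = 2.42  # approximate ellipse perimeter, only used to size Ns
        ns = spec.ns_inner or max(8, int(round(per / spec.h)))
        inner = ellipse_points(ns) + np.array(spec.centre)
        n_out = max(8, int(round(2 * np.pi * spec.rf / spec.h)))
        outer = circle_points(spec.centre, spec.rf, n_out)
        return mesh_polygon_domain(outer, [inner], spec.h, seed=seed)

    # annulus_cell_in_circle: circle of radius r0 inside circle of radius rf,
    # optionally with edge length graded from h_min at the membrane to h far out
    h_min = spec.h_min if spec.h_min is not None else spec.h
    ns = spec.ns_inner or max(8, int(round(2 * np.pi * spec.r0 / h_min)))
    inner = circle_points(spec.centre, spec.r0, ns)
    n_out = max(8, int(round(2 * np.pi * spec.rf / spec.h)))
    outer = circle_points(spec.centre, spec.rf, n_out)

    if spec.h_min is not None and spec.h_min < spec.h:
        r0, rf, hmax = spec.r0, spec.rf, spec.h

        def h_func(p):
            r = np.hypot(p[:, 0] - cx, p[:, 1] - cy)
            t = np.clip((r - r0) / (rf - r0), 0.0, 1.0)
            return h_min + (hmax - h_min) * t
    else:
        h_func = None
    return mesh_polygon_domain(outer, [inner], spec.h, h_func=h_func, seed=seed)


# ---------------------------------------------------------------------------
# point location and interpolation
# ---------------------------------------------------------------------------

def _barycentric(mesh_coords, tri, pts, cells):
    p0 = mesh_coords[tri[cells, 0]]
    p1 = mesh_coords[tri[cells, 1]]
    p2 = mesh_coords[tri[cells, 2]]
    T = np.stack([p1 - p0, p2 - p0], axis=-1)        # (Q,2,2)
    det = T[:, 0, 0] * T[:, 1, 1] - T[:, 0, 1] * T[:, 1, 0]
    rhs = pts - p0
    l1 = (rhs[:, 0] * T[:, 1, 1] - rhs[:, 1] * T[:, 0, 1]) / det
    l2 = (-rhs[:, 0] * T[:, 1, 0] + rhs[:, 1] * T[:, 0, 0]) / det
    return np.column_stack([1.0 - l1 - l2, l1, l2])


def locate_points(mesh: TriMesh, pts: np.ndarray, tol: float = 1e-9):
    """Find (cell index, barycentric coords) for each query point.

    Points within ``tol`` (in barycentric defect, scaled) outside a nearest
    triangle are snapped onto it; anything further raises LocationError.
    """
    import matplotlib.tri as mtri

    pts = np.atleast_2d(np.asarray(pts, float))
    T = mtri.Triangulation(mesh.phys_coords[:, 0], mesh.phys_coords[:, 1],
                           mesh.triangles)
    finder = T.get_trifinder()
    cells = finder(pts[:, 0], pts[:, 1])
    miss = cells < 0
    if np.any(miss):
        # fall back to nearest-node star search with barycentric tolerance
        tree = cKDTree(mesh.phys_coords)
        node2tri = [[] for _ in range(mesh.node_count)]
        for ti, t in enumerate(mesh.triangles):
            for v in t:
                node2tri[v].append(ti)
        for qi in np.nonzero(miss)[0]:
            _, nearest = tree.query(pts[qi])
            best_cell, best_def = -1, np.inf
            cand = set(node2tri[nearest])
            for v in mesh.triangles[list(cand)].ravel() if cand else []:
                cand |= set(node2tri[v])
            for ti in cand:
                lam = _barycentric(mesh.phys_coords, mesh.triangles,
                                   pts[qi:qi + 1], np.array([ti]))[0]
                defect = -min(lam.min(), 0.0)
                if defect < best_def:
                    best_def, best_cell = defect, ti
            if best_cell < 0 or best_def > tol ** 0.5:  # tol on squared scale
                raise LocationError(f"point {pts[qi]} lies outside the mesh")
            cells[qi] = best_cell
    lam = _barycentric(mesh.phys_coords, mesh.triangles, pts, cells)
    lam = np.clip(lam, 0.0, None)
    lam /= lam.sum(axis=1, keepdims=True)
    return cells, lam


def interpolate_to_points(mesh: TriMesh, nodal_field: np.ndarray,
                          query_points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Piecewise-linear (barycentric) interpolation of a nodal field.

    Exact for fields linear in x; the identity when queried at mesh nodes.
    """
    nodal_field = np.asarray(nodal_field, float)
    cells, lam = locate_points(mesh, query_points, tol=tol)
    vals = nodal_field[mesh.triangles[cells]]        # (Q,3) or (Q,3,k)
    if vals.ndim == 2:
        return (lam * vals).sum(axis=1)
    return (lam[:, :, None] * vals).sum(axis=1)


# ---------------------------------------------------------------------------
# remeshing
# ---------------------------------------------------------------------------

def _local_edge_length(mesh: TriMesh) -> np.ndarray:
    """Nodal target edge length carried across a remesh.

    Uses the equilateral-equivalent edge length of the mean incident triangle
    area (sqrt(4 A / sqrt(3))) rather than incident edge lengths: on a
    sheared mesh the latter would bake the distortion into the new sizing,
    while the area measure recovers the isotropic size the region can afford.
    Boundary nodes take the mean adjacent boundary-segment length so the new
    interior grading matches the (fixed) boundary polygon spacing.
    """
    tri = mesh.triangles
    p = mesh.phys_coords
    areas = triangle_signed_areas(p, tri)
    acc = np.zeros(mesh.node_count)
    cnt = np.zeros(mesh.node_count)
    for i in range(3):
        np.add.at(acc, tri[:, i], areas)
        np.add.at(cnt, tri[:, i], 1.0)
    size = np.sqrt(4.0 * (acc / np.maximum(cnt, 1.0)) / np.sqrt(3.0))
    for loop in mesh.boundary_loops:
        c = p[loop]
        seg = np.linalg.norm(np.roll(c, -1, axis=0) - c, axis=1)
        size[loop] = 0.5 * (seg + np.roll(seg, 1))
    return size


def transfer_surface_field(old_loop_coords: np.ndarray, values: np.ndarray,
                           new_loop_coords: np.ndarray) -> np.ndarray:
    """Periodic arc-length-parameter interpolation along the boundary curve."""
    def arcs(c):
        seg = np.linalg.norm(np.diff(np.vstack([c, c[:1]]), axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])
    s_old = arcs(old_loop_coords)
    total = s_old[-1]
    # anchor the new parameterisation at the old curve's nearest point
    tree = cKDTree(old_loop_coords)
    _, j0 = tree.query(new_loop_coords[0])
    s_new = arcs(new_loop_coords)[:-1] + s_old[j0]
    values = np.asarray(values, float)
    vals_ext = np.concatenate([values, values[:1]]) if values.ndim == 1 else \
        np.vstack([values, values[:1]])
    if values.ndim == 1:
        return np.interp(np.mod(s_new, total), s_old, vals_ext, period=None)
    return np.column_stack([
        np.interp(np.mod(s_new, total), s_old, vals_ext[:, k])
        for k in range(values.shape[1])])


def remesh(mesh: TriMesh, bulk_fields: dict[str, np.ndarray] | None = None,
           surface_fields: dict[str, np.ndarray] | None = None,
           seed: int = 0,
           outer_loop_coords: np.ndarray | None = None):
    """Regenerate the mesh with the current boundary polygons held fixed.

    Bulk fields are transferred by barycentric interpolation, surface fields by
    arc-length interpolation along Gamma.  ``outer_loop_coords`` optionally
    replaces the far-field circle (used when the moving window is re-centred);
    bulk nodes that then fall outside the old domain get the nearest-node value.
    Returns (new_mesh, new_bulk_fields, new_surface_fields).
    """
    loops = [mesh.loop_coords(i) for i in range(len(mesh.boundary_loops))]
    if len(loops) == 1:
        outer, holes = loops[0], []
    else:
        holes = [loops[0]]
        outer = loops[1] if outer_loop_coords is None else np.asarray(outer_loop_coords)

    hl = _local_edge_length(mesh)
    from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
    lin = LinearNDInterpolator(mesh.phys_coords, hl)
    near = NearestNDInterpolator(mesh.phys_coords, hl)

    def h_func(p):
        v = lin(p)
        bad = ~np.isfinite(v)
        if np.any(bad):
            v[bad] = near(p[bad])
        return v

    new_mesh = mesh_polygon_domain(outer, holes, h=float(hl.mean()),
                                   h_func=h_func, seed=seed)

    new_bulk = {}
    if bulk_fields:
        tree = cKDTree(mesh.phys_coords)
        for name, vec in bulk_fields.items():
            vals = np.empty(new_mesh.node_count)
            try:
                vals[:] = interpolate_to_points(mesh, vec, new_mesh.phys_coords,
                                                tol=1e-6)
            except LocationError:
                for i, p in enumerate(new_mesh.phys_coords):
                    try:
                        vals[i] = interpolate_to_points(mesh, vec, p[None], tol=1e-6)[0]
                    except LocationError:
                        _, j = tree.query(p)
                        vals[i] = vec[j]
            new_bulk[name] = vals

    new_surf = {}
    if surface_fields:
        old_g = mesh.loop_coords(0)
        new_g = new_mesh.loop_coords(0)
        for name, vec in surface_fields.items():
            new_surf[name] = transfer_surface_field(old_g, vec, new_g)

    return new_mesh, new_bulk, new_surf
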