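"""Parametric geometry of the flagellum-phage complex.

Builds the fibre helix centreline with its orthonormal frames, implicit
(signed-distance) representations of every body, and watertight
triangulated boundary surfaces for the two mechanical models:

* model 1 -- smooth flagellum cylinder with the fibre helix standing off
  the surface;
* model 2 -- flagellum carrying a helical groove (swept circular channel)
  in which the fibre is partly immersed.

Sign convention for all signed distances: positive OUTSIDE the body
(i.e. in the fluid), negative inside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np
from scipy.spatial import cKDTree

from .params import ComplexParams

PHAGE_TAGS = ("fibre", "tail", "head")
BODY_TAGS = ("flagellum",) + PHAGE_TAGS


# ---------------------------------------------------------------------------
# centreline and frames
# ---------------------------------------------------------------------------

@dataclass
class Centreline:
    """Discretised space curve with arclength parameter and local frames.

    ``frames[i]`` stacks the (tangent, normal, binormal) rows of an
    orthonormal triad at ``points[i]``; the normal points toward the
    flagellum axis and the binormal is the Frenet binormal t x n.
    """

    points: np.ndarray      # (n, 3)
    arclength: np.ndarray   # (n,)
    frames: np.ndarray      # (n, 3, 3)

    def __len__(self) -> int:
        return len(self.arclength)


def _helix_angle_theta(params: ComplexParams, l: np.ndarray) -> np.ndarray:
    """Azimuthal angle of the fibre helix at contour length l."""
    R = params.helix_radius
    return l * math.sin(params.alpha_rad) / R


def fibre_centreline_points(params: ComplexParams, l: np.ndarray) -> np.ndarray:
    """Fibre centreline position at contour length(s) ``l`` (vectorised)."""
    l = np.asarray(l, dtype=float)
    R = params.helix_radius
    th = _helix_angle_theta(params, l)
    x = R * np.cos(th)
    y = params.h * R * np.sin(th)
    z = params.z0_eff + l * math.cos(params.alpha_rad)
    return np.stack([x, y, z], axis=-1)


def fibre_frame(params: ComplexParams, l) -> np.ndarray:
    """Orthonormal (tangent, normal, binormal) triad(s) at contour length l.

    The tangent is the exact derivative of the centreline, the normal is
    the principal normal (pointing toward the flagellum axis) and the
    binormal is the Frenet binormal t x n; its z-component is h*sin(alpha).
    Raises ValueError when l is outside [0, L_fib].
    """
    l_arr = np.atleast_1d(np.asarray(l, dtype=float))
    if np.any(l_arr < -1e-12) or np.any(l_arr > params.L_fib + 1e-12):
        raise ValueError("arclength l outside [0, L_fib]")
    sa, ca = math.sin(params.alpha_rad), math.cos(params.alpha_rad)
    h = params.h
    th = _helix_angle_theta(params, l_arr)
    t = np.stack([-sa * np.sin(th), h * sa * np.cos(th),
                  np.full_like(th, ca)], axis=-1)
    n = np.stack([-np.cos(th), -h * np.sin(th), np.zeros_like(th)], axis=-1)
    b = np.cross(t, n)
    out = np.stack([t, n, b], axis=-2)   # (..., 3, 3)
    if np.isscalar(l) or np.asarray(l).ndim == 0:
        return out[0]
    return out


def fibre_centreline(params: ComplexParams, n_points: int) -> Centreline:
    """Sample the fibre centreline at n_points equispaced contour lengths."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    l = np.linspace(0.0, params.L_fib, n_points)
    return Centreline(points=fibre_centreline_points(params, l),
                      arclength=l,
                      frames=fibre_frame(params, l))


def tail_axis(params: ComplexParams):
    """Tail segment (start, end) and unit direction, plus head centre.

    The tail is attached at the fibre's upper end (l = L_fib), tilted
    ``tail_tilt`` off the z-axis in the plane spanned by the local radial
    direction and z, standing off the fibre tip by ``r_fib + tail_gap`` so
    that a clearance ``tail_gap`` separates the tail end cap from the
    spherically capped fibre.  The head sphere is tangent to the far cap.
    """
    tip = fibre_centreline_points(params, np.array([params.L_fib]))[0]
    r_hat = np.array([tip[0], tip[1], 0.0])
    r_hat /= np.linalg.norm(r_hat)
    tilt = math.radians(params.tail_tilt)
    u = math.sin(tilt) * r_hat + math.cos(tilt) * np.array([0.0, 0.0, 1.0])
    start = tip + (params.r_fib + params.tail_gap_eff) * u
    end = start + params.L_t * u
    head_centre = end + params.a_h * u
    return start, end, u, head_centre


# ---------------------------------------------------------------------------
# signed distance primitives
# ---------------------------------------------------------------------------

def sdf_sphere(p: np.ndarray, centre, radius: float) -> np.ndarray:
    return np.linalg.norm(p - np.asarray(centre), axis=-1) - radius


def sdf_capped_cylinder(p: np.ndarray, p0, p1, radius: float) -> np.ndarray:
    """Flat-capped cylinder from p0 to p1 (positive outside)."""
    p0 = np.asarray(p0, dtype=float)
    axis = np.asarray(p1, dtype=float) - p0
    L = np.linalg.norm(axis)
    a = axis / L
    rel = p - p0
    t = rel @ a
    radial = np.linalg.norm(rel - np.outer(t, a), axis=-1)
    dr = radial - radius
    dz = np.maximum(-t, t - L)
    outside = np.hypot(np.maximum(dr, 0.0), np.maximum(dz, 0.0))
    inside = np.minimum(np.maximum(dr, dz), 0.0)
    return outside + inside


class PolylineField:
    """Distance to a densely sampled space curve, via a kd-tree.

    Sampling is fine enough (step ~ r/4 of the querying tube) that the
    polyline-vs-curve error is negligible for the radii used here.
    """

    def __init__(self, points: np.ndarray):
        self.points = np.asarray(points, dtype=float)
        self.tree = cKDTree(self.points)

    def distance(self, p: np.ndarray) -> np.ndarray:
        d, _ = self.tree.query(np.atleast_2d(p))
        return d

    def nearest(self, p: np.ndarray):
        d, idx = self.tree.query(np.atleast_2d(p))
        return d, self.points[idx]


def sdf_capsule_polyline(p: np.ndarray, field: PolylineField, radius: float):
    """Tube of given radius swept along a polyline, spherical end caps."""
    return field.distance(p) - radius


# ---------------------------------------------------------------------------
# bodies
# ---------------------------------------------------------------------------

@dataclass
class Body:
    """One solid of the complex: implicit surface + samplers + tessellation."""

    tag: str
    sdf: Callable[[np.ndarray], np.ndarray]
    project: Callable[[np.ndarray], np.ndarray]
    dense_surface_points: Callable[[float], np.ndarray]
    size_cap: float                     # resolvability cap on local mesh size
    build_surface: Callable[[float], "object"]  # spacing -> trimesh.Trimesh
    size_cap_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def surface_size_caps(self, points: np.ndarray) -> np.ndarray:
        """Per-point resolvability cap (scalar cap unless overridden)."""
        if self.size_cap_fn is not None:
            return self.size_cap_fn(np.atleast_2d(points))
        return np.full(len(np.atleast_2d(points)), self.size_cap)


def _project_sphere(centre, radius):
    centre = np.asarray(centre, dtype=float)

    def proj(p):
        rel = p - centre
        nrm = np.linalg.norm(rel, axis=-1, keepdims=True)
        nrm[nrm == 0] = 1.0
        return centre + radius * rel / nrm
    return proj


def _project_capsule(field: PolylineField, radius: float):
    def proj(p):
        p = np.atleast_2d(p)
        _, cpt = field.nearest(p)
        rel = p - cpt
        nrm = np.linalg.norm(rel, axis=-1, keepdims=True)
        nrm[nrm == 0] = 1.0
        return cpt + radius * rel / nrm
    return proj


def _project_sdf_newton(sdf, n_iter=4, eps=1e-3):
    """Generic projection onto the zero set by damped SDF Newton steps."""
    def proj(p):
        x = np.array(np.atleast_2d(p), dtype=float)
        for _ in range(n_iter):
            f = sdf(x)
            g = np.empty_like(x)
            for k in range(3):
                dx = np.zeros(3)
                dx[k] = eps
                g[:, k] = (sdf(x + dx) - sdf(x - dx)) / (2 * eps)
            gn = np.sum(g * g, axis=1)
            gn[gn < 1e-12] = 1.0
            x -= (f / gn)[:, None] * g
        return x
    return proj


def _project_capped_cylinder(p0, p1, radius):
    """Project to the nearest feature (lateral wall or cap disc) of a cylinder."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    axis = p1 - p0
    L = np.linalg.norm(axis)
    a = axis / L

    def proj(p):
        p = np.atleast_2d(p)
        rel = p - p0
        t = rel @ a
        rad_vec = rel - np.outer(t, a)
        rad = np.linalg.norm(rad_vec, axis=-1)
        safe = np.where(rad < 1e-12, 1.0, rad)
        r_hat = rad_vec / safe[:, None]
        # lateral candidate
        t_cl = np.clip(t, 0.0, L)
        lat = p0 + np.outer(t_cl, a) + radius * r_hat
        # cap candidates
        r_cl = np.minimum(rad, radius)
        cap0 = p0 + r_cl[:, None] * r_hat
        cap1 = p0 + L * a + r_cl[:, None] * r_hat
        cands = np.stack([lat, cap0, cap1], axis=1)
        d = np.linalg.norm(cands - p[:, None, :], axis=-1)
        pick = np.argmin(d, axis=1)
        return cands[np.arange(len(p)), pick]
    return proj


# -- dense surface samplers -------------------------------------------------

def _fibonacci_sphere(centre, radius, spacing) -> np.ndarray:
    n = max(14, int(round(4.0 * math.pi * radius**2 / spacing**2)))
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    cz = 1.0 - 2.0 * i / n
    sz = np.sqrt(np.maximum(0.0, 1.0 - cz**2))
    pts = np.stack([sz * np.cos(phi), sz * np.sin(phi), cz], axis=-1)
    return np.asarray(centre) + radius * pts


def _cylinder_points(p0, p1, radius, spacing, caps=True) -> np.ndarray:
    """Dense points on a capped cylinder's lateral wall and cap discs."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    axis = p1 - p0
    L = np.linalg.norm(axis)
    a = axis / L
    ref = np.array([0.0, 0.0, 1.0])
    if abs(a @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(a, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    pts = []
    n_z = max(2, int(math.ceil(L / spacing)) + 1)
    n_c = max(6, int(math.ceil(2 * math.pi * radius / spacing)))
    zs = np.linspace(0.0, L, n_z)
    for i, z in enumerate(zs):
        # stagger alternating rings by half a step to avoid degenerate tets
        off = (i % 2) * math.pi / n_c
        ang = off + 2 * math.pi * np.arange(n_c) / n_c
        ring = (p0 + z * a
                + radius * (np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2)))
        pts.append(ring)
    if caps:
        for base in (p0, p1):
            pts.append(base[None, :])
            r = radius - spacing
            k = 1
            while r > 0.35 * spacing:
                m = max(6, int(math.ceil(2 * math.pi * r / spacing)))
                off = (k % 2) * math.pi / m
                ang = off + 2 * math.pi * np.arange(m) / m
                pts.append(base + r * (np.outer(np.cos(ang), e1)
                                       + np.outer(np.sin(ang), e2)))
                r -= spacing
                k += 1
    return np.concatenate(pts, axis=0)


def _tube_points(params: ComplexParams, radius, spacing) -> np.ndarray:
    """Dense points on the fibre tube (rings along the helix + end caps)."""
    n_l = max(3, int(math.ceil(params.L_fib / spacing)) + 1)
    cl = fibre_centreline(params, n_l)
    n_c = max(5, int(math.ceil(2 * math.pi * radius / spacing)))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    pts = []
    for i in range(n_l):
        t, n, b = cl.frames[i]
        ang = (i * golden) + 2 * math.pi * np.arange(n_c) / n_c
        ring = cl.points[i] + radius * (np.outer(np.cos(ang), n)
                                        + np.outer(np.sin(ang), b))
        pts.append(ring)
    # spherical end caps
    for i, sgn in ((0, -1.0), (n_l - 1, 1.0)):
        t = sgn * cl.frames[i][0]
        cap = _fibonacci_sphere(cl.points[i], radius, spacing)
        keep = (cap - cl.points[i]) @ t > 0.15 * radius
        pts.append(cap[keep])
        pts.append(cl.points[i][None, :] + radius * t)
    return np.concatenate(pts, axis=0)


# -- triangulated surfaces --------------------------------------------------

def _tube_mesh(params: ComplexParams, radius, spacing):
    """Watertight swept-tube surface for the fibre (area-true cross-section)."""
    import trimesh

    n_l = max(4, int(math.ceil(params.L_fib / spacing)) + 1)
    n_c = max(8, int(math.ceil(2 * math.pi * radius / spacing)))
    # polygon radius preserving the tube cross-section area
    r_poly = radius * math.sqrt(2 * math.pi / (n_c * math.sin(2 * math.pi / n_c)))
    cl = fibre_centreline(params, n_l)
    ang = 2 * math.pi * np.arange(n_c) / n_c
    verts = []
    for i in range(n_l):
        t, n, b = cl.frames[i]
        ring = cl.points[i] + r_poly * (np.outer(np.cos(ang), n)
                                        + np.outer(np.sin(ang), b))
        verts.append(ring)
    verts = np.concatenate(verts, axis=0)
    faces = []
    for i in range(n_l - 1):
        for j in range(n_c):
            a0 = i * n_c + j
            a1 = i * n_c + (j + 1) % n_c
            b0 = (i + 1) * n_c + j
            b1 = (i + 1) * n_c + (j + 1) % n_c
            faces.append([a0, b0, a1])
            faces.append([a1, b0, b1])
    # spherical-ish end caps: one intermediate ring + apex fan per end
    for end, sgn in ((0, -1.0), (n_l - 1, 1.0)):
        t, n, b = cl.frames[end]
        c = cl.points[end]
        mid_r = r_poly * math.cos(math.pi / 4)
        mid = c + sgn * radius * math.sin(math.pi / 4) * t \
            + mid_r * (np.outer(np.cos(ang), n) + np.outer(np.sin(ang), b))
        apex = c + sgn * radius * t
        base_idx = end * n_c + np.arange(n_c)
        mid_idx = len(verts) + np.arange(n_c)
        verts = np.concatenate([verts, mid, apex[None, :]], axis=0)
        apex_idx = len(verts) - 1
        for j in range(n_c):
            j1 = (j + 1) % n_c
            if sgn > 0:
                faces.append([base_idx[j], mid_idx[j], base_idx[j1]])
                faces.append([base_idx[j1], mid_idx[j], mid_idx[j1]])
                faces.append([mid_idx[j], apex_idx, mid_idx[j1]])
            else:
                faces.append([base_idx[j], base_idx[j1], mid_idx[j]])
                faces.append([base_idx[j1], mid_idx[j1], mid_idx[j]])
                faces.append([mid_idx[j], mid_idx[j1], apex_idx])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=True)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _marching_cubes_mesh(sdf, bbox_lo, bbox_hi, pitch):
    """Triangulate the zero set of an SDF on a regular grid."""
    import trimesh
    from skimage.measure import marching_cubes

    lo = np.asarray(bbox_lo, dtype=float)
    hi = np.asarray(bbox_hi, dtype=float)
    # shift the grid by an irrational fraction of the pitch so flat faces
    # (cylinder caps) never coincide with a grid plane
    shift = 0.2137137 * pitch
    lo = lo - shift
    hi = hi + (pitch - shift)
    ns = np.maximum(8, np.ceil((hi - lo) / pitch).astype(int) + 1)
    axes = [np.linspace(lo[k], hi[k], ns[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
    vals = sdf(pts).reshape(X.shape)
    spacing = [(hi[k] - lo[k]) / (ns[k] - 1) for k in range(3)]
    # minute level offset keeps the isosurface off exact grid values, which
    # would produce degenerate (non-manifold after merging) triangles
    verts, faces, _, _ = marching_cubes(vals, level=1.7e-7 * pitch,
                                        spacing=spacing)
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.merge_vertices()
    mesh.update_faces(mesh.unique_faces())
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

def _groove_channel(params: ComplexParams) -> Optional[PolylineField]:
    """Centre helix of the groove channel, spanning the whole flagellum."""
    if params.model != 2 or params.f_cov == 0.0:
        return None
    ca = math.cos(params.alpha_rad)
    r_ch = params.r_fib + params.h_gap_eff
    margin = 3.0 * r_ch
    z_lo = -0.5 * params.L_fl - margin
    z_hi = 0.5 * params.L_fl + margin
    l_lo = (z_lo - params.z0_eff) / ca
    l_hi = (z_hi - params.z0_eff) / ca
    step = max(params.r_fib / 4.0, (l_hi - l_lo) / 20000)
    l = np.arange(l_lo, l_hi + step, step)
    return PolylineField(fibre_centreline_points(params, l))


def groove_channel_radius(params: ComplexParams) -> float:
    return params.r_fib + params.h_gap_eff


def build_bodies(params: ComplexParams) -> Dict[str, Body]:
    """Analytic bodies (SDF + samplers) for every solid of the complex."""
    bodies: Dict[str, Body] = {}
    z_lo, z_hi = -0.5 * params.L_fl, 0.5 * params.L_fl
    p0 = np.array([0.0, 0.0, z_lo])
    p1 = np.array([0.0, 0.0, z_hi])

    # flagellum -------------------------------------------------------------
    channel = _groove_channel(params)
    if channel is None:
        fl_sdf = lambda p: sdf_capped_cylinder(np.atleast_2d(p), p0, p1, params.R_fl)
        fl_proj = _project_capped_cylinder(p0, p1, params.R_fl)

        def fl_dense(s):
            return _cylinder_points(p0, p1, params.R_fl, s)

        def fl_surface(s):
            import trimesh
            n_c = max(16, int(math.ceil(2 * math.pi * params.R_fl / s)))
            m = trimesh.creation.cylinder(radius=params.R_fl,
                                          height=params.L_fl, sections=n_c)
            return m
    else:
        r_ch = groove_channel_radius(params)

        def fl_sdf(p):
            p = np.atleast_2d(p)
            base = sdf_capped_cylinder(p, p0, p1, params.R_fl)
            carved = sdf_capsule_polyline(p, channel, r_ch)
            return np.maximum(base, -carved)

        fl_proj = _project_sdf_newton(fl_sdf)

        def fl_dense(s):
            cyl = _cylinder_points(p0, p1, params.R_fl, s)
            cyl = cyl[sdf_capsule_polyline(cyl, channel, r_ch) > 0.15 * s]
            # groove wall: channel tube points strictly inside the cylinder
            wall = _channel_wall_points(params, channel, r_ch, s)
            inside = sdf_capped_cylinder(wall, p0, p1, params.R_fl) < -0.15 * s
            return np.concatenate([cyl, wall[inside]], axis=0)

        def fl_surface(s):
            pad = 2.0
            lo = [-(params.R_fl + pad), -(params.R_fl + pad), z_lo - pad]
            hi = [params.R_fl + pad, params.R_fl + pad, z_hi + pad]
            pitch = min(s, 0.8 * params.h_gap_eff, 0.8 * params.r_fib)
            pitch = max(pitch, (params.R_fl + pad) / 160)  # grid-size guard
            return _marching_cubes_mesh(fl_sdf, lo, hi, pitch)

    if channel is None:
        fl_capfn = None
    else:
        # the groove wall must stay resolved even where the regional size
        # field is coarse: cap locally near the channel helix
        _r_ch = groove_channel_radius(params)
        _groove_cap = 1.4 * params.r_fib
        _coarse_cap = 0.45 * params.R_fl

        def fl_capfn(p):
            d = channel.distance(np.atleast_2d(p))
            return np.where(d < 2.5 * _r_ch, _groove_cap, _coarse_cap)

    bodies["flagellum"] = Body(
        tag="flagellum", sdf=fl_sdf, project=fl_proj,
        dense_surface_points=fl_dense,
        size_cap=0.45 * params.R_fl,
        build_surface=fl_surface,
        size_cap_fn=fl_capfn)

    # fibre -------------------------------------------------------------
    step = params.r_fib / 4.0
    n_cl = int(math.ceil(params.L_fib / step)) + 1
    fib_field = PolylineField(fibre_centreline(params, n_cl).points)
    fib_sdf = lambda p: sdf_capsule_polyline(np.atleast_2d(p), fib_field, params.r_fib)
    bodies["fibre"] = Body(
        tag="fibre", sdf=fib_sdf,
        project=_project_capsule(fib_field, params.r_fib),
        dense_surface_points=lambda s: _tube_points(params, params.r_fib, s),
        size_cap=1.3 * params.r_fib,
        build_surface=lambda s: _tube_mesh(params, params.r_fib, s))

    # tail -------------------------------------------------------------
    t0, t1, u, head_c = tail_axis(params)
    tail_sdf = lambda p: sdf_capped_cylinder(np.atleast_2d(p), t0, t1, params.r_tail)
    bodies["tail"] = Body(
        tag="tail", sdf=tail_sdf,
        project=_project_capped_cylinder(t0, t1, params.r_tail),
        dense_surface_points=lambda s: _cylinder_points(t0, t1, params.r_tail, s),
        size_cap=0.9 * params.r_tail,
        build_surface=lambda s: _capped_cylinder_mesh(t0, t1, params.r_tail, s))

    # head -------------------------------------------------------------
    head_sdf = lambda p: sdf_sphere(np.atleast_2d(p), head_c, params.a_h)
    bodies["head"] = Body(
        tag="head", sdf=head_sdf,
        project=_project_sphere(head_c, params.a_h),
        dense_surface_points=lambda s: _fibonacci_sphere(head_c, params.a_h, s),
        size_cap=0.4 * params.a_h,
        build_surface=lambda s: _icosphere_mesh(head_c, params.a_h, s))

    return bodies


def _channel_wall_points(params, channel, r_ch, s):
    """Dense points on the groove channel tube (frames from the fibre helix)."""
    ca = math.cos(params.alpha_rad)
    n_c = max(8, int(math.ceil(2 * math.pi * r_ch / s)))
    # reuse fibre frames: channel helix is concentric with the fibre helix
    z_lo = -0.5 * params.L_fl - r_ch
    z_hi = 0.5 * params.L_fl + r_ch
    l_lo = (z_lo - params.z0_eff) / ca
    l_hi = (z_hi - params.z0_eff) / ca
    n_l = max(3, int(math.ceil((l_hi - l_lo) / s)) + 1)
    ls = np.linspace(l_lo, l_hi, n_l)
    centres = fibre_centreline_points(params, ls)
    sa = math.sin(params.alpha_rad)
    th = _helix_angle_theta(params, ls)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    pts = []
    t = np.stack([-sa * np.sin(th), params.h * sa * np.cos(th),
                  np.full_like(th, ca)], axis=-1)
    n = np.stack([-np.cos(th), -params.h * np.sin(th), np.zeros_like(th)], axis=-1)
    b = np.cross(t, n)
    for i in range(n_l):
        ang = i * golden + 2 * math.pi * np.arange(n_c) / n_c
        ring = centres[i] + r_ch * (np.outer(np.cos(ang), n[i])
                                    + np.outer(np.sin(ang), b[i]))
        pts.append(ring)
    return np.concatenate(pts, axis=0)


def gap_sheet_points(params: ComplexParams, spacing: float) -> np.ndarray:
    """Free interior points seeding the narrow fibre-wall clearance.

    The clearance between the fibre tube and the flagellum (1 nm standoff
    gap in model 1, h_gap in the model-2 groove) is narrower than any
    affordable mesh size, so surface-to-surface elements there would have
    every node Dirichlet-constrained; with incompatible wall/fibre data the
    penalty term then manufactures O(lambda) spurious loads.  A sheet of
    unconstrained points on the mid-gap surface gives those elements free
    nodes and resolves the shear layer with one element across the gap.
    """
    n_l = max(3, int(math.ceil(params.L_fib / (0.8 * spacing))) + 1)
    cl = fibre_centreline(params, n_l)
    n = cl.frames[:, 1, :]
    b = cl.frames[:, 2, :]
    if params.model == 1:
        r_mid = 0.5 * (params.r_fib + params.d_eff)
        half_arc = 0.6
        n_phi = 3
    else:
        if params.f_cov == 0.0:
            return np.empty((0, 3))
        r_mid = params.r_fib + 0.5 * params.h_gap_eff
        half_arc = math.pi * params.f_cov * 0.85
        n_phi = max(3, int(math.ceil(2 * half_arc * r_mid / spacing)) | 1)
    phis = np.linspace(-half_arc, half_arc, n_phi)
    pts = []
    for phi in phis:
        off = r_mid * (math.cos(phi) * n + math.sin(phi) * b)
        pts.append(cl.points + off)
    return np.concatenate(pts, axis=0)


def _capped_cylinder_mesh(p0, p1, radius, spacing):
    import trimesh
    n_c = max(12, int(math.ceil(2 * math.pi * radius / spacing)))
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    axis = p1 - p0
    L = np.linalg.norm(axis)
    m = trimesh.creation.cylinder(radius=radius, height=L, sections=n_c)
    a = axis / L
    T = trimesh.geometry.align_vectors([0, 0, 1], a)
    m.apply_transform(T)
    m.apply_translation((p0 + p1) / 2.0)
    return m


def _icosphere_mesh(centre, radius, spacing):
    import trimesh
    subdiv = 2
    while radius * 1.05 / (2 ** subdiv) > spacing and subdiv < 5:
        subdiv += 1
    m = trimesh.creation.icosphere(subdivisions=subdiv, radius=radius)
    m.apply_translation(np.asarray(centre, dtype=float))
    return m


@dataclass
class SceneSurfaces:
    """Watertight tagged boundary surfaces of the complex.

    ``surfaces`` maps each body tag to a trimesh.Trimesh; ``bodies`` keeps
    the analytic (SDF) counterparts used by the volume mesher.
    """

    params: ComplexParams
    bodies: Dict[str, Body]
    surfaces: Dict[str, "object"]

    @property
    def tags(self):
        return tuple(self.surfaces.keys())

    def watertight(self) -> Dict[str, bool]:
        return {tag: bool(m.is_watertight) for tag, m in self.surfaces.items()}

    def volumes(self) -> Dict[str, float]:
        return {tag: float(m.volume) for tag, m in self.surfaces.items()}

    def bounding_boxes(self) -> Dict[str, np.ndarray]:
        return {tag: np.array(m.bounds) for tag, m in self.surfaces.items()}

    def circumscribed_radius(self) -> float:
        """Radius of the origin-centred sphere enclosing every body."""
        r = 0.0
        for m in self.surfaces.values():
            r = max(r, float(np.max(np.linalg.norm(m.vertices, axis=1))))
        return r

    def min_clearance(self, tag_a: str, tag_b: str) -> float:
        """Approximate minimum surface-to-surface distance between bodies.

        Evaluates body-b's SDF at body-a's surface vertices (and vice
        versa), which is exact up to the tessellation density.
        """
        da = float(np.min(self.bodies[tag_b].sdf(self.surfaces[tag_a].vertices)))
        db = float(np.min(self.bodies[tag_a].sdf(self.surfaces[tag_b].vertices)))
        return min(da, db)

    def export_stl(self, directory) -> Dict[str, str]:
        """Write one ASCII STL per body; returns tag -> path."""
        import os
        paths = {}
        os.makedirs(directory, exist_ok=True)
        for tag, m in self.surfaces.items():
            path = os.path.join(directory, f"{tag}.stl")
            m.export(path, file_type="stl_ascii")
            paths[tag] = path
        return paths

    def export_msh(self, path) -> str:
        """Write all tagged surfaces into one Gmsh MSH 4.1 ASCII file."""
        from .meshio_lite import write_msh_surface
        write_msh_surface(path, self.surfaces)
        return path


def _check_scene(params: ComplexParams, bodies: Dict[str, Body]) -> None:
    """Fail loudly on overlaps the models forbid."""
    if params.model == 2:
        depth = params.r_fib + params.h_gap_eff - params.r_fib * math.cos(
            math.pi * params.f_cov)
        if depth >= params.R_fl:
            raise ValueError("groove deeper than the flagellum radius")
    t0, t1, u, head_c = tail_axis(params)
    tail_probe = _cylinder_points(t0, t1, params.r_tail, 2.0)
    if np.min(bodies["flagellum"].sdf(tail_probe)) < 0.0:
        raise ValueError("tail overlaps the flagellum")
    if np.min(bodies["fibre"].sdf(tail_probe)) < 0.0:
        raise ValueError("tail overlaps the fibre")
    if bodies["flagellum"].sdf(head_c[None, :])[0] < params.a_h:
        raise ValueError("head overlaps the flagellum")


def build_scene(params: ComplexParams, scale: float = 1.0) -> SceneSurfaces:
    """Tessellate all bodies into watertight tagged surfaces.

    ``scale`` multiplies the tessellation spacings, whose base values
    follow the local grid-size table used by the volume mesher (fibre
    0.75 nm, tail/head 2.5 nm at scale 1).
    """
    bodies = build_bodies(params)
    _check_scene(params, bodies)
    spacing = {
        "fibre": min(0.75 * scale, bodies["fibre"].size_cap),
        "tail": min(2.5 * scale, bodies["tail"].size_cap),
        "head": min(2.5 * scale, bodies["head"].size_cap),
        "flagellum": min(2.5 * scale, bodies["flagellum"].size_cap),
    }
    surfaces = {tag: bodies[tag].build_surface(spacing[tag])
                for tag in BODY_TAGS}
    return SceneSurfaces(params=params, bodies=bodies, surfaces=surfaces)
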