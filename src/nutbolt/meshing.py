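"""Graded tetrahedral meshing of the fluid domain around the complex.

The fluid region lies between the tagged body surfaces and a large
spherical outer boundary.  Meshing strategy: place points (on every body
surface and graded through the volume, spacing controlled by a size
field), Delaunay-tetrahedralise the cloud, keep tetrahedra whose centroid
lies in the fluid, and tag boundary facets by the body whose interior the
discarded neighbour occupies.  Second-order (ten-node) elements are formed
by edge-midpoint insertion with boundary midpoints projected onto the
analytic body surfaces, giving a curved (isoparametric) boundary
representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .geometry import Body, BODY_TAGS
from .params import ComplexParams

# local grid cell size at scale 1, by region [nm]
SIZE_TABLE = {"fibre": 0.75, "tail": 2.5, "head": 2.5,
              "near": 25.0, "far": 50.0}
GRADATION = 0.3   # max size growth per unit distance (~1.3 between cells)


# ---------------------------------------------------------------------------
# size field
# ---------------------------------------------------------------------------

@dataclass
class SizeField:
    """Target edge length as a function of position.

    Piecewise-regional sizes (fibre / tail+head / a sphere enclosing the
    whole complex / far field), blended by limiting the growth away from
    each refined body to GRADATION per unit distance.  ``scale`` multiplies
    every target size, so the field is exactly linear in ``scale``.
    """

    scale: float
    body_sizes: Dict[str, float]          # base size near each body
    body_sdfs: Dict[str, object]          # distance-to-body callables
    near_centre: np.ndarray
    near_radius: float
    sizes: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.sizes = {k: self.scale * v for k, v in SIZE_TABLE.items()}

    @property
    def far_size(self) -> float:
        return self.sizes["far"]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        r = np.linalg.norm(p - self.near_centre, axis=1)
        s = np.where(r <= self.near_radius, self.sizes["near"],
                     self.sizes["far"])
        # the far size must also respect gradation from the near sphere
        s = np.minimum(s, self.sizes["near"]
                       + GRADATION * np.maximum(r - self.near_radius, 0.0))
        for tag, base in self.body_sizes.items():
            dist = np.maximum(self.body_sdfs[tag](p), 0.0)
            s = np.minimum(s, self.scale * base + GRADATION * dist)
        return s


def make_size_field(params: ComplexParams, scale: float,
                    bodies: Optional[Dict[str, Body]] = None) -> SizeField:
    """Size field with the standard local resolutions (fibre 0.75 nm,
    tail/head 2.5 nm, 25 nm around the complex, 50 nm far field, all
    multiplied by ``scale``)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if bodies is None:
        from .geometry import build_bodies
        bodies = build_bodies(params)
    pts = np.concatenate([b.dense_surface_points(4.0) for b in bodies.values()])
    centre = 0.5 * (pts.min(axis=0) + pts.max(axis=0))
    radius = float(np.max(np.linalg.norm(pts - centre, axis=1))) * 1.15
    return SizeField(
        scale=scale,
        body_sizes={"fibre": SIZE_TABLE["fibre"], "tail": SIZE_TABLE["tail"],
                    "head": SIZE_TABLE["head"]},
        body_sdfs={t: bodies[t].sdf for t in ("fibre", "tail", "head")},
        near_centre=centre, near_radius=radius)


# ---------------------------------------------------------------------------
# FluidMesh
# ---------------------------------------------------------------------------

@dataclass
class FluidMesh:
    """Unstructured ten-node tetrahedral mesh of the fluid domain.

    ``vertices`` are the P1 corners; P2 nodes append edge midpoints, so
    ``nodes = vstack([vertices, midpoints])`` with ``tets10`` indexing into
    it (VTK quadratic-tet local ordering).  Boundary facets carry a body
    tag; ``node_tags`` labels every P2 node lying on a tagged boundary.
    """

    vertices: np.ndarray           # (nv, 3)
    tets: np.ndarray               # (ne, 4) corner indices
    nodes: np.ndarray              # (nn, 3) P2 nodes (corners + midpoints)
    tets10: np.ndarray             # (ne, 10)
    boundary_faces: np.ndarray     # (nb, 3) corner indices
    boundary_tags: np.ndarray      # (nb,) str
    boundary_elem: np.ndarray      # (nb,) adjacent element index
    node_tags: Dict[str, np.ndarray]   # tag -> node indices
    outer_radius: float
    size_scale: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def volumes(self) -> np.ndarray:
        v = self.vertices
        t = self.tets
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        c = v[t[:, 3]] - v[t[:, 0]]
        return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0

    def volume_p2(self) -> float:
        """Total volume with the curved (isoparametric) boundary faces."""
        from .stokes import tet_quadrature, _element_geometry
        q, w = tet_quadrature(3)
        _, det = _element_geometry(self.nodes, self.tets10, q)
        return float(np.sum(det @ w))

    def quality(self) -> dict:
        """Min dihedral angle [deg] and max radius-edge ratio."""
        v = self.vertices
        t = self.tets
        vols = self.volumes()
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        edges = np.stack([np.linalg.norm(v[t[:, j]] - v[t[:, i]], axis=1)
                          for i, j in pairs], axis=1)
        # circumradius from the Cayley-Menger-free formula R = abc.../(6V)?
        # use R = |OP| with O solved from the linear system
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        c = v[t[:, 3]] - v[t[:, 0]]
        A = np.stack([a, b, c], axis=1)
        rhs = 0.5 * np.stack([np.sum(a * a, axis=1), np.sum(b * b, axis=1),
                              np.sum(c * c, axis=1)], axis=1)
        centre = np.linalg.solve(A, rhs[..., None])[..., 0]
        R = np.linalg.norm(centre, axis=1)
        ratio = R / edges.min(axis=1)
        # dihedral angles from face normals
        faces = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
        normals = []
        for f in faces:
            n = np.cross(v[t[:, f[1]]] - v[t[:, f[0]]],
                         v[t[:, f[2]]] - v[t[:, f[0]]])
            n /= np.linalg.norm(n, axis=1)[:, None]
            normals.append(n)
        min_dih = np.full(len(t), 180.0)
        for i in range(4):
            for j in range(i + 1, 4):
                cosd = np.clip(-np.sum(normals[i] * normals[j], axis=1), -1, 1)
                ang = np.degrees(np.arccos(cosd))
                min_dih = np.minimum(min_dih, ang)
        return {"min_dihedral_deg": float(min_dih.min()),
                "median_dihedral_deg": float(np.median(min_dih)),
                "max_radius_edge": float(ratio.max()),
                "min_volume": float(vols.min()),
                "n_elements": int(len(t)), "n_nodes": int(self.n_nodes)}

    def describe(self) -> dict:
        return {"n_vertices": int(len(self.vertices)),
                "n_elements": int(self.n_elements),
                "n_nodes": int(self.n_nodes),
                "outer_radius": float(self.outer_radius),
                "size_scale": float(self.size_scale)}

    def boundary_node_count(self) -> Dict[str, int]:
        return {t: len(idx) for t, idx in self.node_tags.items()}

    def export_vtu(self, path, point_data=None, cell_data=None):
        from .meshio_lite import write_vtu
        write_vtu(path, self, point_data=point_data, cell_data=cell_data)
        return path

    def export_msh(self, path):
        from .meshio_lite import write_msh_volume
        write_msh_volume(path, self)
        return path


# ---------------------------------------------------------------------------
# point placement
# ---------------------------------------------------------------------------

def _thin_points(points: np.ndarray, radii: np.ndarray,
                 blockers: Optional[np.ndarray] = None,
                 blocker_radii: Optional[np.ndarray] = None) -> np.ndarray:
    """Greedy Poisson-disc thinning with per-point radii.

    Keeps a subset so that no two kept points are closer than
    ~min(r_i, r_j); ``blockers`` are already-accepted points that exclude
    candidates within their radii.  Processes candidates fine-to-coarse.
    """
    order = np.argsort(radii, kind="stable")
    pts = points[order]
    rad = radii[order]
    keep_idx = []
    if blockers is not None and len(blockers):
        btree = cKDTree(blockers)
        dist, j = btree.query(pts)
        ok = dist >= 0.75 * np.minimum(rad, blocker_radii[j]) \
            if blocker_radii is not None else dist >= 0.75 * rad
        pts, rad, order = pts[ok], rad[ok], order[ok]
    # grid hash at the finest radius per batch of similar radii
    accepted = np.zeros(len(pts), dtype=bool)
    cell = {}
    inv = 1.0 / np.maximum(rad, 1e-12)
    for i in range(len(pts)):
        r = rad[i]
        key_scale = r * 0.75
        c = tuple((pts[i] // key_scale).astype(np.int64))
        ok = True
        for dx in (-2, -1, 0, 1, 2):
            for dy in (-2, -1, 0, 1, 2):
                for dz in (-2, -1, 0, 1, 2):
                    k = (c[0] + dx, c[1] + dy, c[2] + dz)
                    for j in cell.get(k, ()):
                        d = pts[i] - pts[j]
                        if d @ d < (0.75 * min(r, rad[j])) ** 2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            accepted[i] = True
            cell.setdefault(c, []).append(i)
    kept = pts[accepted]
    return kept


def _surface_points(bodies: Dict[str, Body], size_field: SizeField,
                    rng: np.random.Generator):
    """Thinned surface point sets per body, spaced by the (capped) size field."""
    pts_all, tags_all, rad_all = [], [], []
    for tag, body in bodies.items():
        probe = body.dense_surface_points(50.0)
        s_min = float(np.minimum(size_field(probe),
                                 body.surface_size_caps(probe)).min())
        dense = body.dense_surface_points(max(0.45 * s_min, 0.05))
        # deterministic jitter breaks lattice degeneracies in the Delaunay
        jit = (rng.random(dense.shape) - 0.5) * (0.1 * s_min)
        dense = body.project(dense + jit)
        radii = np.minimum(size_field(dense), body.surface_size_caps(dense))
        kept = _thin_points(dense, radii)
        pts_all.append(kept)
        tags_all.append(np.full(len(kept), tag, dtype=object))
        rad_all.append(np.minimum(size_field(kept),
                                  body.surface_size_caps(kept)))
    return (np.concatenate(pts_all), np.concatenate(tags_all),
            np.concatenate(rad_all))


def _outer_sphere_points(outer_radius: float, spacing: float) -> np.ndarray:
    from .geometry import _fibonacci_sphere
    return _fibonacci_sphere(np.zeros(3), outer_radius, spacing)


def _interior_points(bodies: Dict[str, Body], size_field: SizeField,
                     outer_radius: float, body_pts, blockers, blocker_rad,
                     rng: np.random.Generator) -> np.ndarray:
    """Graded interior points via per-level jittered grids + thinning."""
    s_min = float(size_field(body_pts).min())
    s_max = min(size_field.far_size, outer_radius / 4.0)
    levels = []
    s = s_min
    while s < s_max * 1.01:
        levels.append(min(s, s_max))
        s *= 1.9
    accepted = [blockers]
    accepted_rad = [blocker_rad]
    # bounding box of the refined zone shrinks per level: a point at size
    # level s can only lie within (1.45*s - s_min)/GRADATION of a body
    lo_all, hi_all = body_pts.min(axis=0), body_pts.max(axis=0)
    for s in levels:
        if s >= 0.99 * s_max:
            lo = np.full(3, -outer_radius)
            hi = np.full(3, outer_radius)
        else:
            pad = (1.45 * s - s_min) / GRADATION + 2 * s
            lo = np.maximum(lo_all - pad, -outer_radius)
            hi = np.minimum(hi_all + pad, outer_radius)
        n = np.maximum(1, ((hi - lo) / s).astype(int))
        if int(np.prod(n.astype(np.int64))) > 3e7:
            raise MemoryError("size-field candidate grid too large; "
                              "increase the mesh scale")
        axes = [lo[k] + s * (np.arange(n[k]) + 0.5) for k in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        cand = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
        cand = cand + (rng.random(cand.shape) - 0.5) * (0.35 * s)
        target = size_field(cand)
        band = (target >= s / 1.45) & (target < s * 1.45)
        cand = cand[band]
        if not len(cand):
            continue
        r = np.linalg.norm(cand, axis=1)
        inside = r < outer_radius - 0.6 * min(size_field.far_size, outer_radius / 4.0)
        cand = cand[inside]
        if not len(cand):
            continue
        clear = np.ones(len(cand), dtype=bool)
        for body in bodies.values():
            clear &= body.sdf(cand) > 0.55 * size_field(cand)
        cand = cand[clear]
        if not len(cand):
            continue
        blockers = np.concatenate(accepted)
        brad = np.concatenate(accepted_rad)
        kept = _thin_points(cand, size_field(cand), blockers, brad)
        if len(kept):
            accepted.append(kept)
            accepted_rad.append(size_field(kept))
    return (np.concatenate(accepted[1:])
            if len(accepted) > 1 else np.empty((0, 3)))


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------

_TET_FACES = ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))
_TET10_EDGES = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))


def generate_fluid_mesh(bodies: Dict[str, Body],
                        size_field: SizeField,
                        outer_radius: float,
                        seed: int = 0,
                        smooth_iters: int = 2,
                        extra_points: Optional[np.ndarray] = None,
                        curved_boundary: bool = True) -> FluidMesh:
    """Mesh the fluid between the bodies and the outer sphere.

    Deterministic for a fixed seed.  Raises if any body is closer to the
    outer sphere than its local size (domain too small).
    """
    rng = np.random.default_rng(seed)
    surf_pts, surf_tags, surf_rad = _surface_points(bodies, size_field, rng)
    max_r = np.max(np.linalg.norm(surf_pts, axis=1))
    if outer_radius < max_r * 1.3:
        raise ValueError("outer_radius too small for the scene")
    s_far = min(size_field.far_size, outer_radius / 4.0)
    outer_pts = _outer_sphere_points(outer_radius, s_far)
    if extra_points is None:
        extra_points = np.empty((0, 3))
    blockers = np.concatenate([surf_pts, outer_pts, extra_points])
    blocker_rad = np.concatenate([surf_rad,
                                  np.full(len(outer_pts), s_far),
                                  np.full(len(extra_points), 0.5)])
    inner = _interior_points(bodies, size_field, outer_radius, surf_pts,
                             blockers, blocker_rad, rng)

    def classify(tets, verts):
        cent = verts[tets].mean(axis=1)
        status = np.zeros(len(tets), dtype=int)   # 0 fluid, 1.. body, -1 outer
        rad = np.linalg.norm(cent, axis=1)
        status[rad > outer_radius - 1e-9] = -1
        for k, (tag, body) in enumerate(bodies.items()):
            inside = body.sdf(cent) < 0.0
            status[(status == 0) & inside] = k + 1
        return status

    verts = np.concatenate([surf_pts, outer_pts, extra_points, inner])
    provenance = {"seed": seed, "n_surface": int(len(surf_pts)),
                  "n_outer": int(len(outer_pts)),
                  "n_extra": int(len(extra_points)),
                  "n_interior": int(len(inner))}

    n_fixed = len(surf_pts) + len(outer_pts) + len(extra_points)
    for it in range(max(0, smooth_iters) + 1):
        tri = Delaunay(verts)
        tets = tri.simplices
        status = classify(tets, verts)
        if it == smooth_iters:
            break
        # Lloyd-style smoothing of interior points only
        keep = status == 0
        kept = tets[keep]
        acc = np.zeros_like(verts)
        cnt = np.zeros(len(verts))
        cent = verts[kept].mean(axis=1)
        for j in range(4):
            np.add.at(acc, kept[:, j], cent)
            np.add.at(cnt, kept[:, j], 1.0)
        movable = np.arange(n_fixed, len(verts))
        ok = cnt[movable] > 0
        target = acc[movable[ok]] / cnt[movable[ok], None]
        newpos = 0.5 * verts[movable[ok]] + 0.5 * target
        # reject moves that would enter a body or leave the domain
        good = np.linalg.norm(newpos, axis=1) < outer_radius - 1e-6
        for body in bodies.values():
            good &= body.sdf(newpos) > 0.0
        idx = movable[ok][good]
        verts[idx] = newpos[good]

    fluid = status == 0
    tets = tets[fluid]
    # drop tets with absurd aspect (slivers spanning the far field are fine
    # for Delaunay but poison the FEM when degenerate)
    vols = _tet_volumes(verts, tets)
    neg = vols <= 0
    if np.any(neg):
        # orientation fix: scipy Delaunay can emit either orientation
        t = tets[neg]
        tets[neg] = t[:, [0, 1, 3, 2]]
        vols = _tet_volumes(verts, tets)
    if np.any(vols <= 0):
        raise RuntimeError("degenerate tetrahedra after orientation fix")

    # boundary facets: faces of fluid tets not shared with another fluid tet
    faces, face_elem = _boundary_faces(tets)
    tags = _tag_faces(verts, faces, bodies, outer_radius)

    # restrict to vertices used, reindex
    used = np.unique(tets)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    vertices = verts[used]
    tets = remap[tets]
    faces = remap[faces]

    # vertex provenance tags (surface points only)
    vert_tag = np.full(len(verts), "", dtype=object)
    vert_tag[:len(surf_pts)] = surf_tags
    vert_tag[len(surf_pts):len(surf_pts) + len(outer_pts)] = "outer"
    vert_tag = vert_tag[used]

    nodes, tets10, node_tags = _make_p2(vertices, tets, faces, tags,
                                        vert_tag, bodies, outer_radius,
                                        curved=curved_boundary)
    if curved_boundary:
        nodes = _untangle_p2(nodes, tets10)
    mesh = FluidMesh(vertices=vertices, tets=tets, nodes=nodes,
                     tets10=tets10, boundary_faces=faces,
                     boundary_tags=tags, boundary_elem=face_elem,
                     node_tags=node_tags, outer_radius=outer_radius,
                     size_scale=getattr(size_field, "scale", 1.0),
                     provenance=provenance)
    _check_mesh(mesh, bodies)
    return mesh


def _tet_volumes(verts, tets):
    a = verts[tets[:, 1]] - verts[tets[:, 0]]
    b = verts[tets[:, 2]] - verts[tets[:, 0]]
    c = verts[tets[:, 3]] - verts[tets[:, 0]]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


def _boundary_faces(tets):
    """Faces of the fluid tet set that are not shared by two fluid tets."""
    nf = len(tets) * 4
    f = np.empty((nf, 3), dtype=np.int64)
    elem = np.repeat(np.arange(len(tets)), 4)
    for k, (i, j, l) in enumerate(_TET_FACES):
        f[k::4] = tets[:, (i, j, l)]
    key = np.sort(f, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    key_s = key[order]
    dup = np.zeros(nf, dtype=bool)
    same = np.all(key_s[1:] == key_s[:-1], axis=1)
    dup_idx = np.flatnonzero(same)
    is_dup = np.zeros(nf, dtype=bool)
    is_dup[order[dup_idx]] = True
    is_dup[order[dup_idx + 1]] = True
    bnd = ~is_dup
    return f[bnd], elem[bnd]


def _tag_faces(verts, faces, bodies, outer_radius):
    """Assign each boundary face to the nearest body (or the outer sphere)."""
    cent = verts[faces].mean(axis=1)
    tags = np.full(len(faces), "outer", dtype=object)
    r = np.linalg.norm(cent, axis=1)
    near_outer = r > 0.9 * outer_radius
    dists = np.full(len(faces), np.inf)
    for tag, body in bodies.items():
        d = np.abs(body.sdf(cent))
        closer = (d < dists) & ~near_outer
        tags[closer] = tag
        dists[closer] = d[closer]
    return tags


def _make_p2(vertices, tets, faces, tags, vert_tag, bodies, outer_radius,
             curved: bool = True):
    """Edge-midpoint P2 nodes; boundary midpoints projected to surfaces.

    With ``curved=False`` boundary midpoints stay at the straight midpoint
    (affine elements): less accurate, but the discrete system is then
    exactly equivariant under congruence transformations of the mesh.
    """
    ne = len(tets)
    edges = np.empty((ne * 6, 2), dtype=np.int64)
    for k, (i, j) in enumerate(_TET10_EDGES):
        edges[k::6, 0] = tets[:, i]
        edges[k::6, 1] = tets[:, j]
    edges_sorted = np.sort(edges, axis=1)
    uniq, inverse = np.unique(edges_sorted, axis=0, return_inverse=True)
    mid = 0.5 * (vertices[uniq[:, 0]] + vertices[uniq[:, 1]])

    # which unique edges lie on a tagged boundary face?  The midside tag
    # follows the endpoints' provenance: an edge bridging two different
    # bodies (across an under-resolved clearance) stays FREE -- pinning it
    # to either wall would impose a spurious velocity jump inside elements.
    edge_tag = {}
    face_edges = [(0, 1), (1, 2), (0, 2)]
    for f, tag in zip(faces, tags):
        for i, j in face_edges:
            a, b = (f[i], f[j]) if f[i] < f[j] else (f[j], f[i])
            ta, tb = vert_tag[a], vert_tag[b]
            if ta == tb and ta != "":
                edge_tag[(a, b)] = ta
            elif ta != "" and tb != "" and ta != tb:
                edge_tag.pop((a, b), None)
                edge_tag[(a, b)] = None       # explicitly free
            elif edge_tag.get((a, b)) is not None:
                edge_tag.setdefault((a, b), tag)
    edge_tag = {k: v for k, v in edge_tag.items() if v is not None}
    # project boundary midpoints to the body surface (curved elements)
    by_tag = {}
    for (a, b), tag in edge_tag.items():
        by_tag.setdefault(tag, []).append((a, b))
    edge_index = {(int(a), int(b)): k for k, (a, b) in enumerate(uniq)}
    nv = len(vertices)
    node_tag = np.full(nv + len(uniq), "", dtype=object)
    node_tag[:nv] = vert_tag
    for tag, pairs in by_tag.items():
        ids = np.array([edge_index[p] for p in pairs if p in edge_index])
        if not len(ids):
            continue
        pts = mid[ids]
        if tag == "outer":
            nrm = np.linalg.norm(pts, axis=1, keepdims=True)
            proj = pts * (outer_radius / nrm)
        else:
            proj = bodies[tag].project(pts)
        # cap the projection displacement at a fraction of the edge length
        el = np.linalg.norm(vertices[uniq[ids, 0]] - vertices[uniq[ids, 1]],
                            axis=1)
        disp = np.linalg.norm(proj - pts, axis=1)
        okm = disp <= 0.25 * el
        if curved:
            mid[ids[okm]] = proj[okm]
        node_tag[nv + ids] = tag

    nodes = np.concatenate([vertices, mid])
    tets10 = np.concatenate(
        [tets, nv + inverse.reshape(ne, 6)], axis=1)

    node_tags = {}
    for tag in list(bodies.keys()) + ["outer"]:
        node_tags[tag] = np.flatnonzero(node_tag == tag)
    return nodes, tets10, node_tags


def _untangle_p2(nodes, tets10, max_iter: int = 6):
    """Straighten curved midpoints of any element with a non-positive
    isoparametric Jacobian (slivers near curved boundaries can invert when
    their midside nodes are projected).

    Validity is checked on the vertex-permutation closure of the assembly
    quadrature points, so congruence transformations of the mesh (e.g. the
    mirrored system used to verify chirality antisymmetry) see valid
    elements regardless of how their corners are relabelled.
    """
    from itertools import permutations
    from .stokes import tet10_shape, tet_quadrature

    q, _ = tet_quadrature(3)
    L = np.column_stack([1.0 - q.sum(axis=1), q])
    imgs = {tuple(np.round(row, 12)) for perm in permutations(range(4))
            for row in L[:, perm][:, 1:]}
    q = np.array(sorted(imgs))
    _, dN = tet10_shape(q)
    for _ in range(max_iter):
        coords = nodes[tets10]
        J = np.einsum("eak,qal->eqkl", coords, dN)
        detJ = np.linalg.det(J)
        bad = np.flatnonzero(detJ.min(axis=1) <= 0)
        if not len(bad):
            return nodes
        for k, (i, j) in enumerate(_TET10_EDGES):
            mids = tets10[bad, 4 + k]
            nodes[mids] = 0.5 * (nodes[tets10[bad, i]] + nodes[tets10[bad, j]])
    raise RuntimeError("could not untangle curved elements")


def _check_mesh(mesh: FluidMesh, bodies):
    counts = mesh.boundary_node_count()
    for tag in bodies:
        if counts.get(tag, 0) < 4:
            raise RuntimeError(f"body '{tag}' has no boundary nodes; "
                               "increase resolution")
    if counts.get("outer", 0) < 4:
        raise RuntimeError("outer boundary lost during meshing")


# ---------------------------------------------------------------------------
# convenience: scene -> mesh
# ---------------------------------------------------------------------------

def mesh_complex(params: ComplexParams, scale: float = 4.0,
                 outer_factor: float = 10.0, seed: int = 0,
                 smooth_iters: int = 2, curved_boundary: bool = True):
    """Mesh the full flagellum-phage fluid domain at a given size scale.

    Seeds the narrow fibre-wall clearance with free mid-gap points (see
    :func:`nutbolt.geometry.gap_sheet_points`) so that the penalty method
    sees no fully-constrained gap elements.
    """
    from .geometry import build_bodies, gap_sheet_points

    bodies = build_bodies(params)
    sf = make_size_field(params, scale, bodies)
    pts = np.concatenate([b.dense_surface_points(5.0) for b in bodies.values()])
    circum = float(np.max(np.linalg.norm(pts, axis=1)))
    outer_radius = outer_factor * circum
    gap_spacing = min(SIZE_TABLE["fibre"] * scale,
                      bodies["fibre"].size_cap)
    extras = gap_sheet_points(params, gap_spacing)
    if len(extras):
        ok = np.ones(len(extras), dtype=bool)
        for body in bodies.values():
            ok &= body.sdf(extras) > 0.05
        extras = extras[ok]
    return generate_fluid_mesh(bodies, sf, outer_radius, seed=seed,
                               smooth_iters=smooth_iters, extra_points=extras,
                               curved_boundary=curved_boundary)
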