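"""Surface loads: tractions, axial force and torque on tagged bodies.

Two evaluation routes are provided:

* the variationally consistent (residual-based) route: the nodal reactions
  R = K u on a body's Dirichlet nodes are the discrete boundary fluxes, so
  the force exerted by the fluid ON the body is -sum(R) over its nodes and
  the z-torque is -sum(x R_y - y R_x).  This is the accurate,
  superconvergent route used by the mobility pipeline.
* the direct route: per-facet tractions t = sigma . m with
  sigma = -p I + mu (grad v + grad v^T) evaluated from element gradients on
  the curved boundary faces (m = outward normal of the body).  First-order
  accurate; serves as an independent cross-check and for VTU export.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from .meshing import FluidMesh, _TET_FACES
from .stokes import StokesCase, FlowSolution, tet10_shape


# ---------------------------------------------------------------------------
# variational route
# ---------------------------------------------------------------------------

def axial_force_and_torque(case: StokesCase, sol: FlowSolution,
                           tags: Sequence[str]) -> Tuple[float, float]:
    """(F_z, M_z) exerted by the fluid on the union of tagged bodies.

    The torque axis is the flagellum centreline (z-axis through the
    origin).  Raises on an empty tag set or unknown tags.
    """
    if not tags:
        raise ValueError("empty tag set")
    node_ids = []
    for tag in tags:
        if tag not in case.mesh.node_tags:
            raise KeyError(f"unknown surface tag '{tag}'")
        node_ids.append(case.mesh.node_tags[tag])
    nodes = np.unique(np.concatenate(node_ids))
    R = case.residual_forces(sol)[nodes]
    xy = case.mesh.nodes[nodes]
    F_z = -float(np.sum(R[:, 2]))
    M_z = -float(np.sum(xy[:, 0] * R[:, 1] - xy[:, 1] * R[:, 0]))
    return F_z, M_z


def force_and_torque_vectors(case: StokesCase, sol: FlowSolution,
                             tags: Sequence[str]):
    """Full force vector and z-torque (diagnostics beyond the axial pair)."""
    nodes = np.unique(np.concatenate([case.mesh.node_tags[t] for t in tags]))
    R = case.residual_forces(sol)[nodes]
    xy = case.mesh.nodes[nodes]
    F = -R.sum(axis=0)
    M_z = -float(np.sum(xy[:, 0] * R[:, 1] - xy[:, 1] * R[:, 0]))
    return F, M_z


def load_table(case: StokesCase, sol: FlowSolution) -> "object":
    """Per-tag (F_z, M_z, node count) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for tag in case.mesh.node_tags:
        if not len(case.mesh.node_tags[tag]):
            continue
        F_z, M_z = axial_force_and_torque(case, sol, (tag,))
        rows.append({"tag": tag, "F_z": F_z, "M_z": M_z,
                     "n_nodes": int(len(case.mesh.node_tags[tag]))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# direct (stress-gradient) route
# ---------------------------------------------------------------------------

@dataclass
class SurfaceLoads:
    """Per-facet tractions on one tagged body plus their aggregates."""

    tag: str
    face_centres: np.ndarray     # (nf, 3)
    tractions: np.ndarray        # (nf, 3) force/area on the body
    areas: np.ndarray            # (nf,)
    F: np.ndarray                # aggregated force vector
    F_z: float
    M_z: float

    def resum(self) -> Tuple[float, float]:
        """Re-aggregate from facets (consistency check)."""
        F_z = float(np.sum(self.tractions[:, 2] * self.areas))
        M_z = float(np.sum((self.face_centres[:, 0] * self.tractions[:, 1]
                            - self.face_centres[:, 1] * self.tractions[:, 0])
                           * self.areas))
        return F_z, M_z


# face quadrature: 3 mid-edge points integrate degree-2 exactly
_FACE_QP = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5]])
_FACE_QW = np.full(3, 1.0 / 3.0)

# reference coordinates of the 4 corner nodes
_REF_CORNERS = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                         [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])


def surface_traction(case: StokesCase, sol: FlowSolution,
                     tag: str) -> SurfaceLoads:
    """Tractions on a tagged body from element stress evaluation.

    Uses the recovered element pressure (-lambda * div v) and the P2
    velocity gradient at three quadrature points per curved face.
    """
    mesh = case.mesh
    if sol.pressure is None:
        raise ValueError("solution lacks a recovered pressure")
    sel = np.flatnonzero(mesh.boundary_tags == tag)
    if not len(sel):
        raise KeyError(f"no boundary facets tagged '{tag}'")
    faces = mesh.boundary_faces[sel]
    elems = mesh.boundary_elem[sel]
    tets = mesh.tets[elems]

    # local face id: which corner of the element is NOT on the face
    local_missing = np.empty(len(sel), dtype=int)
    for k in range(len(sel)):
        fs = set(faces[k])
        local_missing[k] = next(j for j in range(4)
                                if tets[k, j] not in fs)
    # _TET_FACES[j] lists the face opposite corner j, outward-oriented
    centres = np.zeros((len(sel), 3))
    tract = np.zeros((len(sel), 3))
    areas = np.zeros(len(sel))
    vel = sol.velocity
    for j in range(4):
        grp = np.flatnonzero(local_missing == j)
        if not len(grp):
            continue
        corners = _TET_FACES[j]
        # barycentric face points -> reference tet coordinates
        ref_pts = _FACE_QP @ _REF_CORNERS[list(corners)]
        N, dN = tet10_shape(ref_pts)
        # reference tangents of the face parametrisation (b1, b2)
        refc = _REF_CORNERS[list(corners)]
        db1 = refc[1] - refc[0]
        db2 = refc[2] - refc[0]
        e = elems[grp]
        coords = mesh.nodes[mesh.tets10[e]]            # (g, 10, 3)
        u_el = vel[mesh.tets10[e]]                     # (g, 10, 3)
        p_el = sol.pressure[e]
        for q in range(len(_FACE_QP)):
            # J[g,k,l] = sum_a coords[g,a,k] dN[q,a,l]
            J = np.einsum("gak,al->gkl", coords, dN[q])
            invJ = np.linalg.inv(J)
            G = np.einsum("al,glk->gak", dN[q], invJ)  # physical grads
            gradv = np.einsum("gak,gai->gik", G, u_el)  # (g, 3comp, 3deriv)
            x_q = np.einsum("a,gak->gk", N[q], coords)
            t1 = np.einsum("gkl,l->gk", J, db1)
            t2 = np.einsum("gkl,l->gk", J, db2)
            nvec = np.cross(t1, t2)                    # outward of element
            dA = np.linalg.norm(nvec, axis=1)
            n_hat = nvec / dA[:, None]
            sigma = case.mu * (gradv + np.transpose(gradv, (0, 2, 1)))
            sigma[:, 0, 0] -= p_el
            sigma[:, 1, 1] -= p_el
            sigma[:, 2, 2] -= p_el
            # traction on the body: m = -n (outward of body)
            t_body = -np.einsum("gik,gk->gi", sigma, n_hat)
            w = _FACE_QW[q] * 0.5 * dA                 # triangle area weight
            tract[grp] += t_body * w[:, None]
            areas[grp] += w
            centres[grp] += x_q * w[:, None]
    centres /= areas[:, None]
    tract /= areas[:, None]
    F = (tract * areas[:, None]).sum(axis=0)
    F_z = float(F[2])
    M_z = float(np.sum((centres[:, 0] * tract[:, 1]
                        - centres[:, 1] * tract[:, 0]) * areas))
    return SurfaceLoads(tag=tag, face_centres=centres, tractions=tract,
                        areas=areas, F=F, F_z=F_z, M_z=M_z)


def global_balance(case: StokesCase, sol: FlowSolution) -> Tuple[float, float]:
    """Net (F_z, M_z) over ALL boundaries; vanishes by momentum balance."""
    tags = [t for t, n in case.mesh.node_tags.items() if len(n)]
    return axial_force_and_torque(case, sol, tags)
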