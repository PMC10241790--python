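"""Penalty-method finite-element solver for incompressible Stokes flow.

Velocity is discretised with second-order (ten-node, isoparametric)
tetrahedral elements.  Incompressibility is enforced by adding the penalty
term lambda*(div v)^2 to the viscous dissipation, so the discrete problem
minimises

    J(v) = int [ 2*mu*eps(v):eps(v) + lambda*(div v)^2 ] dV

over fields matching the rigid-motion Dirichlet data on every boundary.
The viscous term uses a degree-5 conical-product rule (exact for straight
P2 elements, accurate for curved ones); the penalty term is
under-integrated with the 4-point degree-2 rule -- the standard selective
reduced integration that prevents volumetric locking as lambda/mu grows.
Pressure is recovered per element as p = -lambda*(div v).

The assembled system is symmetric positive definite; after eliminating the
Dirichlet rows it is factorised once with a sparse direct LU
(SuperLU), so all elementary motions of one mesh reuse the factorisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import roots_jacobi, roots_legendre

from .meshing import FluidMesh
from .mobility import BoundarySpec


# ---------------------------------------------------------------------------
# reference element
# ---------------------------------------------------------------------------

def tet10_shape(xi: np.ndarray):
    """Shape functions and reference gradients of the 10-node tet.

    ``xi``: (nq, 3) reference coordinates.  Returns N (nq, 10) and
    dN (nq, 10, 3) in the VTK quadratic-tet node ordering (4 corners, then
    midpoints of edges 01, 12, 02, 03, 13, 23).
    """
    xi = np.atleast_2d(xi)
    x, y, z = xi[:, 0], xi[:, 1], xi[:, 2]
    L = np.stack([1.0 - x - y - z, x, y, z], axis=1)           # (nq, 4)
    dL = np.array([[-1.0, -1.0, -1.0],
                   [1.0, 0.0, 0.0],
                   [0.0, 1.0, 0.0],
                   [0.0, 0.0, 1.0]])                            # (4, 3)
    nq = len(xi)
    N = np.empty((nq, 10))
    dN = np.empty((nq, 10, 3))
    for a in range(4):
        N[:, a] = L[:, a] * (2.0 * L[:, a] - 1.0)
        dN[:, a, :] = (4.0 * L[:, a, None] - 1.0) * dL[a]
    edges = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))
    for k, (i, j) in enumerate(edges):
        N[:, 4 + k] = 4.0 * L[:, i] * L[:, j]
        dN[:, 4 + k, :] = 4.0 * (L[:, i, None] * dL[j] + L[:, j, None] * dL[i])
    return N, dN


def tet_quadrature(n: int):
    """Conical-product rule on the reference tet, exact to degree 2n-1.

    Built from Gauss-Jacobi rules so all weights are positive; the weights
    sum to the reference volume 1/6.
    """
    x1, w1 = roots_jacobi(n, 2.0, 0.0)
    x2, w2 = roots_jacobi(n, 1.0, 0.0)
    x3, w3 = roots_legendre(n)
    t1, u1 = (x1 + 1.0) / 2.0, w1 / 8.0
    t2, u2 = (x2 + 1.0) / 2.0, w2 / 4.0
    t3, u3 = (x3 + 1.0) / 2.0, w3 / 2.0
    pts, wts = [], []
    for a, wa in zip(t1, u1):
        for b, wb in zip(t2, u2):
            for c, wc in zip(t3, u3):
                xi = a
                eta = b * (1.0 - a)
                zeta = c * (1.0 - a) * (1.0 - b)
                pts.append((xi, eta, zeta))
                wts.append(wa * wb * wc)
    return np.array(pts), np.array(wts)


def tet_quadrature_p1():
    """One-point centroid rule for the reduced penalty integration.

    Under-integrating the penalty with a single point per element makes the
    recovered pressure piecewise constant (the P2/P0 pair), which is
    inf-sup stable; richer reduced rules (4-point, i.e. discontinuous-P1
    pressure) carry spurious pressure modes on tetrahedra and let the
    penalty energy swamp the viscous physics.
    """
    pts = np.array([[0.25, 0.25, 0.25]])
    w = np.array([1.0 / 6.0])
    return pts, w


# ---------------------------------------------------------------------------
# solution container
# ---------------------------------------------------------------------------

@dataclass
class FlowSolution:
    """Velocity/pressure field for one elementary motion."""

    velocity: np.ndarray          # (nn, 3) nodal velocities
    pressure: np.ndarray          # (ne,) element pressure -lambda*div
    divergence_norm: float        # sqrt(int (div v)^2 dV)
    functional_value: float       # J(v), zero for rigid motions
    residual: float               # relative residual of the free-dof solve
    bc_name: str = ""

    @property
    def u_flat(self) -> np.ndarray:
        return self.velocity.reshape(-1)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _element_geometry(nodes, tets10, qpts):
    """Jacobians, physical gradients and weighted measures at quad points.

    Returns G (ne, nq, 10, 3) and wdet (ne, nq) for the given rule.
    Raises on non-positive Jacobian determinants (inverted curved element).
    """
    N, dN = tet10_shape(qpts)             # dN: (nq, 10, 3)
    coords = nodes[tets10]                # (ne, 10, 3)
    # J[e,q,k,l] = sum_a coords[e,a,k] * dN[q,a,l]
    J = np.einsum("eak,qal->eqkl", coords, dN)
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        bad = int(np.sum(detJ.min(axis=1) <= 0))
        raise RuntimeError(f"{bad} elements have non-positive Jacobians")
    invJ = np.linalg.inv(J)               # (ne, nq, 3, 3)
    G = np.einsum("qal,eqlk->eqak", dN, invJ)
    return G, detJ


def assemble_penalty_system(mesh: FluidMesh, mu: float, lam: float,
                            quad_order: int = 3):
    """Assemble the SPD stiffness matrix of the penalised Stokes functional.

    Dof layout: node-major, (3*i + component).  Returns a CSR matrix of
    size (3*nn, 3*nn).
    """
    nodes, tets10 = mesh.nodes, mesh.tets10
    ne = len(tets10)
    nn = len(nodes)
    qv, wv = tet_quadrature(quad_order)
    Gv, detv = _element_geometry(nodes, tets10, qv)
    qp, wp = tet_quadrature_p1()
    Gp, detp = _element_geometry(nodes, tets10, qp)

    Ke = np.zeros((ne, 3, 10, 3, 10))
    eye = np.eye(3)
    # viscous term: mu * (grad v : grad u + grad v : grad u^T)
    for q in range(len(wv)):
        g = Gv[:, q]                       # (ne, 10, 3)
        w = (wv[q] * detv[:, q])[:, None, None]
        lap = np.einsum("eak,ebk->eab", g, g) * w     # (ne, 10, 10)
        for c in range(3):
            Ke[:, c, :, c, :] += mu * lap
            for d in range(3):
                Ke[:, c, :, d, :] += mu * w * np.einsum("ea,eb->eab",
                                                        g[:, :, d], g[:, :, c])
    # penalty term, reduced integration
    for q in range(len(wp)):
        g = Gp[:, q]
        w = (wp[q] * detp[:, q])[:, None, None]
        for c in range(3):
            for d in range(3):
                Ke[:, c, :, d, :] += lam * w * np.einsum(
                    "ea,eb->eab", g[:, :, c], g[:, :, d])

    # dof order within the element matches Ke's (component, node) layout
    dofs = (3 * tets10[:, None, :] + np.arange(3)[None, :, None]).reshape(ne, 30)
    rows = np.repeat(dofs, 30, axis=1).ravel()
    cols = np.tile(dofs, (1, 30)).ravel()
    # Ke index order (c,a,d,b) must match dof order (c,a) rows, (d,b) cols
    vals = Ke.reshape(ne, 30, 30).ravel()
    K = sp.coo_matrix((vals, (rows, cols)), shape=(3 * nn, 3 * nn)).tocsr()
    return K


# ---------------------------------------------------------------------------
# case: one mesh, one factorisation, many boundary conditions
# ---------------------------------------------------------------------------

class StokesCase:
    """Assembled and factorised penalty-Stokes problem on one mesh.

    The Dirichlet node set (all tagged boundary nodes) is identical for
    every elementary motion, so the reduced stiffness is factorised once
    and each motion costs one back-substitution.
    """

    def __init__(self, mesh: FluidMesh, mu: float, lam: Optional[float] = None,
                 quad_order: int = 3):
        self.mesh = mesh
        self.mu = mu
        self.lam = 1.0e7 * mu if lam is None else lam
        if self.lam < 100.0 * mu:
            raise ValueError("penalty parameter must dominate the viscosity")
        self.K = assemble_penalty_system(mesh, mu, self.lam, quad_order)
        nn = mesh.n_nodes
        bnodes = np.unique(np.concatenate(list(mesh.node_tags.values())))
        self.boundary_nodes = bnodes
        bdofs = (3 * bnodes[:, None] + np.arange(3)).ravel()
        free = np.ones(3 * nn, dtype=bool)
        free[bdofs] = False
        self.free = np.flatnonzero(free)
        self.fixed = bdofs
        self.Kff = self.K[self.free][:, self.free].tocsr()
        self.Kfb = self.K[self.free][:, self.fixed].tocsr()
        # SPD system: symmetric-mode SuperLU without partial pivoting gives
        # the same factorisation several times faster with half the fill
        self._lu = spla.splu(self.Kff.tocsc(), permc_spec="MMD_AT_PLUS_A",
                             diag_pivot_thresh=0.0,
                             options={"SymmetricMode": True})
        # geometry caches for pressure / divergence evaluation
        qp, wp = tet_quadrature_p1()
        self._Gp, self._detp = _element_geometry(mesh.nodes, mesh.tets10, qp)
        self._wp = wp

    # -- helpers -----------------------------------------------------------

    def boundary_values(self, spec: BoundarySpec) -> np.ndarray:
        """Dirichlet velocities on the fixed dofs for a boundary spec."""
        ub = np.zeros((len(self.boundary_nodes), 3))
        pos = {int(n): k for k, n in enumerate(self.boundary_nodes)}
        for tag, nids in self.mesh.node_tags.items():
            if not len(nids):
                continue
            motion = spec.motion(tag)
            vals = motion.velocity(self.mesh.nodes[nids])
            idx = np.array([pos[int(n)] for n in nids])
            ub[idx] = vals
        return ub.reshape(-1)

    def solve(self, spec: BoundarySpec) -> FlowSolution:
        """Solve one elementary motion; Dirichlet data from the spec."""
        ub = self.boundary_values(spec)
        rhs = -self.Kfb @ ub
        uf = self._lu.solve(rhs)
        res = np.linalg.norm(self.Kfb @ ub + self.Kff @ uf)
        scale = max(np.linalg.norm(rhs), 1e-300)
        u = np.zeros(3 * self.mesh.n_nodes)
        u[self.free] = uf
        u[self.fixed] = ub
        vel = u.reshape(-1, 3)
        div_q = np.einsum("eqak,eak->eq", self._Gp, vel[self.mesh.tets10])
        # element pressure: -lambda * mean divergence
        wq = self._wp[None, :] * self._detp
        div_mean = np.sum(div_q * wq, axis=1) / np.sum(wq, axis=1)
        div_norm = math.sqrt(float(np.sum(div_q ** 2 * wq)))
        J = float(u @ (self.K @ u))
        return FlowSolution(velocity=vel, pressure=-self.lam * div_mean,
                            divergence_norm=div_norm, functional_value=J,
                            residual=float(res / scale), bc_name=spec.name)

    def energy(self, velocity: np.ndarray) -> float:
        """J(v) for an arbitrary nodal field (testing hook)."""
        u = velocity.reshape(-1)
        return float(u @ (self.K @ u))

    def residual_forces(self, sol: FlowSolution) -> np.ndarray:
        """Nodal residual K u (the variationally consistent reactions)."""
        return (self.K @ sol.u_flat).reshape(-1, 3)
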