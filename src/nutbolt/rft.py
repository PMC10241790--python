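"""Resistive-force-theory (RFT) twin of the Stokes model.

Drag on each element of the phage is a local, linear, anisotropic function
of its velocity.  Two velocity references are used:

* the helical fibre hugs the flagellum, so its drag (the near-wall
  slender-body coefficient ``zeta_perp = 4*pi*mu / ln(2d/r_fib)``,
  ``zeta_par = zeta_perp/2``) acts on the velocity RELATIVE to the nearest
  material point of the flagellum surface;
* tail and head are far from the wall and use free-space slender-body /
  Stokes-sphere coefficients against the quiescent fluid.

In model 2 the immersed fraction of the fibre circumference is resisted by
a Couette (fully developed shear) sliding law in the groove clearance,
``zeta_groove = mu * (f_cov * 2*pi*r_fib) / h_gap`` per unit length, while
the exposed fraction keeps the near-wall coefficient weighted by
``1 - f_cov``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import Centreline, fibre_centreline, tail_axis
from .motions import (RigidMotion, Rest, RotationZ, TranslationZ, ScrewMotion,
                      angular_rate_z)
from .params import ComplexParams


# ---------------------------------------------------------------------------
# friction coefficients
# ---------------------------------------------------------------------------

def fibre_friction_coefficients(mu: float, d: float, r_fib: float):
    """Near-wall slender-body coefficients (zeta_perp, zeta_par) [Pa*s].

    zeta_perp = 4*pi*mu / ln(2d/r_fib), zeta_par = zeta_perp / 2; valid for
    2d/r_fib > 1 (the image-system construction behind the formula).
    """
    ratio = 2.0 * d / r_fib
    if ratio <= 1.0:
        raise ValueError("2d/r_fib must exceed 1")
    zp = 4.0 * math.pi * mu / math.log(ratio)
    return zp, 0.5 * zp


def tail_friction_coefficients(mu: float, L_t: float, r_tail: float):
    """Free-space slender-body coefficients for the tail cylinder."""
    lam = math.log(2.0 * L_t / r_tail)
    return 4.0 * math.pi * mu / (lam + 0.5), 2.0 * math.pi * mu / (lam - 0.5)


def groove_sliding_coefficient(mu: float, r_fib: float, h_gap: float,
                               f_cov: float) -> float:
    """Couette sliding resistance of the immersed fibre arc, per unit length.

    The immersed arc length of the cross-section is f_cov * 2*pi*r_fib and
    the shear gap is h_gap, so zeta_groove = mu * f_cov * 2*pi*r_fib / h_gap.
    """
    if h_gap <= 0:
        raise ValueError("h_gap must be positive")
    return mu * f_cov * 2.0 * math.pi * r_fib / h_gap


@dataclass(frozen=True)
class FrictionCoefficients:
    """Bundle of all RFT coefficients for one parameter set."""

    zeta_perp_fib: float
    zeta_par_fib: float
    zeta_perp_tail: float
    zeta_par_tail: float
    head_translation: float   # 6*pi*mu*a_h      [Pa*s*nm]
    head_rotation: float      # 8*pi*mu*a_h^3    [Pa*s*nm^3]
    zeta_groove: float

    def __post_init__(self):
        if not math.isclose(self.zeta_par_fib, 0.5 * self.zeta_perp_fib,
                            rel_tol=1e-12):
            raise ValueError("zeta_par_fib must equal zeta_perp_fib / 2")


def friction_for(params: ComplexParams,
                 zeta_perp_fib: Optional[float] = None) -> FrictionCoefficients:
    """Coefficients at the given parameters; zeta_perp_fib may be overridden
    (e.g. by a value extracted from the Stokes solution)."""
    zp, zpar = fibre_friction_coefficients(params.mu, params.d_eff, params.r_fib)
    if zeta_perp_fib is not None:
        zp, zpar = zeta_perp_fib, 0.5 * zeta_perp_fib
    tp, tpar = tail_friction_coefficients(params.mu, params.L_t, params.r_tail)
    zg = (groove_sliding_coefficient(params.mu, params.r_fib,
                                     params.h_gap_eff, params.f_cov)
          if params.f_cov > 0 else 0.0)
    return FrictionCoefficients(
        zeta_perp_fib=zp, zeta_par_fib=zpar,
        zeta_perp_tail=tp, zeta_par_tail=tpar,
        head_translation=6.0 * math.pi * params.mu * params.a_h,
        head_rotation=8.0 * math.pi * params.mu * params.a_h ** 3,
        zeta_groove=zg)


# ---------------------------------------------------------------------------
# element drag integrals
# ---------------------------------------------------------------------------

def nearest_wall_points(points: np.ndarray, R_fl: float) -> np.ndarray:
    """Radially project points onto the flagellum lateral surface."""
    p = np.atleast_2d(points).astype(float).copy()
    rho = np.hypot(p[:, 0], p[:, 1])
    rho_safe = np.where(rho < 1e-12, 1.0, rho)
    p[:, 0] *= R_fl / rho_safe
    p[:, 1] *= R_fl / rho_safe
    return p


def element_drag_integrals(centreline: Centreline,
                           motion: RigidMotion,
                           zeta_perp: float,
                           zeta_par: float,
                           wall_motion: Optional[RigidMotion] = None,
                           R_fl: Optional[float] = None):
    """(F_z, M_z) on a slender element from local anisotropic drag.

    Per unit length the drag is -zeta_par*v_par - zeta_perp*v_perp, where v
    is the element velocity (relative to the nearest wall material point
    when ``wall_motion`` is given), decomposed against the local tangent.
    The torque is taken about the flagellum (z) axis.  Trapezoidal
    quadrature over the stored arclength grid.
    """
    if centreline.frames is None:
        raise ValueError("centreline lacks frames")
    pts = centreline.points
    t = centreline.frames[:, 0, :]
    v = motion.velocity(pts)
    if wall_motion is not None:
        if R_fl is None:
            raise ValueError("R_fl required with wall_motion")
        v = v - wall_motion.velocity(nearest_wall_points(pts, R_fl))
    v_par = np.sum(v * t, axis=1)[:, None] * t
    v_perp = v - v_par
    f = -(zeta_par * v_par + zeta_perp * v_perp)        # force per length
    m_z = pts[:, 0] * f[:, 1] - pts[:, 1] * f[:, 0]
    F_z = float(np.trapezoid(f[:, 2], centreline.arclength))
    M_z = float(np.trapezoid(m_z, centreline.arclength))
    return F_z, M_z


def isotropic_drag_integrals(centreline: Centreline, motion: RigidMotion,
                             zeta: float,
                             wall_motion: Optional[RigidMotion] = None,
                             R_fl: Optional[float] = None):
    """(F_z, M_z) for an isotropic per-length law (groove sliding)."""
    return element_drag_integrals(centreline, motion, zeta, zeta,
                                  wall_motion=wall_motion, R_fl=R_fl)


def _tail_centreline(params: ComplexParams, n: int = 201) -> Centreline:
    p0, p1, u, _ = tail_axis(params)
    s = np.linspace(0.0, params.L_t, n)
    pts = p0[None, :] + s[:, None] * u[None, :]
    # any orthonormal completion of the tangent will do for a straight rod
    ref = np.array([0.0, 0.0, 1.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    nvec = np.cross(u, ref)
    nvec /= np.linalg.norm(nvec)
    b = np.cross(u, nvec)
    frames = np.broadcast_to(np.stack([u, nvec, b]), (n, 3, 3)).copy()
    return Centreline(points=pts, arclength=s, frames=frames)


def head_drag(params: ComplexParams, motion: RigidMotion,
              coeffs: FrictionCoefficients):
    """(F_z, M_z) on the spherical head: point drag at the centre plus the
    spin torque 8*pi*mu*a^3 * omega_z about its own axis."""
    _, _, _, head_c = tail_axis(params)
    v = motion.velocity(head_c[None, :])[0]
    F = -coeffs.head_translation * v
    F_z = float(F[2])
    M_z = float(head_c[0] * F[1] - head_c[1] * F[0])
    M_z -= coeffs.head_rotation * angular_rate_z(motion)
    return F_z, M_z


def phage_drag(params: ComplexParams, motion: RigidMotion,
               coeffs: FrictionCoefficients,
               wall_motion: RigidMotion = Rest(),
               n_fib: int = 801):
    """Total (F_z, M_z) on the phage (fibre + tail + head) for one rigid
    motion of the phage with the flagellum wall moving as ``wall_motion``."""
    fib = fibre_centreline(params, n_fib)
    if params.model == 1 or params.f_cov == 0.0:
        F_f, M_f = element_drag_integrals(
            fib, motion, coeffs.zeta_perp_fib, coeffs.zeta_par_fib,
            wall_motion=wall_motion, R_fl=params.R_fl)
    else:
        # exposed fraction: near-wall anisotropic law, weight (1 - f_cov)
        w = 1.0 - params.f_cov
        F_e, M_e = element_drag_integrals(
            fib, motion, w * coeffs.zeta_perp_fib, w * coeffs.zeta_par_fib,
            wall_motion=wall_motion, R_fl=params.R_fl)
        # immersed fraction: Couette sliding in the groove clearance
        F_g, M_g = isotropic_drag_integrals(
            fib, motion, coeffs.zeta_groove,
            wall_motion=wall_motion, R_fl=params.R_fl)
        F_f, M_f = F_e + F_g, M_e + M_g
    tail = _tail_centreline(params)
    F_t, M_t = element_drag_integrals(tail, motion, coeffs.zeta_perp_tail,
                                      coeffs.zeta_par_tail)
    F_h, M_h = head_drag(params, motion, coeffs)
    return F_f + F_t + F_h, M_f + M_t + M_h


# ---------------------------------------------------------------------------
# C-coefficients from RFT
# ---------------------------------------------------------------------------

def assemble_rft_coefficients(params: ComplexParams,
                              coeffs: Optional[FrictionCoefficients] = None,
                              eps: float = 1.0):
    """RFT counterparts of the linearised force/torque coefficients.

    Model 1 returns all six C's (phage loads per unit flagellum rotation,
    phage rotation, phage translation); model 2 returns C1, C3, C4, C6
    (co-rotation and groove-screw elementary motions).  Import is local to
    avoid a circular module dependency.
    """
    from .mobility import MobilityCoefficients

    if coeffs is None:
        coeffs = friction_for(params)
    if params.model == 1:
        # flagellum rotates, phage at rest
        F1, M1 = phage_drag(params, Rest(), coeffs,
                            wall_motion=RotationZ(eps))
        # phage rotates, flagellum at rest
        F2, M2 = phage_drag(params, RotationZ(eps), coeffs)
        # phage translates, flagellum at rest
        F3, M3 = phage_drag(params, TranslationZ(eps), coeffs)
        return MobilityCoefficients(
            C1=F1 / eps, C2=F2 / eps, C3=F3 / eps,
            C4=M1 / eps, C5=M2 / eps, C6=M3 / eps,
            epsilon=eps, model=1, provenance={"method": "rft"})
    # model 2: co-rotation of phage and flagellum
    F1, M1 = phage_drag(params, RotationZ(eps), coeffs,
                        wall_motion=RotationZ(eps))
    # screw motion along the groove, flagellum at rest
    screw = ScrewMotion(eps, params.alpha, params.helix_radius, params.h)
    F3, M3 = phage_drag(params, screw, coeffs)
    return MobilityCoefficients(
        C1=F1 / eps, C2=math.nan, C3=F3 / eps,
        C4=M1 / eps, C5=math.nan, C6=M3 / eps,
        epsilon=eps, model=2, provenance={"method": "rft"})


def rft_translocation_speed(params: ComplexParams,
                            coeffs: Optional[FrictionCoefficients] = None):
    """Convenience: full RFT mobility solve for the given parameters."""
    from .mobility import solve_model1, solve_model2

    C = assemble_rft_coefficients(params, coeffs)
    if params.model == 1:
        return solve_model1(C, params.omega_fl, R_fl=params.R_fl)
    return solve_model2(C, params.omega_fl, params)
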