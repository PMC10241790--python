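"""Linearised mobility problem of the flagellum-phage complex.

The steady state is fixed by zero net axial force and torque on the phage.
Because Stokes flow is linear, the loads are linear in the kinematic
degrees of freedom; unit elementary motions give the coefficients

    model 1:  F_z = C1*w_fl + C2*w_p + C3*U,   M_z = C4*w_fl + C5*w_p + C6*U
    model 2:  F_z = C1*w_fl + h*L_fib*k_delta*sin(a) + C3*V,
              M_z = C4*w_fl - h*L_fib*R_fl*k_delta*cos(a) + C6*V

and the mobility solve is a 2x2 linear system for (w_p, U), respectively
(k_delta, V) with U = V*cos(a).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .motions import RigidMotion, Rest, RotationZ, TranslationZ, ScrewMotion
from .params import ComplexParams
from .geometry import PHAGE_TAGS


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundarySpec:
    """Per-tag rigid-motion boundary descriptors; the outer boundary rests."""

    motions: Dict[str, RigidMotion]
    name: str = ""

    def __post_init__(self):
        outer = self.motions.get("outer", Rest())
        if not isinstance(outer, Rest):
            raise ValueError("outer boundary must be at rest")

    def motion(self, tag: str) -> RigidMotion:
        return self.motions.get(tag, Rest())

    def scaled(self, factor: float) -> "BoundarySpec":
        return BoundarySpec({t: m.scaled(factor)
                             for t, m in self.motions.items()},
                            name=self.name)


@dataclass
class MobilityCoefficients:
    """Force/torque coefficients C1..C6 of the linearised balance.

    C1-C3 are axial forces per unit rate [Pa*s*nm^2 per rad/s or per nm/s];
    C4-C6 the corresponding axial torques.  Model 2 carries only C1, C3,
    C4, C6 (C2, C5 are NaN).
    """

    C1: float
    C2: float
    C3: float
    C4: float
    C5: float
    C6: float
    epsilon: float = 1.0
    model: int = 1
    provenance: dict = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([self.C1, self.C2, self.C3,
                         self.C4, self.C5, self.C6])


@dataclass
class MobilitySolution:
    """Solved kinematics: (w_p, U) for model 1, (k_delta, V, U) for model 2."""

    model: int
    omega_fl: float
    U: float                     # translocation speed [nm/s]
    omega_p: float = math.nan    # phage rotation rate [rad/s] (model 1)
    k_delta: float = math.nan    # groove restoring force per length (model 2)
    V: float = math.nan          # screw speed along the groove (model 2)
    U_dimensionless: float = math.nan   # U / (omega_fl * R_fl)


# ---------------------------------------------------------------------------
# elementary motions
# ---------------------------------------------------------------------------

def elementary_motion_bcs(params: ComplexParams,
                          eps: float = 1.0) -> List[BoundarySpec]:
    """Unit-perturbation boundary conditions, one per degree of freedom.

    Model 1: (i) flagellum rotation, (ii) phage rotation, (iii) phage axial
    translation.  Model 2: (i) rigid co-rotation of flagellum and phage,
    (ii) screw motion of the phage along the groove helix.
    """
    if params.model == 1:
        return [
            BoundarySpec({"flagellum": RotationZ(eps)}, name="flagellum-rotation"),
            BoundarySpec({t: RotationZ(eps) for t in PHAGE_TAGS},
                         name="phage-rotation"),
            BoundarySpec({t: TranslationZ(eps) for t in PHAGE_TAGS},
                         name="phage-translation"),
        ]
    if params.model == 2:
        co = {t: RotationZ(eps) for t in PHAGE_TAGS + ("flagellum",)}
        screw = ScrewMotion(eps, params.alpha, params.helix_radius, params.h)
        return [
            BoundarySpec(co, name="co-rotation"),
            BoundarySpec({t: screw for t in PHAGE_TAGS}, name="groove-screw"),
        ]
    raise ValueError("model must be 1 or 2")


# ---------------------------------------------------------------------------
# mobility solves
# ---------------------------------------------------------------------------

def solve_model1(C: MobilityCoefficients, omega_fl: float,
                 R_fl: Optional[float] = None) -> MobilitySolution:
    """Solve C2*w_p + C3*U = -C1*w_fl, C5*w_p + C6*U = -C4*w_fl."""
    A = np.array([[C.C2, C.C3], [C.C5, C.C6]])
    if abs(np.linalg.det(A)) < 1e-14 * max(1.0, np.abs(A).max() ** 2):
        raise np.linalg.LinAlgError("singular mobility block (C2,C3;C5,C6)")
    rhs = -omega_fl * np.array([C.C1, C.C4])
    omega_p, U = np.linalg.solve(A, rhs)
    sol = MobilitySolution(model=1, omega_fl=omega_fl, U=float(U),
                           omega_p=float(omega_p))
    if R_fl is not None and omega_fl != 0.0:
        sol.U_dimensionless = sol.U / (omega_fl * R_fl)
    return sol


def solve_model2(C: MobilityCoefficients, omega_fl: float,
                 params: ComplexParams) -> MobilitySolution:
    """Solve for (k_delta, V); the restoring-force torque arm is R_fl.

    The restoring force per unit length is k_delta times the Frenet
    binormal, whose z-component carries the chirality index h while the
    azimuthal component does not: the force row of the balance therefore
    has an h factor and the torque row does not (at h = +1, the only case
    with published results, both conventions coincide).
    """
    sa = math.sin(params.alpha_rad)
    ca = math.cos(params.alpha_rad)
    h, L = params.h, params.L_fib
    A = np.array([[h * L * sa, C.C3],
                  [-L * params.R_fl * ca, C.C6]])
    if abs(np.linalg.det(A)) < 1e-14 * max(1.0, np.abs(A).max() ** 2):
        raise np.linalg.LinAlgError("singular mobility block (k_delta, V)")
    rhs = -omega_fl * np.array([C.C1, C.C4])
    k_delta, V = np.linalg.solve(A, rhs)
    U = float(V) * ca
    sol = MobilitySolution(model=2, omega_fl=omega_fl, U=U,
                           k_delta=float(k_delta), V=float(V))
    if omega_fl != 0.0:
        sol.U_dimensionless = U / (omega_fl * params.R_fl)
    return sol


def limiting_translocation_speed(omega_fl: float, R_fl: float,
                                 alpha_deg: float) -> float:
    """Zero-slip limit U = omega_fl * R_fl * cot(alpha).

    This is the axial velocity of a material point of the rotating groove
    helix: with an infinitely long tail the phage cannot co-rotate, so it
    rides the groove like a nut on a bolt.
    """
    if not (0.0 < alpha_deg < 90.0):
        raise ValueError("alpha must lie strictly between 0 and 90 deg")
    a = math.radians(alpha_deg)
    return omega_fl * R_fl / math.tan(a)


# ---------------------------------------------------------------------------
# FEM route: coefficients from Stokes solutions
# ---------------------------------------------------------------------------

def compute_coefficients(case, params: ComplexParams, eps: float = 1.0):
    """C-coefficients from penalty-Stokes solves of the elementary motions.

    ``case`` is a :class:`nutbolt.stokes.StokesCase` built on a mesh of the
    same parameter set.  Returns (MobilityCoefficients, details) where
    details stores per-motion phage and fibre-only loads and solver
    diagnostics (used for friction-coefficient extraction and regression
    monitoring).
    """
    from .loads import axial_force_and_torque

    specs = elementary_motion_bcs(params, eps=eps)
    Cs_F, Cs_M = [], []
    details = {"motions": [], "mesh": case.mesh.describe()}
    for spec in specs:
        sol = case.solve(spec)
        F_ph, M_ph = axial_force_and_torque(case, sol, PHAGE_TAGS)
        F_fib, M_fib = axial_force_and_torque(case, sol, ("fibre",))
        Cs_F.append(F_ph / eps)
        Cs_M.append(M_ph / eps)
        details["motions"].append({
            "name": spec.name,
            "F_z_phage": F_ph, "M_z_phage": M_ph,
            "F_z_fibre": F_fib, "M_z_fibre": M_fib,
            "divergence_norm": sol.divergence_norm,
            "J": sol.functional_value,
        })
    if params.model == 1:
        C = MobilityCoefficients(
            C1=Cs_F[0], C2=Cs_F[1], C3=Cs_F[2],
            C4=Cs_M[0], C5=Cs_M[1], C6=Cs_M[2],
            epsilon=eps, model=1,
            provenance={"method": "fem", **details["mesh"]})
    else:
        C = MobilityCoefficients(
            C1=Cs_F[0], C2=math.nan, C3=Cs_F[1],
            C4=Cs_M[0], C5=math.nan, C6=Cs_M[1],
            epsilon=eps, model=2,
            provenance={"method": "fem", **details["mesh"]})
    return C, details


# ---------------------------------------------------------------------------
# friction-coefficient extraction
# ---------------------------------------------------------------------------

def _fibre_rft_unit_integrals(params: ComplexParams, route: str):
    """Fibre (F_z, M_z) from the RFT drag integral at zeta_perp = 1."""
    from .rft import element_drag_integrals
    from .geometry import fibre_centreline

    fib = fibre_centreline(params, 801)
    if route == "translocation":
        return element_drag_integrals(fib, TranslationZ(1.0), 1.0, 0.5,
                                      wall_motion=Rest(), R_fl=params.R_fl)
    if route == "rotation":
        return element_drag_integrals(fib, Rest(), 1.0, 0.5,
                                      wall_motion=RotationZ(1.0),
                                      R_fl=params.R_fl)
    raise ValueError("route must be 'translocation' or 'rotation'")


def extract_fibre_friction_coefficient(params: ComplexParams,
                                       F_z_fibre: float, M_z_fibre: float,
                                       route: str = "translocation") -> float:
    """Perpendicular fibre friction coefficient implied by Stokes loads.

    Matches the RFT fibre drag integral (with zeta_par = zeta_perp/2) to
    the FEM force and torque on the fibre surface for one elementary
    motion, in the relative least-squares sense.  ``route`` selects the
    elementary motion: 'translocation' (phage translation, C3/C6 data) or
    'rotation' (flagellum rotation, C1/C4 data).
    """
    phi = np.array(_fibre_rft_unit_integrals(params, route))
    target = np.array([F_z_fibre, M_z_fibre])
    if np.any(np.abs(target) < 1e-300) or np.any(np.abs(phi) < 1e-300):
        raise ValueError("degenerate loads; cannot extract friction coefficient")
    a = phi / target               # zeta * a_i ~ 1
    zeta = float(np.sum(a) / np.sum(a * a))
    if not np.isfinite(zeta) or zeta <= 0:
        raise ValueError("ill-conditioned friction-coefficient fit")
    return zeta
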