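"""Shared fixtures: the sphere validation case and a lazy cache of
flagellum-phage FEM runs at the desk-scale study conditions.

The desk-scale conditions (fibre contour length 80 nm, mesh scale 6, outer
boundary at 2.2 x the circumscribed radius, fixed seed) are chosen once so
the whole graded suite runs on a single CPU; trend directions at these
conditions are cross-checked against the RFT twin, which is also evaluated
at the full-size geometry where it is cheap.
"""

from __future__ import annotations

import gc
import math

import numpy as np
import pytest

try:
    from hypothesis import settings, HealthCheck
    settings.register_profile(
        "ci", derandomize=True,
        suppress_health_check=[HealthCheck.too_slow])
    settings.load_profile("ci")
except ImportError:
    pass

from nutbolt.params import ComplexParams
from nutbolt.geometry import PHAGE_TAGS, fibre_centreline_points

CI_SCALE = 6.0
CI_SCALE_COARSE = 8.0
CI_OUTER = 2.2
CI_SEED = 1
CI_LFIB = 80.0


def ci_params(model: int, **overrides) -> ComplexParams:
    return ComplexParams(model=model, L_fib=CI_LFIB, **overrides)


# ---------------------------------------------------------------------------
# sphere benchmark case (kept alive for the whole session: it is small)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def sphere_case():
    from nutbolt.benchmarks import sphere_fluid_mesh
    from nutbolt.stokes import StokesCase

    mesh = sphere_fluid_mesh(a=1.0, outer_radius=20.0, near=0.3, far=4.0,
                             seed=0)
    return StokesCase(mesh, mu=1.0e-3)


# ---------------------------------------------------------------------------
# scene FEM results, computed lazily and with the heavy factorisation freed
# ---------------------------------------------------------------------------

_SCENE_DEFS = {
    "m1_220": dict(model=1),
    "m1_440": dict(model=1, L_t=440.0),
    "m2_110": dict(model=2, L_t=110.0),
    "m2_220": dict(model=2),
    "m2_440": dict(model=2, L_t=440.0),
    "m2_ah60": dict(model=2, a_h=60.0),
    "m2_fcov75": dict(model=2, f_cov=0.75),
    "m2_scale8": dict(model=2, _scale=CI_SCALE_COARSE),
    "m1_straight": dict(model=1, _scale=CI_SCALE_COARSE, _straight=True),
}


def _run_scene(key: str) -> dict:
    from nutbolt.meshing import mesh_complex
    from nutbolt.stokes import StokesCase
    from nutbolt.mobility import (compute_coefficients, solve_model1,
                                  solve_model2,
                                  extract_fibre_friction_coefficient,
                                  elementary_motion_bcs)
    from nutbolt.rft import rft_translocation_speed
    from nutbolt.loads import axial_force_and_torque

    spec = dict(_SCENE_DEFS[key])
    scale = spec.pop("_scale", CI_SCALE)
    straight = spec.pop("_straight", False)
    model = spec.pop("model")
    params = ci_params(model, **spec)
    mesh = mesh_complex(params, scale=scale, outer_factor=CI_OUTER,
                        seed=CI_SEED, curved_boundary=not straight)
    case = StokesCase(mesh, mu=params.mu)
    C, details = compute_coefficients(case, params)
    out = {
        "params": params,
        "C": C,
        "motions": {m["name"]: m for m in details["motions"]},
        "mesh": mesh.describe(),
        "rft_U_dimless": rft_translocation_speed(params).U_dimensionless,
    }
    if model == 1:
        sol = solve_model1(C, params.omega_fl, R_fl=params.R_fl)
        mo = out["motions"]
        out["zeta_translocation"] = extract_fibre_friction_coefficient(
            params, mo["phage-translation"]["F_z_fibre"],
            mo["phage-translation"]["M_z_fibre"], "translocation")
        out["zeta_rotation"] = extract_fibre_friction_coefficient(
            params, mo["flagellum-rotation"]["F_z_fibre"],
            mo["flagellum-rotation"]["M_z_fibre"], "rotation")
    else:
        sol = solve_model2(C, params.omega_fl, params)
    out["U"] = sol.U
    out["U_dimless"] = sol.U_dimensionless
    out["solution"] = sol

    if key == "m1_220":
        # epsilon-doubling re-check of linearity of the C extraction
        C2s = []
        for bc in elementary_motion_bcs(params, eps=2.0):
            s = case.solve(bc)
            F, M = axial_force_and_torque(case, s, PHAGE_TAGS)
            C2s.append((F / 2.0, M / 2.0))
        out["C_eps2"] = np.array([[f for f, _ in C2s], [m for _, m in C2s]])
        # steady-state flow synthesised from the elementary fields
        sols = [case.solve(bc) for bc in elementary_motion_bcs(params)]
        v_steady = (params.omega_fl * sols[0].velocity
                    + sol.omega_p * sols[1].velocity
                    + sol.U * sols[2].velocity)
        out["steady_wake_mean_w"] = _wake_statistic(params, mesh.nodes,
                                                    v_steady)
    if key == "m1_straight":
        # straight (affine) elements: the degree-5 rule integrates their
        # stiffness exactly, so the discrete system is exactly equivariant
        # under the mirror relabelling used by the chirality check
        sols = [case.solve(bc) for bc in elementary_motion_bcs(params)]
        out["mirror_pack"] = {
            "nodes": mesh.nodes.copy(),
            "tets10": mesh.tets10.copy(),
            "node_tags": {t: v.copy() for t, v in mesh.node_tags.items()},
            "velocities": [s.velocity.copy() for s in sols],
        }
    del case
    gc.collect()
    return out


def _wake_statistic(params, nodes, velocity):
    """Mean z-velocity in boxes beside the fibre (same helix radius, offset
    in azimuth), for the synthesised steady translocating state."""
    R = params.helix_radius
    rho = np.hypot(nodes[:, 0], nodes[:, 1])
    near_radius = np.abs(rho - R) < 2.5 * params.r_fib
    z_mid = params.z0_eff + 0.5 * params.L_fib * math.cos(params.alpha_rad)
    central = np.abs(nodes[:, 2] - z_mid) < 0.3 * params.L_fib
    # azimuthal offset from the local fibre strand
    theta = np.arctan2(nodes[:, 1] * params.h, nodes[:, 0])
    l_here = (nodes[:, 2] - params.z0_eff) / math.cos(params.alpha_rad)
    theta_fib = l_here * math.sin(params.alpha_rad) / R
    dtheta = np.angle(np.exp(1j * (theta - theta_fib)))
    beside = (np.abs(dtheta) > math.pi / 3) & (np.abs(dtheta) < math.pi)
    sel = near_radius & central & beside
    if sel.sum() < 10:
        return float("nan")
    return float(np.mean(velocity[sel, 2]))


class _SceneCache:
    def __init__(self):
        self._store = {}

    def __call__(self, key: str) -> dict:
        if key not in self._store:
            self._store[key] = _run_scene(key)
        return self._store[key]


@pytest.fixture(scope="session")
def scene_results():
    return _SceneCache()
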