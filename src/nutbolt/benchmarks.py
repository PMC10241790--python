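"""Canonical validation fixtures for the Stokes solver.

Closed-form oracles for a solid sphere in a large spherical container:
drag 6*pi*mu*a*U on a translating sphere and torque 8*pi*mu*a^3*omega on a
rotating one.  These exercise the whole meshing -> assembly -> solve ->
loads pipeline on geometry with known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import Body, sdf_sphere, _fibonacci_sphere, _project_sphere
from .meshing import generate_fluid_mesh, FluidMesh


@dataclass
class SimpleSizeField:
    """Size that grows linearly with distance from an inner sphere."""

    centre: np.ndarray
    inner_radius: float
    near: float
    far: float
    gradation: float = 0.35
    scale: float = 1.0

    @property
    def far_size(self) -> float:
        return self.far

    def __call__(self, points):
        p = np.atleast_2d(points)
        d = np.maximum(np.linalg.norm(p - self.centre, axis=1)
                       - self.inner_radius, 0.0)
        return np.minimum(self.far, self.near + self.gradation * d)


def sphere_body(radius: float, centre=(0.0, 0.0, 0.0),
                tag: str = "sphere") -> Body:
    centre = np.asarray(centre, dtype=float)
    return Body(
        tag=tag,
        sdf=lambda p: sdf_sphere(np.atleast_2d(p), centre, radius),
        project=_project_sphere(centre, radius),
        dense_surface_points=lambda s: _fibonacci_sphere(centre, radius, s),
        size_cap=0.5 * radius,
        build_surface=lambda s: None)


def sphere_fluid_mesh(a: float = 1.0, outer_radius: float = 20.0,
                      near: float = 0.3, far: float = 4.0,
                      seed: int = 0) -> FluidMesh:
    """Fluid mesh between a sphere of radius ``a`` and the outer sphere."""
    body = sphere_body(a)
    sf = SimpleSizeField(centre=np.zeros(3), inner_radius=a,
                         near=near, far=far)
    return generate_fluid_mesh({"sphere": body}, sf, outer_radius, seed=seed)


def stokes_drag(mu: float, a: float, U: float) -> float:
    """Closed-form translating-sphere drag magnitude (unbounded fluid)."""
    return 6.0 * math.pi * mu * a * U


def stokes_spin_torque(mu: float, a: float, omega: float) -> float:
    """Closed-form rotating-sphere torque magnitude (unbounded fluid)."""
    return 8.0 * math.pi * mu * a ** 3 * omega


def container_drag_correction(a: float, R: float) -> float:
    """Leading wall correction for concentric container: drag is amplified
    by ~1/(1 - 2.10444*(a/R)) relative to the unbounded value."""
    return 1.0 / (1.0 - 2.10444 * (a / R))
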