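"""Rigid-motion velocity fields used as boundary data and in the RFT model."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class RigidMotion:
    """Base class: a solenoidal rigid velocity field v(x)."""

    def velocity(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def scaled(self, factor: float) -> "RigidMotion":
        raise NotImplementedError


@dataclass(frozen=True)
class Rest(RigidMotion):
    def velocity(self, points):
        return np.zeros_like(np.atleast_2d(points), dtype=float)

    def scaled(self, factor):
        return self


@dataclass(frozen=True)
class RotationZ(RigidMotion):
    """Rigid rotation about the z-axis at angular rate omega [rad/s]."""

    omega: float

    def velocity(self, points):
        p = np.atleast_2d(points)
        v = np.zeros_like(p, dtype=float)
        v[:, 0] = -self.omega * p[:, 1]
        v[:, 1] = self.omega * p[:, 0]
        return v

    def scaled(self, factor):
        return RotationZ(self.omega * factor)


@dataclass(frozen=True)
class TranslationZ(RigidMotion):
    """Uniform axial translation at speed u_z."""

    u_z: float

    def velocity(self, points):
        p = np.atleast_2d(points)
        v = np.zeros_like(p, dtype=float)
        v[:, 2] = self.u_z
        return v

    def scaled(self, factor):
        return TranslationZ(self.u_z * factor)


@dataclass(frozen=True)
class ScrewMotion(RigidMotion):
    """Screw motion along a helical groove of radius R and helix angle alpha.

    For a clockwise groove (h = +1):
    v = (-eps*y*sin(a)/R, eps*x*sin(a)/R, eps*cos(a)): a rotation about z at
    rate eps*sin(a)/R superposed with an axial translation eps*cos(a).  On
    the groove radius the speed equals eps and the velocity is tangent to
    the helix; for h = -1 the rotation sense is reversed so the field stays
    tangent to the mirrored helix.
    """

    eps: float
    alpha_deg: float
    R: float
    h: int = 1

    @property
    def omega(self) -> float:
        return self.h * self.eps * math.sin(math.radians(self.alpha_deg)) / self.R

    @property
    def u_z(self) -> float:
        return self.eps * math.cos(math.radians(self.alpha_deg))

    def velocity(self, points):
        p = np.atleast_2d(points)
        v = np.zeros_like(p, dtype=float)
        v[:, 0] = -self.omega * p[:, 1]
        v[:, 1] = self.omega * p[:, 0]
        v[:, 2] = self.u_z
        return v

    def scaled(self, factor):
        return ScrewMotion(self.eps * factor, self.alpha_deg, self.R, self.h)


@dataclass(frozen=True)
class Superposed(RigidMotion):
    """Sum of two rigid motions (still a rigid motion for compatible axes)."""

    first: RigidMotion
    second: RigidMotion

    def velocity(self, points):
        return self.first.velocity(points) + self.second.velocity(points)

    def scaled(self, factor):
        return Superposed(self.first.scaled(factor), self.second.scaled(factor))


def angular_rate_z(motion: RigidMotion) -> float:
    """z-angular rate of a rigid motion (for spin-torque bookkeeping)."""
    if isinstance(motion, RotationZ):
        return motion.omega
    if isinstance(motion, ScrewMotion):
        return motion.omega
    if isinstance(motion, Superposed):
        return angular_rate_z(motion.first) + angular_rate_z(motion.second)
    return 0.0
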