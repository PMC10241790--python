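"""Parameters of the flagellum-phage complex.

All lengths are in nanometres, times in seconds, viscosity in Pa*s.
Forces produced downstream are therefore in units of Pa*s*nm^2/s; the
unit system is consistent, so mobility solves and friction-coefficient
extractions (which are ratios) come out in physical units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import yaml


@dataclass(frozen=True)
class ComplexParams:
    """Geometric and kinematic parameters of the flagellum-phage complex.

    The defaults are the baseline configuration: a bacterial flagellum of
    radius 10 nm carrying a phage whose helical tail fibre (contour length
    200 nm, radius 1 nm, helix angle 51 deg) wraps around it, with a
    220 x 7 nm tail cylinder tilted 45 deg off the flagellum axis and a
    30 nm spherical capsid head.  ``model`` selects the mechanical model:

    * model 1 -- smooth flagellum, fibre centreline standing off the
      surface by ``d`` (default ``2 * r_fib``);
    * model 2 -- flagellum with a helical groove replicating the fibre
      shape; the fibre sits in the groove with bottom clearance ``h_gap``
      and a fraction ``f_cov`` of its circumference below the nominal
      cylinder surface.
    """

    R_fl: float = 10.0          # flagellum radius [nm]
    L_fl: float = 124.0         # flagellum length [nm]
    a_h: float = 30.0           # head radius [nm]
    L_t: float = 220.0          # tail length [nm]
    r_tail: float = 7.0         # tail radius [nm]
    L_fib: float = 200.0        # fibre contour length [nm]
    r_fib: float = 1.0          # fibre radius [nm]
    alpha: float = 51.0         # helix angle [deg]
    h: int = 1                  # chirality index: +1 clockwise, -1 ccw
    z_0: Optional[float] = None  # fibre start z; None -> centred on flagellum
    d: Optional[float] = None    # model-1 centreline standoff; None -> 2*r_fib
    h_gap: Optional[float] = None  # model-2 groove bottom clearance; None -> r_fib/2
    f_cov: float = 0.5          # fraction of fibre circumference in groove
    tail_tilt: float = 45.0     # tail angle to flagellum axis [deg]
    tail_gap: Optional[float] = None  # clearance tail <-> fibre/flagellum; None -> r_fib
    f: float = 100.0            # flagellum rotation frequency [Hz]
    mu: float = 1.0e-3          # dynamic viscosity [Pa*s]
    model: int = 1

    def __post_init__(self):
        for name in ("R_fl", "L_fl", "a_h", "L_t", "r_tail", "L_fib", "r_fib"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.alpha < 90.0):
            raise ValueError("alpha must lie strictly between 0 and 90 deg")
        if self.h not in (-1, 1):
            raise ValueError("chirality index h must be +1 or -1")
        if not (0.0 <= self.f_cov < 1.0):
            raise ValueError("f_cov must lie in [0, 1)")
        if self.model not in (1, 2):
            raise ValueError("model must be 1 or 2")
        if self.mu <= 0:
            raise ValueError("mu must be positive")

    # -- derived quantities ------------------------------------------------

    @property
    def d_eff(self) -> float:
        """Model-1 fibre centreline standoff from the flagellum surface."""
        return 2.0 * self.r_fib if self.d is None else self.d

    @property
    def h_gap_eff(self) -> float:
        """Model-2 clearance between fibre surface and groove bottom."""
        return 0.5 * self.r_fib if self.h_gap is None else self.h_gap

    @property
    def tail_gap_eff(self) -> float:
        return self.r_fib if self.tail_gap is None else self.tail_gap

    @property
    def alpha_rad(self) -> float:
        return math.radians(self.alpha)

    @property
    def omega_fl(self) -> float:
        """Flagellum angular speed, 2*pi*f [rad/s]."""
        return 2.0 * math.pi * self.f

    @property
    def helix_radius(self) -> float:
        """Radius of the fibre centreline helix.

        Model 1: flagellum radius plus standoff.  Model 2: the centreline
        sits so that a fraction ``f_cov`` of the fibre circumference lies
        below the nominal cylinder surface; at the default f_cov = 0.5
        this is exactly the flagellum surface radius R_fl.
        """
        if self.model == 1:
            return self.R_fl + self.d_eff
        return self.R_fl + self.r_fib * math.cos(math.pi * self.f_cov)

    @property
    def z0_eff(self) -> float:
        """Fibre start z-coordinate (flagellum spans [-L_fl/2, L_fl/2])."""
        if self.z_0 is not None:
            return self.z_0
        return -0.5 * self.L_fib * math.cos(self.alpha_rad)

    @property
    def turn_length(self) -> float:
        """Fibre contour length of one full helix turn."""
        return 2.0 * math.pi * self.helix_radius / math.sin(self.alpha_rad)

    @property
    def velocity_scale(self) -> float:
        """omega_fl * R_fl [nm/s]; 6.28 um/s at the defaults."""
        return self.omega_fl * self.R_fl

    def with_(self, **kw) -> "ComplexParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "ComplexParams":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ComplexParams":
        return cls.from_dict(yaml.safe_load(text))
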