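"""Configuration, orchestration and file output for whole-pipeline runs.

A :class:`RunConfig` (YAML round-trippable, unknown keys rejected) drives
geometry -> meshing -> per-elementary-motion Stokes solves -> loads ->
mobility, always alongside the RFT twin, and writes CSV results plus a
provenance manifest.  ``rft_only`` runs skip every FEM stage but emit the
same schema so FEM and RFT sweeps overlay directly.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, fields, asdict
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .params import ComplexParams
from .geometry import PHAGE_TAGS
from .mobility import (MobilityCoefficients, MobilitySolution,
                       compute_coefficients, solve_model1, solve_model2,
                       limiting_translocation_speed,
                       extract_fibre_friction_coefficient)
from .rft import assemble_rft_coefficients, rft_translocation_speed

SWEEPABLE = ("L_t", "r_fib", "a_h", "f_cov")
# dimensionless output conventions: velocities in units of omega_fl*R_fl;
# lengths in units of 10 nm for tail sweeps, 1 nm otherwise
LENGTH_UNIT = {"L_t": 10.0, "r_fib": 1.0, "a_h": 1.0, "f_cov": 1.0}


@dataclass
class MeshConfig:
    scale: float = 6.0
    outer_factor: float = 2.2
    smooth_iters: int = 2
    min_dihedral_deg: float = 0.2
    seed: int = 0


@dataclass
class SolverConfig:
    lam_factor: float = 1.0e7
    quad_order: int = 3
    max_residual: float = 1.0e-8


@dataclass
class SweepConfig:
    parameter: str = "L_t"
    values: List[float] = field(default_factory=list)

    def __post_init__(self):
        if self.parameter not in SWEEPABLE:
            raise ValueError(f"sweep parameter must be one of {SWEEPABLE}")


@dataclass
class RunConfig:
    params: ComplexParams = field(default_factory=ComplexParams)
    mesh: MeshConfig = field(default_factory=MeshConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    sweep: Optional[SweepConfig] = None
    rft_only: bool = False
    output_dir: Optional[str] = None
    export_fields: bool = False
    seed: int = 0

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {"params": self.params.to_dict(),
             "mesh": asdict(self.mesh),
             "solver": asdict(self.solver),
             "rft_only": self.rft_only,
             "output_dir": self.output_dir,
             "export_fields": self.export_fields,
             "seed": self.seed}
        if self.sweep is not None:
            d["sweep"] = asdict(self.sweep)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {"params", "mesh", "solver", "sweep", "rft_only",
                 "output_dir", "export_fields", "seed"}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")

        def sub(klass, block):
            if block is None:
                return klass()
            names = {f.name for f in fields(klass)}
            bad = set(block) - names
            if bad:
                raise KeyError(f"unknown {klass.__name__} keys: {sorted(bad)}")
            return klass(**block)

        return cls(
            params=ComplexParams.from_dict(data.get("params", {}) or {}),
            mesh=sub(MeshConfig, data.get("mesh")),
            solver=sub(SolverConfig, data.get("solver")),
            sweep=(sub(SweepConfig, data["sweep"])
                   if data.get("sweep") else None),
            rft_only=bool(data.get("rft_only", False)),
            output_dir=data.get("output_dir"),
            export_fields=bool(data.get("export_fields", False)),
            seed=int(data.get("seed", 0)))

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class CaseResult:
    """Everything one configuration produces."""

    params: ComplexParams
    fem_coefficients: Optional[MobilityCoefficients]
    fem_solution: Optional[MobilitySolution]
    rft_coefficients: MobilityCoefficients
    rft_solution: MobilitySolution
    details: dict = field(default_factory=dict)

    def row(self) -> dict:
        p = self.params
        scale = p.omega_fl * p.R_fl
        r = {"model": p.model, "L_t": p.L_t, "r_fib": p.r_fib,
             "a_h": p.a_h, "f_cov": p.f_cov, "L_fib": p.L_fib,
             "U_rft": self.rft_solution.U,
             "U_rft_dimless": self.rft_solution.U / scale,
             "U_limit": limiting_translocation_speed(p.omega_fl, p.R_fl,
                                                     p.alpha)}
        if self.fem_solution is not None:
            r["U_fem"] = self.fem_solution.U
            r["U_fem_dimless"] = self.fem_solution.U / scale
            if p.model == 1:
                r["omega_p_fem"] = self.fem_solution.omega_p
            else:
                r["k_delta_fem"] = self.fem_solution.k_delta
                r["V_fem"] = self.fem_solution.V
        return r


def _solve_mobility(params: ComplexParams, C: MobilityCoefficients):
    if params.model == 1:
        return solve_model1(C, params.omega_fl, R_fl=params.R_fl)
    return solve_model2(C, params.omega_fl, params)


def build_case(params: ComplexParams, mesh_cfg: MeshConfig,
               solver_cfg: SolverConfig):
    """Geometry -> mesh -> assembled/factorised Stokes case."""
    from .meshing import mesh_complex
    from .stokes import StokesCase

    mesh = mesh_complex(params, scale=mesh_cfg.scale,
                        outer_factor=mesh_cfg.outer_factor,
                        seed=mesh_cfg.seed,
                        smooth_iters=mesh_cfg.smooth_iters)
    q = mesh.quality()
    if q["min_dihedral_deg"] < mesh_cfg.min_dihedral_deg:
        raise RuntimeError(
            f"mesh quality below floor: min dihedral "
            f"{q['min_dihedral_deg']:.3f} deg (stage: meshing)")
    case = StokesCase(mesh, mu=params.mu,
                      lam=solver_cfg.lam_factor * params.mu,
                      quad_order=solver_cfg.quad_order)
    return case


def run_case(config: RunConfig,
             params: Optional[ComplexParams] = None) -> CaseResult:
    """Run one configuration end to end (FEM + RFT twin)."""
    p = params if params is not None else config.params
    rft_C = assemble_rft_coefficients(p)
    rft_sol = _solve_mobility(p, rft_C)
    fem_C = None
    fem_sol = None
    details: dict = {}
    if not config.rft_only:
        case = build_case(p, config.mesh, config.solver)
        fem_C, details = compute_coefficients(case, p)
        fem_sol = _solve_mobility(p, fem_C)
        details["lam"] = case.lam
        if p.model == 1:
            mo = {m["name"]: m for m in details["motions"]}
            details["zeta_perp_translocation"] = \
                extract_fibre_friction_coefficient(
                    p, mo["phage-translation"]["F_z_fibre"],
                    mo["phage-translation"]["M_z_fibre"], "translocation")
            details["zeta_perp_rotation"] = \
                extract_fibre_friction_coefficient(
                    p, mo["flagellum-rotation"]["F_z_fibre"],
                    mo["flagellum-rotation"]["M_z_fibre"], "rotation")
        if config.export_fields and config.output_dir:
            _export_fields(case, p, config.output_dir)
    result = CaseResult(params=p, fem_coefficients=fem_C, fem_solution=fem_sol,
                        rft_coefficients=rft_C, rft_solution=rft_sol,
                        details=details)
    if config.output_dir:
        _write_case_outputs(result, config)
    return result


def _export_fields(case, params, outdir):
    from .mobility import elementary_motion_bcs
    os.makedirs(outdir, exist_ok=True)
    for spec in elementary_motion_bcs(params):
        sol = case.solve(spec)
        div = np.full(case.mesh.n_elements, 0.0)
        case.mesh.export_vtu(
            os.path.join(outdir, f"flow_{spec.name}.vtu"),
            point_data={"velocity": sol.velocity},
            cell_data={"pressure": sol.pressure})


def _write_case_outputs(result: CaseResult, config: RunConfig):
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    pd.DataFrame([result.row()]).to_csv(
        os.path.join(outdir, "case.csv"), index=False)
    coeffs = {"rft": result.rft_coefficients.as_array().tolist()}
    if result.fem_coefficients is not None:
        coeffs["fem"] = result.fem_coefficients.as_array().tolist()
    manifest = {
        "config": config.to_dict(),
        "coefficients": coeffs,
        "details": {k: v for k, v in result.details.items()
                    if k != "motions"},
        "motions": result.details.get("motions", []),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=1, default=float)
    # solver diagnostics, one JSON record per elementary motion
    with open(os.path.join(outdir, "diagnostics.jsonl"), "w") as f:
        for m in result.details.get("motions", []):
            f.write(json.dumps(m, default=float) + "\n")


def run_sweep(config: RunConfig) -> pd.DataFrame:
    """One row per sweep value; FEM and RFT columns share the schema."""
    if config.sweep is None:
        raise ValueError("config lacks a sweep block")
    name = config.sweep.parameter
    rows = []
    for value in config.sweep.values:
        p = config.params.with_(**{name: value})
        res = run_case(RunConfig(params=p, mesh=config.mesh,
                                 solver=config.solver,
                                 rft_only=config.rft_only), params=p)
        row = res.row()
        row["sweep_parameter"] = name
        row["sweep_value"] = value
        row["sweep_value_dimless"] = value / LENGTH_UNIT[name]
        rows.append(row)
    table = pd.DataFrame(rows)
    col = "U_fem_dimless" if "U_fem_dimless" in table else "U_rft_dimless"
    diffs = np.diff(np.abs(table[col].to_numpy()))
    table.attrs["monotone_increasing"] = bool(np.all(diffs > 0))
    table.attrs["monotone_decreasing"] = bool(np.all(diffs < 0))
    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        table.to_csv(os.path.join(config.output_dir,
                                  f"sweep_{name}.csv"), index=False)
    return table
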