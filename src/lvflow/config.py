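"""Run configuration: a validated, versioned YAML schema for the pipeline.

Every block is validated against its model before any compute starts;
unknown keys are rejected with the offending field path.  SI units
throughout (times s, lengths m, velocities m/s, pressures Pa).
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import anatomy, boundary, solver as solver_mod

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Raised with a readable list of configuration violations."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryBlock(_Block):
    long_axis_length: float = Field(0.08, gt=0)
    base_radius: float = Field(0.025, gt=0)
    inlet_offset: tuple[float, float] = (-0.012, 0.0)
    outlet_offset: tuple[float, float] = (0.009, 0.0)
    inlet_radius: float = Field(0.011, ge=0)
    outlet_radius: float = Field(0.007, ge=0)
    inlet_tube_length: float = Field(0.050, gt=0)
    outlet_tube_length: float = Field(0.070, gt=0)
    inlet_tilt_deg: float = -20.0
    outlet_tilt_deg: float = 29.0
    n_phi: int = Field(64, ge=12)
    n_theta: int = Field(24, ge=4)
    edge_length: Optional[float] = Field(None, gt=0)   # mesher target

    def cavity_params(self) -> anatomy.CavityParams:
        kw = self.model_dump()
        kw.pop("edge_length")
        return anatomy.CavityParams(**kw)


class TrabeculationBlock(_Block):
    amplitude: float = Field(0.004, ge=0)
    min_cross_section: float = Field(1e-6, gt=0)
    density: float = Field(15000.0, gt=0)
    target_volume_fraction: float = Field(0.0, ge=0, lt=0.5)
    papillary_count: int = Field(2, ge=0)
    papillary_scale: float = Field(2.5, gt=0)
    bump_width: float = Field(0.0045, gt=0)
    seed: int = 0

    def params(self) -> anatomy.TrabeculationParams:
        return anatomy.TrabeculationParams(**self.model_dump())


class FluidBlock(_Block):
    density: float = Field(1060.0, gt=0)
    dynamic_viscosity: float = Field(0.0035, gt=0)
    gravity: float = Field(9.81, gt=0)

    def props(self) -> anatomy.FluidProperties:
        return anatomy.FluidProperties(**self.model_dump())


class InflowBlock(_Block):
    kind: Literal["constant", "ea"] = "constant"
    speed: float = Field(0.55, ge=0)
    ramp: float = Field(0.02, ge=0)
    ea: Optional[dict] = None

    def waveform(self):
        if self.kind == "constant":
            return boundary.ConstantInflow(self.speed, self.ramp)
        params = boundary.EAWaveParams(**(self.ea or {}))
        return lambda t: boundary.ea_wave(t, params)


class OutletBlock(_Block):
    baseline_pressure: float = Field(10700.0, ge=0)
    resistance: float = Field(6.0e6, ge=0)

    def model(self) -> boundary.OutletModel:
        return boundary.OutletModel(**self.model_dump())


class SolverBlock(_Block):
    nonlinear_form: Literal["CONV", "EMAC"] = "EMAC"
    cfl_safety: float = Field(0.5, gt=0, le=1)
    rk_stages: int = Field(3, ge=2)
    diffusive_constant: float = Field(4.0, gt=0)
    projection_tolerance: float = Field(1e-6, gt=0)
    max_time: float = Field(0.35, gt=0)
    output_interval: float = Field(0.005, gt=0)
    fixed_dt: Optional[float] = Field(None, gt=0)
    backflow_beta: float = Field(1.0, ge=0)

    def config(self) -> solver_mod.SolverConfig:
        return solver_mod.SolverConfig(**self.model_dump())


class PorousBlock(_Block):
    thickness: float = Field(0.012, ge=0)
    sigma: float = Field(20.0, gt=0)


class AnalysisBlock(_Block):
    q_threshold: float = 5000.0
    window_frames: int = Field(10, ge=1)
    probe_length: float = Field(0.015, gt=0)


class RunConfig(_Block):
    schema_version: int = SCHEMA_VERSION
    geometry: GeometryBlock = GeometryBlock()
    trabeculation: TrabeculationBlock = TrabeculationBlock()
    fluid: FluidBlock = FluidBlock()
    inflow: InflowBlock = InflowBlock()
    outlet: OutletBlock = OutletBlock()
    solver: SolverBlock = SolverBlock()
    porous: Optional[PorousBlock] = None
    analysis: AnalysisBlock = AnalysisBlock()


def _format_errors(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        path = ".".join(str(p) for p in err["loc"])
        lines.append(f"{path}: {err['msg']}")
    return "; ".join(lines)


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run configuration."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    return parse_config(raw)


def parse_config(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_errors(exc)) from exc


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
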