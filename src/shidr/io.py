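"""Run configuration (YAML/JSON) and output serialization.

A run is fully described by a ``RunConfig``: the model constants, the pulse
schedule, the initial state, the solver request, output paths and a seed.
Unknown keys are rejected and every schema violation is reported, not just
the first, so a config file either round-trips losslessly or fails loudly.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .model import ModelParameters, PulseSchedule, StateVector
from .solver import SolverConfig

__all__ = ["RunConfig", "ConfigError", "read_config", "write_json",
           "write_text", "log"]

log = logging.getLogger("shidr")


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every violation."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


class _Parameters(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pi: float = Field(ge=0)
    mu: float = Field(gt=0)
    alpha1: float = Field(ge=0)
    alpha2: float = Field(ge=0)
    rho1: float = Field(ge=0)
    rho2: float = Field(ge=0)
    gamma1: float = Field(ge=0)
    gamma2: float = Field(ge=0)
    theta: float = Field(ge=0, le=1)
    k: float = Field(ge=0, le=1)


class _Schedule(BaseModel):
    model_config = ConfigDict(extra="forbid")
    phi: float = Field(ge=0, lt=1)
    T: float = Field(gt=0)
    tau: float = Field(ge=0)


class _Initial(BaseModel):
    model_config = ConfigDict(extra="forbid")
    S: float = Field(ge=0, default=0.92)
    H: float = Field(ge=0, default=0.03)
    I: float = Field(ge=0, default=0.02)
    D: float = Field(ge=0, default=0.02)
    R: float = Field(ge=0, default=0.01)


class _Solver(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dt_target: float = Field(gt=0, default=0.01)
    t_end: float = Field(gt=0, default=200.0)


class _Output(BaseModel):
    model_config = ConfigDict(extra="forbid")
    trajectory_csv: Optional[str] = None
    report_json: Optional[str] = None


class RunConfig(BaseModel):
    """Validated, serializable description of one simulation run."""

    model_config = ConfigDict(extra="forbid")
    parameters: _Parameters
    schedule: _Schedule
    initial: _Initial = _Initial()
    solver: _Solver = _Solver()
    output: _Output = _Output()
    seed: int = 0

    # -- conversions to the science types ---------------------------------
    def model_parameters(self) -> ModelParameters:
        return ModelParameters(**self.parameters.model_dump())

    def pulse_schedule(self) -> PulseSchedule:
        return PulseSchedule(**self.schedule.model_dump())

    def initial_state(self) -> StateVector:
        d = self.initial.model_dump()
        return StateVector(d["S"], d["H"], d["I"], d["D"], d["R"])

    def solver_config(self) -> SolverConfig:
        return SolverConfig(dt_target=self.solver.dt_target,
                            t_end=self.solver.t_end)

    # -- file round-trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return self.model_dump()

    def write(self, path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2) if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        write_text(text, path)


def _format_errors(exc: ValidationError) -> list[str]:
    out = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        out.append(f"{loc}: {err['msg']} (got {err.get('input')!r})")
    return out


def read_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError([f"config root must be a mapping, got {type(raw).__name__}"])
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_errors(exc)) from None


def write_text(text: str, path) -> None:
    """Atomic text write: temp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sanitize(obj):
    # strict JSON: non-finite floats become null
    if isinstance(obj, float):
        return obj if obj == obj and abs(obj) != float("inf") else None
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    write_text(json.dumps(_sanitize(obj), indent=2) + "\n", path)
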