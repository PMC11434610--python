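"""Run configuration: schema-validated YAML/JSON with filled defaults.

The configuration mirrors the library's dataclasses; unknown keys are
rejected so typos fail loudly, and every run can serialize its fully
resolved configuration beside the results.  Units are fixed package-wide:
mV, ms, mS/cm^2, uA/cm^2, uF/cm^2.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .errors import ConfigError
from .model import ConductanceModulation, HHParams, StimulusProtocol

__all__ = ["RunConfig", "load_validate_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
    C: float = 0.75
    gNa_max: float = 120.0
    gK_max: float = 36.0
    gL: float = 0.3
    vNa: float = 50.0
    vK: float = -77.0
    vL: float = -54.4
    k_gate_exponent: int = 1
    leak_gated: bool = True
    rate_set: str = "classic"
    v_shift: float = 0.0

    def to_params(self) -> HHParams:
        return HHParams(**self.model_dump())


class ModulationSection(_Strict):
    beta_K: float = 0.0
    beta_Na: float = 0.0
    intensity: float = 0.0

    def to_modulation(self) -> ConductanceModulation:
        return ConductanceModulation(**self.model_dump())


class SegmentSection(_Strict):
    start_ms: float
    duration_ms: float
    amplitude: float


class ConventionsSection(_Strict):
    dvdt_threshold: float = 20.0
    peak_threshold: float = 0.0
    min_interval: float = 2.0
    baseline: str = "threshold"
    steady_state_discard: float = 100.0


class RunConfig(_Strict):
    """Top-level run configuration (see module docstring for units)."""

    model: ModelSection = ModelSection()
    modulation: ModulationSection = ModulationSection()
    protocol: list[SegmentSection] = []
    conventions: ConventionsSection = ConventionsSection()
    T: float = 500.0
    dt: float = 0.01
    seed: int = 0
    output_dir: str = "."

    @model_validator(mode="after")
    def _check(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T < self.dt:
            raise ValueError("T must be at least one step dt")
        # surface dataclass invariant violations (e.g. vK < vL < vNa) early
        self.model.to_params()
        self.modulation.to_modulation()
        return self

    def to_protocol(self) -> StimulusProtocol:
        return StimulusProtocol(segments=tuple(
            (s.start_ms, s.duration_ms, s.amplitude) for s in self.protocol))

    def resolved(self) -> dict:
        """Fully resolved configuration with all defaults filled."""
        return self.model_dump()


def load_validate_config(path) -> RunConfig:
    """Load a YAML or JSON configuration file and validate it.

    Defaults are filled, unknown keys rejected, and invariant violations
    reported as :class:`ConfigError` naming the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigError(f"invalid config field '{loc}': {first['msg']}") from exc
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
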