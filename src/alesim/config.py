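"""Validated configuration tree for simulator runs.

One flat, documented schema with four sections (``run``, ``culture``,
``biofilm``, ``sensor``, ``controller``); units are hours, millilitres and
h^-1 throughout.  Unknown keys are rejected with the offending key path.
A minimal file containing only a seed expands to the full default tree:
the 42-day preset with the [0.1, 0.5] OD600 operating band in a 20 ml
reactor.  The ``45d`` preset lengthens the run to 45 days (the device's
alternative protocol length); ``paper`` is an alias of ``42d``.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import culture, sensing

PRESET_DURATIONS_H = {"42d": 42 * 24.0, "45d": 45 * 24.0, "paper": 42 * 24.0}


class ConfigError(ValueError):
    """Raised for parse failures, invariant violations or unknown keys."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class MutationSettings(_Section):
    rate_per_division: float = Field(1e-9, ge=0.0, le=1.0)
    effect: Literal["point", "exponential"] = "point"
    s: float = Field(0.6, ge=0.0)


class SeededMutant(_Section):
    """A lineage injected at t=0 with a relative rate advantage."""

    cells: float = Field(1.0, gt=0)
    advantage: float = Field(0.6, ge=0.0)


class CultureSettings(_Section):
    initial_cells: float = Field(1e9, gt=0)
    growth_rate: float = Field(0.3, ge=0.0)  # h^-1, ancestor
    mutation: MutationSettings = MutationSettings()
    seeded_mutants: list[SeededMutant] = []


class BiofilmSettings(_Section):
    enabled: bool = True
    attach_rate: float = Field(2e-6, ge=0.0)  # h^-1
    detach_rate: float = Field(0.05, ge=0.0)  # h^-1
    growth_rate: float = Field(0.10, ge=0.0)  # h^-1
    per_genotype: bool = False


class FaultSettings(_Section):
    start_h: float
    end_h: float
    offset: float  # reading units

    @model_validator(mode="after")
    def _window(self):
        if not self.start_h < self.end_h:
            raise ValueError("fault window requires start_h < end_h")
        return self


class SensorSettings(_Section):
    slope: float = 1.0  # reading units per OD
    intercept: float = 0.0  # reading units
    valid_od_min: float = 0.0
    valid_od_max: float = 1.0
    noise_sd: float = Field(0.005, ge=0.0)  # OD units
    fouling_coeff: float = Field(2e-8, ge=0.0)  # reading units per cell
    cells_per_ml_per_od: float = Field(sensing.CELLS_PER_ML_PER_OD, gt=0)
    faults: list[FaultSettings] = []

    @model_validator(mode="after")
    def _invariants(self):
        if self.slope == 0:
            raise ValueError("sensor.slope must be non-zero")
        if not self.valid_od_min < self.valid_od_max:
            raise ValueError("sensor valid OD range requires min < max")
        return self


class ControllerSettings(_Section):
    t_sampling_h: float = Field(1.0 / 6.0, gt=0)  # 10 min
    od_upper_cap: float = Field(0.5, gt=0)
    od_trigger: float = Field(0.45, gt=0)
    od_post_dilution: float = Field(0.12, gt=0)
    cleaning_period_h: float = Field(24.0, gt=0)
    run_duration_h: float = Field(42 * 24.0, gt=0)
    volume_ml: float = Field(20.0, gt=0)

    @model_validator(mode="after")
    def _band(self):
        if not (0 < self.od_post_dilution < self.od_trigger
                <= self.od_upper_cap):
            raise ValueError(
                "controller invariant violated: require 0 < od_post_dilution"
                f" < od_trigger <= od_upper_cap, got {self.od_post_dilution}"
                f" < {self.od_trigger} <= {self.od_upper_cap}")
        return self


class RunSettings(_Section):
    seed: int = 0
    mode: Literal["stochastic", "deterministic"] = "stochastic"
    preset: Literal["42d", "45d", "paper"] | None = None
    #: inert metadata echoed into the manifest, not simulated
    medium: str = "M9 + 0.2% (w/v) D-xylose + 60 ug/ml streptomycin"


class SimulationConfig(_Section):
    run: RunSettings = RunSettings()
    culture: CultureSettings = CultureSettings()
    biofilm: BiofilmSettings = BiofilmSettings()
    sensor: SensorSettings = SensorSettings()
    controller: ControllerSettings = ControllerSettings()

    @model_validator(mode="before")
    @classmethod
    def _apply_preset(cls, data):
        if isinstance(data, dict):
            preset = (data.get("run") or {}).get("preset")
            if preset:
                if preset not in PRESET_DURATIONS_H:
                    raise ValueError(f"unknown preset {preset!r}")
                ctrl = dict(data.get("controller") or {})
                ctrl.setdefault("run_duration_h", PRESET_DURATIONS_H[preset])
                data = {**data, "controller": ctrl}
        return data

    # -- domain-object builders -------------------------------------------
    def sensor_model(self) -> sensing.SensorModel:
        cal = sensing.CalibrationModel(
            self.sensor.slope, self.sensor.intercept,
            (self.sensor.valid_od_min, self.sensor.valid_od_max))
        faults = tuple(sensing.FaultWindow(f.start_h, f.end_h, f.offset)
                       for f in self.sensor.faults)
        return sensing.SensorModel(cal, self.sensor.noise_sd,
                                   self.sensor.fouling_coeff, faults)

    def mutation_model(self) -> culture.MutationModel:
        m = self.culture.mutation
        return culture.MutationModel(m.rate_per_division, m.effect, m.s)

    def initial_population(self) -> culture.Population:
        stochastic = self.run.mode == "stochastic"
        counts = [self.culture.initial_cells]
        rates = [self.culture.growth_rate]
        for m in self.culture.seeded_mutants:
            counts.append(m.cells)
            rates.append(self.culture.growth_rate * (1.0 + m.advantage))
        dtype = np.int64 if stochastic else np.float64
        return culture.Population.from_arrays(np.asarray(counts, dtype),
                                              np.asarray(rates))

    def biofilm_state(self) -> culture.BiofilmState | None:
        if not self.biofilm.enabled:
            return None
        return culture.BiofilmState(self.biofilm.attach_rate,
                                    self.biofilm.detach_rate,
                                    self.biofilm.growth_rate,
                                    self.biofilm.per_genotype)


def validate_config(data: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig`, turning pydantic errors into
    :class:`ConfigError` messages that name the offending key path."""
    try:
        return SimulationConfig.model_validate(data or {})
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            path = ".".join(str(p) for p in err["loc"]) or "<root>"
            if err["type"] == "extra_forbidden":
                lines.append(f"unknown key: {path}")
            else:
                lines.append(f"invalid value at {path}: {err['msg']}")
        raise ConfigError("; ".join(lines)) from None
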