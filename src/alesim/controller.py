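"""Finite-state dilution/cleaning controller and the virtual rig.

The cultivation protocol is a recurrent cycle: incubate, measure OD at
regular intervals (``t_sampling``), and dilute with fresh medium whenever an
upper OD600 threshold is reached, which keeps the culture in exponential
phase inside the [0.1, 0.5] operating band and produces the characteristic
sawtooth trace.  A second timer swaps the culture into the auxiliary chamber
every ``cleaning_period`` hours so the fouled chamber can be washed
(NaOH/water), zeroing its wall biofilm and optical fouling.

The controller itself (:func:`controller_decide`) is a pure function of the
latest sample and the protocol timers; :func:`apply_commands` executes its
commands on the rig state and appends to the event log; and
:func:`run_experiment` drives a full, bit-reproducible run from a validated
configuration and a seed.

Dilution is modelled as instantaneous media replacement at constant volume:
a fraction ``od_post_dilution / od_measured`` of cells survives, so the
guard threshold ``od_trigger`` is deliberately below the band ceiling to
absorb one sampling interval of overshoot (at mu <= 0.6 h^-1 and 10-min
sampling the worst case is 0.45*e^{0.1} ~ 0.497 < 0.5).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import culture, sensing
from .config import SimulationConfig


class EventKind(str, enum.Enum):
    SAMPLE = "SAMPLE"
    DILUTE = "DILUTE"
    SWAP = "SWAP"
    CLEAN = "CLEAN"
    FAULT_FLAG = "FAULT_FLAG"
    END = "END"


@dataclass(frozen=True)
class Event:
    """One row of the append-only actuation log."""

    time: float  # hours
    kind: EventKind
    payload: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ControllerConfig:
    """Protocol thresholds and timers (hours, OD600 units, ml)."""

    t_sampling: float = 1.0 / 6.0
    od_upper_cap: float = 0.5
    od_trigger: float = 0.45
    od_post_dilution: float = 0.12
    cleaning_period: float = 24.0
    run_duration: float = 42 * 24.0
    volume_ml: float = 20.0

    def __post_init__(self) -> None:
        if not (0 < self.od_post_dilution < self.od_trigger
                <= self.od_upper_cap):
            raise ValueError("require 0 < od_post_dilution < od_trigger"
                             " <= od_upper_cap")
        if self.t_sampling <= 0 or self.run_duration <= 0:
            raise ValueError("t_sampling and run_duration must be > 0")


class CommandKind(str, enum.Enum):
    WAIT = "WAIT"
    DILUTE = "DILUTE"
    SWAP = "SWAP"
    CLEAN = "CLEAN"


@dataclass(frozen=True)
class Command:
    kind: CommandKind
    survival_prob: float | None = None


@dataclass(frozen=True)
class ControllerTimers:
    """Controller-internal state: the clock and the next cleaning deadline."""

    now: float
    next_clean_due: float


def controller_decide(sample: sensing.ODSample, cfg: ControllerConfig,
                      timers: ControllerTimers) -> list[Command]:
    """Pure decision function of the protocol's sampling loop.

    Returns DILUTE (survival fraction ``od_post_dilution / od``, always
    < 1 because the trigger exceeds the post-dilution target) iff the
    measured OD is at or above the trigger; SWAP+CLEAN iff the cleaning
    timer has elapsed; otherwise WAIT for the next sampling interval.
    """
    commands: list[Command] = []
    if sample.od >= cfg.od_trigger:
        commands.append(Command(CommandKind.DILUTE,
                                survival_prob=cfg.od_post_dilution / sample.od))
    # timer granularity is one sampling interval: fire at the nearest sample
    if timers.now >= timers.next_clean_due - 0.5 * cfg.t_sampling:
        commands.append(Command(CommandKind.SWAP))
        commands.append(Command(CommandKind.CLEAN))
    if not any(c.kind is CommandKind.DILUTE for c in commands):
        commands.append(Command(CommandKind.WAIT))
    return commands


@dataclass
class RigState:
    """The virtual two-chamber rig: culture, walls, sensor and clock."""

    active_chamber: str
    population: culture.Population
    biofilm: culture.BiofilmState | None
    sensor: sensing.SensorModel
    clock: float = 0.0

    @property
    def idle_chamber(self) -> str:
        return "B" if self.active_chamber == "A" else "A"

    def window_biofilm(self) -> float:
        if self.biofilm is None:
            return 0.0
        return self.biofilm.adhered(self.active_chamber)


def apply_commands(rig: RigState, commands: list[Command],
                   events: list[Event],
                   rng: np.random.Generator | None = None) -> RigState:
    """Execute controller commands on the rig, appending one event each.

    DILUTE bottlenecks the planktonic culture in place; SWAP moves the
    culture to the other chamber (wall biofilm stays behind, so the optical
    window is clean afterwards); CLEAN washes the now-idle chamber, zeroing
    its adhered biomass.  WAIT is a no-op and is not logged.
    """
    for cmd in commands:
        if cmd.kind is CommandKind.WAIT:
            continue
        if cmd.kind is CommandKind.DILUTE:
            if rig.population.total() == 0:
                raise RuntimeError("cannot dilute an empty culture")
            rig.population = culture.dilute(rig.population,
                                            cmd.survival_prob, rng)
            events.append(Event(rig.clock, EventKind.DILUTE,
                                {"survival_prob": cmd.survival_prob}))
        elif cmd.kind is CommandKind.SWAP:
            frm, to = rig.active_chamber, rig.idle_chamber
            rig.active_chamber = to
            events.append(Event(rig.clock, EventKind.SWAP,
                                {"from": frm, "to": to}))
        elif cmd.kind is CommandKind.CLEAN:
            target = rig.idle_chamber
            if rig.biofilm is not None:
                rig.biofilm.clean(target)
            events.append(Event(rig.clock, EventKind.CLEAN,
                                {"chamber": target}))
    return rig


@dataclass
class RunResult:
    """Everything a completed run produced, reproducible from (config, seed)."""

    trace: pd.DataFrame  # time_h, od_measured, od_true, raw_reading, flags
    events: list[Event]
    final_state: RigState
    seed: int
    config: dict
    frequencies: pd.DataFrame | None = None  # per-genotype counts per sample

    def dilution_times(self) -> np.ndarray:
        return np.array([e.time for e in self.events
                         if e.kind is EventKind.DILUTE])


def _controller_config(cfg: SimulationConfig) -> ControllerConfig:
    c = cfg.controller
    return ControllerConfig(c.t_sampling_h, c.od_upper_cap, c.od_trigger,
                            c.od_post_dilution, c.cleaning_period_h,
                            c.run_duration_h, c.volume_ml)


def run_experiment(cfg: SimulationConfig, seed: int | None = None, *,
                   record_frequencies: bool = False) -> RunResult:
    """Run the full protocol and return its trace, event log and final state.

    Time advances in steps of ``t_sampling``; within each step the culture is
    sub-stepped to honour the stochastic integrator's cap, then the sensor is
    read and the controller's commands are applied.  All randomness flows
    from one run-level seed via per-module sub-streams, so identical
    (config, seed) give bit-identical results.
    """
    seed = cfg.run.seed if seed is None else int(seed)
    ctrl = _controller_config(cfg)
    ss = np.random.SeedSequence(seed)
    culture_stream, sensor_stream = (np.random.default_rng(s)
                                     for s in ss.spawn(2))
    stochastic = cfg.run.mode == "stochastic"
    rng_culture = culture_stream if stochastic else None
    mutation = cfg.mutation_model()

    rig = RigState("A", cfg.initial_population(), cfg.biofilm_state(),
                   cfg.sensor_model())
    events: list[Event] = []
    rows: list[tuple] = []
    freq_snapshots: list[dict[int, float]] = []
    freq_times: list[float] = []
    cells_per_ml_per_od = cfg.sensor.cells_per_ml_per_od

    def sample_and_act(timers_due: float) -> float:
        od_true = sensing.biomass_to_od(rig.population.total(),
                                        ctrl.volume_ml, cells_per_ml_per_od)
        sample = sensing.measure(od_true, rig.sensor, rig.window_biofilm(),
                                 rig.clock, sensor_stream)
        events.append(Event(rig.clock, EventKind.SAMPLE,
                            {"od": sample.od, "od_true": od_true,
                             "flags": sorted(sample.flags)}))
        if "fault_suspected" in sample.flags:
            events.append(Event(rig.clock, EventKind.FAULT_FLAG,
                                {"offset": rig.sensor.fault_offset(rig.clock)}))
        rows.append((rig.clock, sample.od, od_true, sample.raw_reading,
                     "|".join(sorted(sample.flags))))
        if record_frequencies:
            freq_times.append(rig.clock)
            freq_snapshots.append({int(g): float(c) for g, c in
                                   zip(rig.population.ids,
                                       rig.population.counts)})
        commands = controller_decide(sample, ctrl,
                                     ControllerTimers(rig.clock, timers_due))
        swapped = any(c.kind is CommandKind.SWAP for c in commands)
        apply_commands(rig, commands, events, rng_culture)
        return timers_due + ctrl.cleaning_period if swapped else timers_due

    n_steps = round(ctrl.run_duration / ctrl.t_sampling)
    next_clean_due = ctrl.cleaning_period
    next_clean_due = sample_and_act(next_clean_due)  # t = 0 baseline sample
    for step in range(1, n_steps + 1):
        rig.population, rig.biofilm = culture.advance_culture(
            rig.population, ctrl.t_sampling, biofilm=rig.biofilm,
            chamber=rig.active_chamber, mutation=mutation, rng=rng_culture,
            mutation_rng=culture_stream, time0=rig.clock)
        rig.clock = step * ctrl.t_sampling  # grid clock: no float drift
        next_clean_due = sample_and_act(next_clean_due)
    events.append(Event(rig.clock, EventKind.END,
                        {"n_samples": len(rows)}))

    trace = pd.DataFrame(rows, columns=["time_h", "od_measured", "od_true",
                                        "raw_reading", "flags"])
    freqs = None
    if record_frequencies:
        freqs = pd.DataFrame(freq_snapshots).fillna(0.0)
        freqs.columns = [str(c) for c in freqs.columns]
        freqs.insert(0, "time_h", freq_times)
    return RunResult(trace, events, rig, seed, cfg.model_dump(),
                     frequencies=freqs)
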