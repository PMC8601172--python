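"""Virtual OD600 sensor: biomass conversion, calibration, noise and faults.

The physical device reads culture turbidity through an optical chamber and
maps the light reading to OD600 with a linear calibration.  This module
reproduces that measurement chain:

    raw = a*od_true + b + fouling_coeff*B_window + fault_offset + N(0, a*sd)
    od  = (raw - b)/a

Noise is applied in reading space with SD ``a*noise_sd`` so that the
OD-space SD equals ``noise_sd`` regardless of the calibration.  ``B_window``
is the adhered biomass on the active chamber's optical window: biofilm
fouling biases the reading upward until the chamber is cleaned.  Hard sensor
faults (the mid-run drift artefact where arbitrarily larger values are
detected until the optics are realigned) are deterministic scheduled
reading offsets, so runs remain reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Bacteriological rule of thumb: cells per ml per OD600 unit.  At this
#: value a 20 ml reactor inside the [0.1, 0.5] operating band holds
#: 1e9-5e9 cells.
CELLS_PER_ML_PER_OD = 5e8


@dataclass(frozen=True)
class CalibrationModel:
    """Linear light-reading calibration ``reading = slope*od + intercept``."""

    slope: float = 1.0
    intercept: float = 0.0
    valid_od_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero")
        lo, hi = self.valid_od_range
        if not lo < hi:
            raise ValueError("valid_od_range must satisfy low < high")

    def reading_from_od(self, od: float) -> float:
        return self.slope * od + self.intercept

    def od_from_reading(self, reading: float) -> float:
        return (reading - self.intercept) / self.slope


@dataclass(frozen=True)
class FaultWindow:
    """Scheduled hard fault: a constant reading offset while active."""

    start_h: float
    end_h: float
    offset: float  # reading units

    def __post_init__(self) -> None:
        if not self.start_h < self.end_h:
            raise ValueError("fault window requires start_h < end_h")

    def active(self, time: float) -> bool:
        return self.start_h <= time < self.end_h


@dataclass(frozen=True)
class SensorModel:
    calibration: CalibrationModel = CalibrationModel()
    noise_sd: float = 0.005  # OD units
    fouling_coeff: float = 0.0  # reading units per adhered cell
    faults: tuple[FaultWindow, ...] = ()

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.fouling_coeff < 0:
            raise ValueError("fouling_coeff must be >= 0")

    def fault_offset(self, time: float) -> float:
        return sum(f.offset for f in self.faults if f.active(time))


@dataclass(frozen=True)
class ODSample:
    """One timestamped measurement with its raw reading and quality flags."""

    time: float  # hours
    od: float  # OD600-equivalent
    raw_reading: float
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not np.isfinite(self.od):
            raise ValueError("od must be finite")


def biomass_to_od(total_cells: float, volume_ml: float,
                  cells_per_ml_per_od: float = CELLS_PER_ML_PER_OD) -> float:
    """True OD600 of ``total_cells`` suspended in ``volume_ml``."""
    if volume_ml <= 0:
        raise ValueError(f"volume must be > 0 ml, got {volume_ml}")
    if cells_per_ml_per_od <= 0:
        raise ValueError("cells_per_ml_per_od must be > 0")
    return total_cells / (volume_ml * cells_per_ml_per_od)


def measure(true_od: float, sensor: SensorModel,
            biofilm_on_window: float = 0.0, time: float = 0.0,
            rng: np.random.Generator | None = None) -> ODSample:
    """Simulate one OD measurement through the calibrated optical chain.

    Out-of-calibration ODs are flagged (``in_band`` absent), never raised;
    an active scheduled fault sets ``fault_suspected``.
    """
    cal = sensor.calibration
    raw = cal.reading_from_od(true_od)
    raw += sensor.fouling_coeff * biofilm_on_window
    fault = sensor.fault_offset(time)
    raw += fault
    if rng is not None and sensor.noise_sd > 0:
        raw += rng.normal(0.0, abs(cal.slope) * sensor.noise_sd)
    od = cal.od_from_reading(raw)
    flags = set()
    lo, hi = cal.valid_od_range
    if lo <= true_od <= hi:
        flags.add("in_band")
    if fault != 0.0:
        flags.add("fault_suspected")
    return ODSample(time, od, raw, frozenset(flags))


def fit_calibration(pairs) -> CalibrationModel:
    """Ordinary least squares of reading on reference OD.

    ``pairs`` is an iterable of (raw_reading, reference_od); at least two
    distinct reference ODs are required.  The fitted valid range is the span
    of the reference ODs.
    """
    arr = np.asarray(list(pairs), dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (reading, reference_od) tuples")
    readings, ods = arr[:, 0], arr[:, 1]
    if np.unique(ods).size < 2:
        raise ValueError(
            "calibration needs >= 2 pairs with distinct reference ODs")
    fit = stats.linregress(ods, readings)
    return CalibrationModel(float(fit.slope), float(fit.intercept),
                            (float(ods.min()), float(ods.max())))


def read_calibration_pairs(path) -> list[tuple[float, float]]:
    """Read (reading, od) pairs from a two-column headed CSV."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header] != ["reading", "od"]:
            raise ValueError(
                f"expected header 'reading,od' in {path}, got {header}")
        return [(float(r), float(o)) for r, o in reader]
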