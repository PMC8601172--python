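"""Fit the light-reading-to-OD600 calibration line.

The optical reader reports raw light readings; a dilution series of known
ODs calibrates the linear map reading = a*od + b.  Here we synthesise a
noisy dilution series with a known line and recover it by ordinary least
squares.
"""

import numpy as np

from alesim import fit_calibration, measure
from alesim.sensing import CalibrationModel, SensorModel

rng = np.random.default_rng(1)
true = CalibrationModel(slope=2.4, intercept=0.15, valid_od_range=(0.0, 0.6))
sensor = SensorModel(calibration=true, noise_sd=0.005)

reference_ods = np.linspace(0.05, 0.55, 12)
pairs = [(measure(od, sensor, rng=rng).raw_reading, od)
         for od in reference_ods]

fitted = fit_calibration(pairs)
print(f"true line:   reading = {true.slope:.3f}*od + {true.intercept:.3f}")
print(f"fitted line: reading = {fitted.slope:.3f}*od + "
      f"{fitted.intercept:.3f}")
print(f"valid OD range: [{fitted.valid_od_range[0]:.2f}, "
      f"{fitted.valid_od_range[1]:.2f}]")

# The fitted slope/intercept should match the true line within the noise
# of the 12-point dilution series; the valid range records the span of
# reference ODs the calibration can be trusted over.
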