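"""Watch a beneficial mutant sweep through the reactor.

A mutant with a 60% growth-rate advantage (s = 0.6) is seeded into the
ancestor culture; the protocol's repeated regrowth selects for it.  The
daily growth-rate series — mean +/- SD of per-cycle OLS slopes of
ln(OD) on time — rises from the ancestor's rate to the mutant's, and the
log-odds slope of the mutant frequency estimates delta-mu directly.
"""

import alesim

cfg = alesim.validate_config({
    "run": {"mode": "deterministic"},
    "culture": {"mutation": {"rate_per_division": 0.0},
                "seeded_mutants": [{"cells": 10_000, "advantage": 0.6}]},
    "controller": {"run_duration_h": 10 * 24.0},
})
result = alesim.run_experiment(cfg, seed=4, record_frequencies=True)

trace = alesim.ODTrace.from_dataframe(result.trace)
series = alesim.growth_rate_series(trace, result.events)
print("daily growth-rate series (h^-1):")
for row in series.itertuples():
    print(f"  day {int(row.t_mid_h // 24):2d}: mu = {row.mu_mean:.3f} "
          f"+/- {row.mu_sd:.3f}  ({row.n_cycles} cycles)")

freqs = result.frequencies
f = freqs["1"] / (freqs["0"] + freqs["1"])
inside = (f > 0) & (f < 1)
dmu = alesim.logodds_selection_slope(freqs["time_h"][inside], f[inside])
print(f"\nlog-odds selection slope: {dmu:.4f} h^-1 "
      f"(expected mu_anc*s = 0.3*0.6 = 0.18)")

# The series plateaus near 0.30 h^-1 before the sweep and near
# 0.48 h^-1 = 0.3*(1+0.6) after it; the log-odds slope recovers the
# growth-rate difference the protocol selected for.
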