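# Methods

## Scope and model structure

`alesim` is a digital twin of a dual-chamber semi-continuous ("log-phase")
bioreactor used for adaptive laboratory evolution of *Pseudomonas putida*:
a stochastic evolving-culture model, a virtual OD600 sensor, the
threshold-triggered dilution/cleaning control loop, and the downstream
trace analysis. It deliberately models the *protocol*, not the hardware:
pumps, valves, electronics and liquid handling are abstracted into
instantaneous, ideal actuations, and contamination, aeration, substrate
depletion and spatial structure are out of scope.

## Culture dynamics

Each genotype grows exponentially at a fixed intrinsic rate μ (h⁻¹). A
substrate (Monod) term is intentionally absent: the controller holds the
culture inside the [0.1, 0.5] OD600 band, i.e. permanently in early
exponential phase, where a constant μ is the appropriate reduction. The
cost is that the model cannot represent lag phases, stationary-phase
physiology or density-dependent rate changes; runs that leave the band
(e.g. controller disabled) are outside its validity.

Two integration modes share one interface:

* **deterministic** — float counts multiplied by e^{μ·dt}; exact for any
  step size, used for closed-form cross-checks and fast what-if runs;
* **stochastic** — integer counts advanced by a Poisson tau-leap of the
  pure-birth (Yule) process: the per-step increment is Poisson with mean
  N(e^{μ·dt}−1), the exact Yule expectation, so the leap is unbiased for
  any step. Steps are capped at μ·dt ≤ 0.05 (≈2.5% step-to-step growth),
  where the Poisson's variance deficit relative to the exact negative
  binomial is negligible; the integrator sub-steps automatically, and
  re-checks the cap whenever a faster mutant appears mid-interval. Exact
  Yule/binomial sampling is reserved for test oracles — at 10⁹ cells it
  would be hopeless, the tau-leap costs one Poisson draw per genotype per
  step.

**Mutation.** Beneficial mutations arrive at u per cell division
(divisions ≙ births in a pure-birth model), each founding a new genotype
with rate μ_parent·(1+s); s is a point mass or exponential draw. Defaults
u = 10⁻⁹ per division and point-mass s = 0.6 are placeholders chosen to
put one successful sweep inside a 42-day run at the reactor's population
size and to mirror the observed end-to-end phenotype scale (a ~60% faster
evolved strain); neither value is empirically constrained, and both are
plain config keys. Deleterious and neutral mutations are not modelled —
they would only dilute the bookkeeping, not the selection dynamics the
device exploits.

**Dilution.** Bottlenecks are binomial: each cell survives with
p = od_post/od_measured independently. This is the mechanism that can
lose rare beneficial lineages, so it is sampled exactly rather than
approximated. Extinct lineages are pruned from the live arrays (threshold:
exactly 0 cells) but archived for the lineage table.

**Biofilm.** Wall-adhered biomass B per chamber follows
dB/dt = k_a·N + (μ_f − k_s)·B (explicit Euler on the integrator's
sub-steps; exact for the pure-attachment case). Defaults — k_a = 2×10⁻⁶
h⁻¹, k_s = 0.05 h⁻¹, μ_f = 0.10 h⁻¹ — were chosen once so that, with
daily cleaning, the film reaches ~2×10⁵ cells and the optical fouling
(below) drifts the reading by ~5×10⁻³ OD per day: a visible nuisance at
the device's scale that motivates the cleaning cycle without dominating
the dynamics. In the default aggregate mode each chamber's film is one
pool and shed cells rejoin the planktonic phase proportionally to its
current composition — a genotype-symmetric rule that cannot bias
selection estimates; `biofilm.per_genotype = true` tracks film
composition per lineage instead (with the caveat that stochastic
shedding is then conserved only in expectation). Cell number is conserved
exactly by the exchange when μ = μ_f = 0.

## Sensor

The measurement chain is
`raw = a·OD_true + b + fouling_coeff·B_window + fault + N(0, a·σ)`,
inverted through the calibration to the reported OD. Noise is injected in
reading space with SD a·σ so the OD-space SD is σ regardless of the
calibration; default σ = 0.005 OD. The calibration default is the
identity (a = 1, b = 0) because no numeric slope/intercept is available
for the physical reader; `fit_calibration` recovers a line from a
(reading, OD) dilution series by OLS and records its valid range.
Readings outside that range are flagged, not corrected — OD saturation
above the calibrated range is a known, unmodelled nonlinearity.

Hard faults (the mid-run artefact in which the detector reported
arbitrarily larger values until the optics were realigned) are
deterministic scheduled reading offsets, so faulty runs remain exactly
reproducible; affected samples carry a `fault_suspected` flag that
propagates through cycle fits into the growth-rate series.

Biomass→OD conversion uses 5×10⁸ cells·ml⁻¹ per OD unit (standard
bacteriological rule of thumb), so the 20 ml reactor holds 10⁹–5×10⁹
cells across the operating band.

## Controller

A pure decision function runs at every sampling instant: DILUTE (to
od_post = 0.12) iff the measured OD ≥ od_trigger = 0.45 (inclusive);
SWAP + CLEAN iff the cleaning timer (default 24 h, granularity one
sampling interval) has elapsed; otherwise WAIT. Defaults: t_sampling =
10 min, band [0.1, 0.5], 20 ml, 42-day duration (a 45-day preset ships as
`run.preset = "45d"`; neither length is canonical). Dilution is
instantaneous media replacement at constant volume.

Numerical/tie-break choices: the trigger comparison is inclusive (≥); the
clock is computed from the step index (no floating-point accumulation);
the cleaning timer fires at the nearest sample to its deadline; DILUTE
and SWAP/CLEAN can co-occur in one step, executed in that order; events
share the triggering sample's timestamp and are logged in causal order.

**Band guarantees.** od_trigger sits below the ceiling so one sampling
interval of growth cannot overshoot: worst case 0.45·e^{μ·Δt}, ≈0.497 at
μ = 0.6 h⁻¹ and Δt = 10 min. od_post = 0.12 (not 0.10) keeps measurement
noise from reporting sub-band ODs after dilution. One caveat is inherent
to triggering on a noisy reading: a ~2σ-low reading at a true OD just
above the danger point delays dilution by one sample, with analytic
probability ≈5×10⁻⁴ per cycle at μ = 0.48 h⁻¹ — over a full 42-day run
there is a ~10% chance of a single-sample excursion of ≲1% above the
ceiling. The ceiling guarantee is therefore statistical, not absolute;
tightening it would require faster sampling or reading filtration, both
outside the protocol being twinned.

## Trace analysis

* **Segmentation** uses DILUTE events when available; otherwise a new
  cycle starts at any relative OD drop > δ = 0.2 between consecutive
  samples (the protocol's smallest dilution is ≈73%, so the two modes
  agree on simulator output). Cycles partition the trace.
* **Per-cycle rate**: OLS slope of ln(OD) on time, ≥3 positive-OD points.
  Additive OD noise makes ln(OD) noise mildly heteroscedastic; at
  σ = 0.005 the induced slope bias is below the estimator's Monte-Carlo
  resolution (verified at 10³ cycles).
* **Growth-rate series**: cycles grouped by start time into 24 h windows
  (daily values), reported as mean ± SD (SD 0 for singleton windows);
  windows inherit any cycle's fault flag. The final window typically
  contains the run-truncated cycle and is noisier — plateau comparisons
  should use complete days.
* **Strain comparison**: one regression of ln(OD) on time over both
  datasets with a per-replicate intercept and per-dataset slope. The
  headline test is the interaction (slope-difference) t-test — the
  biological claim is a *between*-strain difference — with each slope's
  own t-statistic reported alongside; percent increment is
  100·(μ_b/μ_a − 1). The caller supplies the exponential-phase time
  window; there is no automatic lag/stationary trimming (documented
  limitation).
* **Selection slope**: OLS slope of ln(f/(1−f)) on time equals
  μ_mut − μ_anc exactly in the two-genotype exponential model, because
  symmetric bottlenecks and symmetric wall exchange leave frequencies
  unbiased. Frequencies at 0 or 1 are rejected with advice to clip or
  truncate.
* **Protocol timing**: `growth_times_to_threshold` measures, per cycle,
  the time from the dilution instant (where OD is exactly od_post) to the
  log-interpolated trigger crossing; exact to machine precision on
  noiseless exponential data, and the right quantity to compare with
  ln(od_trigger/od_post)/μ (raw event spacing is quantised to
  t_sampling).

## Synthetic data: what it does and does not emulate

The simulator *is* the data generator. Its stochastic mode reproduces the
features the analysis must cope with: demographic birth noise, binomial
bottleneck loss of rare lineages, measurement noise, slow fouling drift
with daily resets, and scheduled hard-fault spikes. Flask growth curves
for strain comparison are synthesised separately with multiplicative
log-normal noise (CV 2%) and log-normally varied inocula — the standard
error model for flask/plate OD readings, and one under which the pooled
log-linear model is exactly specified (the type-I-error check holds its
nominal 5% there). Real traces additionally contain lag after dilution,
slow medium/temperature drifts, non-stationary mutation supply and
contamination risk, none of which are modelled; passing tests therefore
validate the estimators and the controller logic, not the biology of any
particular strain.

## Problem sizes and reproducibility

Default test and reference problem sizes — a 42-day run at 10-min sampling
(~6×10³ samples, sub-stepped), 10⁴–10⁶-replicate oracle comparisons, 10³
replicate estimator calibrations — were chosen so the whole suite runs in
well under a minute of simulation time while leaving Monte-Carlo standard
errors small enough for 3-SE assertions. All randomness flows from a
single run-level seed through per-module `SeedSequence` sub-streams;
identical (config, seed) reproduce every data output byte-for-byte. The
run manifest holds the config echo, seed, package version, wall times and
SHA-256 checksums of every output file (the manifest itself, containing
wall times, is the one file that differs between identical runs).
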