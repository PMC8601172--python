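"""Sawtooth-trace and growth-curve analysis.

Downstream of the simulator (or of a real device's log files) this module
segments the sawtooth OD trace into growth cycles, fits a per-cycle growth
rate by ordinary least squares of ln(OD) on time, aggregates the estimates
into a daily growth-rate time series (mean +/- SD per window), compares two
strains' flask growth curves with a slope-difference t-test and percent
increment, and estimates a selection coefficient from the log-odds slope of
mutant frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .controller import Event, EventKind

#: Default relative OD drop between consecutive samples that marks a
#: dilution when no event log is available.
DEFAULT_REL_DROP = 0.2


@dataclass(frozen=True)
class ODTrace:
    """An ordered OD time series with optional per-sample quality flags."""

    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray
    flags: tuple[frozenset[str], ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, np.float64))
        object.__setattr__(self, "od", np.asarray(self.od, np.float64))
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            bad = int(np.flatnonzero(np.diff(self.times) <= 0)[0]) + 1
            raise ValueError(f"times must be strictly increasing "
                             f"(first violation at sample {bad})")
        if self.flags is not None and len(self.flags) != self.times.size:
            raise ValueError("flags must align with samples")

    def __len__(self) -> int:
        return int(self.times.size)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       od_column: str = "od_measured") -> "ODTrace":
        """Build from a simulator trace table (``time_h`` + an OD column)."""
        flags = None
        if "flags" in df.columns:
            flags = tuple(frozenset(s.split("|")) if s else frozenset()
                          for s in df["flags"].fillna(""))
        return cls(df["time_h"].to_numpy(), df[od_column].to_numpy(), flags)


@dataclass(frozen=True)
class CycleEstimate:
    """Per-cycle exponential growth-rate fit (slope of ln OD on time)."""

    cycle_index: int  # 1-based
    t_start: float
    t_end: float
    n_points: int
    mu_hat: float  # h^-1
    mu_se: float  # h^-1
    r_squared: float
    fault_suspected: bool = False


@dataclass(frozen=True)
class SlopeComparison:
    """Two-dataset pooled log-linear slope comparison.

    ``percent_increase`` is 100*(mu_b/mu_a - 1); the headline t-test is on
    the slope difference (interaction term of a shared regression with a
    dataset indicator and per-replicate intercepts); each dataset's own
    slope t-statistic is reported alongside.
    """

    mu_a: float
    mu_b: float
    mu_a_se: float
    mu_b_se: float
    percent_increase: float
    t_statistic: float
    p_value: float
    alpha: float
    t_a: float
    t_b: float


def _dilution_times(events) -> np.ndarray:
    return np.sort(np.array([e.time for e in events
                             if e.kind is EventKind.DILUTE], np.float64))


def segment_cycles(trace: ODTrace, events=None,
                   rel_drop: float = DEFAULT_REL_DROP) -> list[slice]:
    """Partition the trace into growth cycles.

    With an event log, cycle boundaries sit at DILUTE times (the triggering
    sample closes its cycle; the next sample opens the new one).  Without
    events, a new cycle starts wherever OD falls by more than ``rel_drop``
    relative between consecutive samples.  The returned slices are disjoint
    and cover the whole trace; an empty trace yields an empty list.
    """
    n = len(trace)
    if n == 0:
        return []
    if events is not None:
        boundaries = np.searchsorted(trace.times, _dilution_times(events),
                                     side="right")
    else:
        drops = trace.od[1:] < (1.0 - rel_drop) * trace.od[:-1]
        boundaries = np.flatnonzero(drops) + 1
    cuts = [0] + [int(b) for b in boundaries if 0 < b < n] + [n]
    cuts = sorted(set(cuts))
    return [slice(a, b) for a, b in zip(cuts[:-1], cuts[1:])]


def fit_cycle_growth_rate(trace: ODTrace, cycle: slice,
                          cycle_index: int = 1) -> CycleEstimate:
    """OLS of ln(OD) on time over one cycle's samples."""
    t = trace.times[cycle]
    od = trace.od[cycle]
    if t.size < 3:
        raise ValueError(f"cycle {cycle_index}: need >= 3 points to fit a "
                         f"growth rate, got {t.size}")
    if np.any(od <= 0):
        raise ValueError(f"cycle {cycle_index}: non-positive OD values "
                         "cannot be log-transformed")
    fit = stats.linregress(t, np.log(od))
    flagged = False
    if trace.flags is not None:
        flagged = any("fault_suspected" in f for f in trace.flags[cycle])
    return CycleEstimate(cycle_index, float(t[0]), float(t[-1]), int(t.size),
                         float(fit.slope), float(fit.stderr),
                         float(fit.rvalue ** 2), flagged)


def estimate_cycles(trace: ODTrace, events=None,
                    rel_drop: float = DEFAULT_REL_DROP,
                    min_points: int = 3) -> list[CycleEstimate]:
    """Segment and fit every cycle with at least ``min_points`` samples."""
    out = []
    for i, sl in enumerate(segment_cycles(trace, events, rel_drop), start=1):
        if sl.stop - sl.start >= min_points:
            out.append(fit_cycle_growth_rate(trace, sl, i))
    return out


def cycles_table(estimates: list[CycleEstimate]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in estimates])


def growth_rate_series(trace: ODTrace, events=None, window: float = 24.0,
                       rel_drop: float = DEFAULT_REL_DROP) -> pd.DataFrame:
    """Windowed mean +/- SD of per-cycle growth rates (daily by default).

    Cycles are assigned to the window containing their start time; windows
    without a complete cycle are omitted.  A window inherits the
    ``fault_suspected`` flag of any of its cycles, so sensor-drift artefacts
    (sharp spurious peaks in the series) remain identifiable downstream.
    """
    estimates = estimate_cycles(trace, events, rel_drop)
    if not estimates:
        return pd.DataFrame(columns=["t_mid_h", "mu_mean", "mu_sd",
                                     "n_cycles", "fault_suspected"])
    df = cycles_table(estimates)
    df["window"] = np.floor(df["t_start"] / window).astype(int)
    rows = []
    for w, grp in df.groupby("window"):
        mu = grp["mu_hat"].to_numpy()
        rows.append(((w + 0.5) * window, float(mu.mean()),
                     float(mu.std(ddof=1)) if mu.size > 1 else 0.0,
                     int(mu.size), bool(grp["fault_suspected"].any())))
    return pd.DataFrame(rows, columns=["t_mid_h", "mu_mean", "mu_sd",
                                       "n_cycles", "fault_suspected"])


# ---------------------------------------------------------------------------
# strain comparison

def _check_flask_dataset(df: pd.DataFrame, name: str) -> pd.DataFrame:
    for col in ("replicate", "time_h", "od"):
        if col not in df.columns:
            raise ValueError(f"dataset {name}: missing column {col!r}")
    if df["replicate"].nunique() < 2:
        raise ValueError(f"dataset {name}: need >= 2 replicate curves")
    for rep, grp in df.groupby("replicate"):
        if len(grp) < 3:
            raise ValueError(f"dataset {name}, replicate {rep}: need >= 3 "
                             "points in exponential phase")
        if (grp["od"] <= 0).any():
            raise ValueError(f"dataset {name}, replicate {rep}: "
                             "non-positive OD")
    return df


def compare_growth(dataset_a: pd.DataFrame, dataset_b: pd.DataFrame,
                   alpha: float = 0.05,
                   time_window: tuple[float, float] | None = None,
                   ) -> SlopeComparison:
    """Compare pooled log-linear growth-rate slopes of two strains.

    Each dataset is long-format replicate growth curves
    (``replicate,time_h,od``), restricted to exponential phase (optionally
    via ``time_window``).  A single regression of ln(OD) on time is fitted
    with a per-replicate intercept and a per-dataset slope; the headline
    significance test is the t-test on the slope difference.
    """
    if time_window is not None:
        lo, hi = time_window
        dataset_a = dataset_a[dataset_a["time_h"].between(lo, hi)]
        dataset_b = dataset_b[dataset_b["time_h"].between(lo, hi)]
    a = _check_flask_dataset(dataset_a, "a").assign(_ds=0)
    b = _check_flask_dataset(dataset_b, "b").assign(_ds=1)
    both = pd.concat([a, b], ignore_index=True)
    y = np.log(both["od"].to_numpy())
    groups = both["_ds"].astype(str) + ":" + both["replicate"].astype(str)
    intercepts = pd.get_dummies(groups, dtype=float).to_numpy()
    t = both["time_h"].to_numpy()
    X = np.column_stack([intercepts, t, t * both["_ds"].to_numpy()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate design: time points are collinear with "
                         "the dataset indicator; cannot separate slopes")
    model = sm.OLS(y, X).fit()
    k = intercepts.shape[1]
    mu_a = float(model.params[k])
    diff = float(model.params[k + 1])
    mu_b = mu_a + diff
    cov = model.cov_params()
    se_a = float(np.sqrt(cov[k, k]))
    se_b = float(np.sqrt(cov[k, k] + cov[k + 1, k + 1] + 2 * cov[k, k + 1]))
    se_diff = float(np.sqrt(cov[k + 1, k + 1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = diff / se_diff if se_diff > 0 else math.inf * np.sign(diff)
        if diff == 0 and se_diff == 0:
            t_stat = 0.0
    p = (2 * stats.t.sf(abs(t_stat), df=model.df_resid)
         if np.isfinite(t_stat) else 0.0)
    if t_stat == 0.0 and se_diff == 0:
        p = 1.0
    if mu_a <= 0:
        raise ValueError("percent increase undefined: pooled slope of "
                         f"dataset a is not positive (mu_a={mu_a:.4g})")
    return SlopeComparison(mu_a, mu_b, se_a, se_b,
                           100.0 * (mu_b / mu_a - 1.0), float(t_stat),
                           float(p), alpha,
                           mu_a / se_a if se_a > 0 else math.inf,
                           mu_b / se_b if se_b > 0 else math.inf)


def logodds_selection_slope(times, freqs) -> float:
    """Selection estimate: OLS slope of ln(f/(1-f)) on time (h^-1).

    Under the two-genotype exponential model the log-odds of the mutant
    frequency is linear in time with slope mu_mut - mu_anc, so the fitted
    slope estimates the growth-rate difference directly.
    """
    times = np.asarray(times, np.float64)
    freqs = np.asarray(freqs, np.float64)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("frequencies must lie strictly in (0, 1); clip or "
                         "truncate the series before/after fixation")
    fit = stats.linregress(times, np.log(freqs / (1.0 - freqs)))
    return float(fit.slope)


# ---------------------------------------------------------------------------
# protocol timing

def growth_times_to_threshold(trace: ODTrace, events,
                              threshold: float) -> np.ndarray:
    """Per-cycle time from the dilution instant to the threshold crossing.

    The crossing is located by log-linear interpolation between the
    bracketing samples, which is exact for exponential growth; the first
    (pre-dilution) cycle is excluded since it does not start at the
    post-dilution OD.  Useful for checking the protocol's inter-dilution
    timing against ``ln(od_trigger/od_post)/mu``.
    """
    dil = _dilution_times(events)
    out = []
    for start in dil:
        i0 = int(np.searchsorted(trace.times, start, side="right"))
        seg_t, seg_od = trace.times[i0:], trace.od[i0:]
        above = np.flatnonzero(seg_od >= threshold)
        if not above.size or above[0] == 0:
            continue
        j = int(above[0])
        t0, t1 = seg_t[j - 1], seg_t[j]
        lo, hi = math.log(seg_od[j - 1]), math.log(seg_od[j])
        t_cross = t0 + (math.log(threshold) - lo) / (hi - lo) * (t1 - t0)
        out.append(t_cross - start)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# synthetic flask curves

def simulate_flask_curves(mu: float, times, n_replicates: int = 3,
                          od0: float = 0.05, noise_cv: float = 0.02,
                          rng: np.random.Generator | None = None,
                          ) -> pd.DataFrame:
    """Synthetic replicate flask growth curves in long format.

    OD follows ``od0*exp(mu*t)`` per replicate with multiplicative
    log-normal measurement noise of coefficient of variation ``noise_cv``
    (the standard error model for plate/flask OD readings); replicate
    inocula vary by the same factor.  Returns ``replicate,time_h,od``.
    """
    rng = rng or np.random.default_rng()
    times = np.asarray(times, np.float64)
    sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
    frames = []
    for r in range(n_replicates):
        start = od0 * math.exp(rng.normal(0.0, sigma))
        od = start * np.exp(mu * times) * np.exp(
            rng.normal(0.0, sigma, times.size))
        frames.append(pd.DataFrame({"replicate": f"r{r + 1}",
                                    "time_h": times, "od": od}))
    return pd.concat(frames, ignore_index=True)
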