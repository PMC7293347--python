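"""Real-time run interpretation.

Calls amplification times from fluorescence curves, locates anneal-derivative
peaks from post-amplification annealing sweeps, classifies wells against a
policy (positive / late / negative / anomalous), summarises groups and fits
the sensitivity regressions (amplification time vs qPCR Cq or log template
concentration).

Portable isothermal fluorometers report "time of amplification" and "anneal
derivative temperature" from proprietary algorithms; the surrogates here are
documented, tunable, and validated against synthetic ground truth: take-off
is detected where the smoothed slope first exceeds a fraction of its maximum,
and the reported time is the quadratically refined slope-peak (inflection)
time within that take-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import linregress

WellClass = Literal["positive", "late", "negative", "anomalous"]


class RunDataError(ValueError):
    """Malformed run data (non-monotone time axis, too few points...)."""


@dataclass
class CallPolicy:
    """Decision thresholds for interpreting a run.

    ``positivity_cutoff_min``: amplification under this many minutes counts as
    detection; ``late_flag_min``: calls at or beyond this are flagged late.
    ``expected_anneal_c``/``anneal_window_c``: the product-identity check —
    the anneal-derivative peak must sit within the window for a well to be a
    true positive (assay-specific; 82.5 +/- 1.2 °C for the bundled Queensland
    fruit fly assay).
    """

    positivity_cutoff_min: float = 25.0
    late_flag_min: float = 24.0
    expected_anneal_c: float = 82.5
    anneal_window_c: float = 1.2
    slope_fraction: float = 0.2
    noise_floor_mult: float = 5.0
    min_amplitude: float = 100.0
    smooth_window: int = 9
    melt_smooth_window: int = 15
    smooth_order: int = 2

    def __post_init__(self) -> None:
        if self.late_flag_min > self.positivity_cutoff_min:
            raise ValueError("late threshold must not exceed the positivity cutoff")
        if self.anneal_window_c <= 0:
            raise ValueError("anneal window must be positive")


@dataclass
class RunWell:
    """One well: raw series plus derived calls."""

    well: str
    sample: str
    times_min: np.ndarray | None = None
    fluorescence: np.ndarray | None = None
    melt_temps_c: np.ndarray | None = None
    melt_signal: np.ndarray | None = None
    called_time_min: float | None = None
    anneal_temp_c: float | None = None
    classification: WellClass | None = None


@dataclass
class GroupSummary:
    """Average / SD / min-max of amplification time and anneal temperature."""

    label: str
    n: int
    time_mean: float
    time_sd: float | None
    time_min: float
    time_max: float
    anneal_mean: float | None
    anneal_sd: float | None
    anneal_min: float | None
    anneal_max: float | None

    def to_row(self) -> dict:
        """Bench-style rendering: one decimal, blank SD for single wells."""
        fmt = lambda v: "" if v is None else f"{v:.1f}"
        return {
            "group": self.label, "n": self.n,
            "time_avg": fmt(self.time_mean), "time_sd": fmt(self.time_sd),
            "time_min_max": f"{self.time_min:.1f}-{self.time_max:.1f}",
            "anneal_avg": fmt(self.anneal_mean), "anneal_sd": fmt(self.anneal_sd),
            "anneal_min_max": "" if self.anneal_min is None
            else f"{self.anneal_min:.1f}-{self.anneal_max:.1f}",
        }


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    x_label: str = "x"
    y_label: str = "y"

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("R^2 outside [0, 1]")


def _smooth_window(n: int, policy: CallPolicy) -> int:
    w = min(policy.smooth_window, n if n % 2 == 1 else n - 1)
    return max(w, policy.smooth_order + 2 if (policy.smooth_order + 2) % 2 == 1
               else policy.smooth_order + 3)


def _quadratic_refine(x: np.ndarray, y: np.ndarray, m: int) -> float:
    """Sub-grid extremum via a parabola through (m-1, m, m+1)."""
    if m <= 0 or m >= len(x) - 1:
        return float(x[m])
    a, b, c = y[m - 1], y[m], y[m + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(x[m])
    off = 0.5 * (a - c) / denom
    off = float(np.clip(off, -1.0, 1.0))
    return float(x[m] + off * (x[m] - x[m - 1]))


def call_time(times_min: Sequence[float], signal: Sequence[float],
              policy: CallPolicy = CallPolicy()) -> float | None:
    """Amplification time in minutes, or ``None`` for a no-amplification well.

    Detection requires the smoothed plateau to rise above the baseline by at
    least ``max(min_amplitude, noise_floor_mult * baseline SD)``.  Take-off is
    the first interval where the smoothed slope exceeds
    ``slope_fraction * max slope``; the reported time is the refined slope
    peak inside that interval.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise RunDataError("time and signal series must be 1-D and equal length")
    if len(t) < 10:
        raise RunDataError(f"need at least 10 time points, got {len(t)}")
    if np.any(np.diff(t) <= 0):
        raise RunDataError("time axis must be strictly increasing")

    w = _smooth_window(len(t), policy)
    dt = float(np.median(np.diff(t)))
    smooth = savgol_filter(y, w, policy.smooth_order)
    slope = savgol_filter(y, w, policy.smooth_order, deriv=1, delta=dt)

    nb = max(5, len(t) // 10)
    baseline = y[:nb]
    amplitude = float(np.max(smooth) - np.median(baseline))
    floor = max(policy.min_amplitude, policy.noise_floor_mult * float(np.std(baseline)))
    if amplitude < floor:
        return None

    m = int(np.argmax(slope))
    smax = float(slope[m])
    if smax <= 0:
        return None
    # take-off: walk back from the slope peak to the last point still above
    # the fraction threshold; the reported time is the refined slope peak
    thresh = policy.slope_fraction * smax
    i0 = m
    while i0 > 0 and slope[i0 - 1] >= thresh:
        i0 -= 1
    if i0 == 0 and slope[0] >= thresh:
        return None  # already rising at t=0: take-off not observed
    return _quadratic_refine(t, slope, m)


def anneal_peak(temps_c: Sequence[float], signal: Sequence[float],
                policy: CallPolicy = CallPolicy()) -> float | None:
    """Temperature of the anneal-derivative peak, or ``None`` if no peak.

    The annealing sweep cools from high to low temperature while product
    re-anneals (signal rises as temperature falls), so the derivative peak is
    the maximum of -dS/dT on the temperature-ascending series.  Sub-grid
    precision comes from a local quadratic fit; a peak must exceed
    the noise floor (robust residual SD) and the peak must sit inside the sweep.
    """
    T = np.asarray(temps_c, dtype=float)
    y = np.asarray(signal, dtype=float)
    if T.ndim != 1 or T.shape != y.shape:
        raise RunDataError("temperature and signal series must be 1-D and equal length")
    if len(T) < 20:
        raise RunDataError(f"need at least 20 sweep points, got {len(T)}")
    order = np.argsort(T)
    T, y = T[order], y[order]
    if np.any(np.diff(T) <= 0):
        raise RunDataError("temperature sweep contains duplicate temperatures")

    w = min(policy.melt_smooth_window, len(T) if len(T) % 2 == 1 else len(T) - 1)
    w = max(w, policy.smooth_order + 2 + (policy.smooth_order % 2))
    dT = float(np.median(np.diff(T)))
    smooth = savgol_filter(y, w, policy.smooth_order)
    # detection gate: the annealing transition must rise out of the noise,
    # with noise estimated robustly from the smoothing residuals
    sigma = 1.4826 * float(np.median(np.abs(y - smooth)))
    amplitude = float(np.max(smooth) - np.min(smooth))
    if amplitude < max(policy.min_amplitude, policy.noise_floor_mult * sigma):
        return None
    deriv = -savgol_filter(y, w, policy.smooth_order, deriv=1, delta=dT)
    m = 1 + int(np.argmax(deriv[1:-1]))
    if deriv[m] <= 0:
        return None
    return _quadratic_refine(T, deriv, m)


def classify_well(time_min: float | None, anneal_c: float | None,
                  policy: CallPolicy = CallPolicy()) -> WellClass:
    """Published decision rule for one well.

    No call -> negative.  A call whose anneal-derivative temperature is
    missing or outside the expected window -> anomalous (wrong product).
    A confirmed call before the late threshold -> positive; at or after it ->
    late.
    """
    if time_min is None:
        return "negative"
    if anneal_c is None or abs(anneal_c - policy.expected_anneal_c) > policy.anneal_window_c:
        return "anomalous"
    if time_min < policy.late_flag_min and time_min < policy.positivity_cutoff_min:
        return "positive"
    return "late"


def summarize_group(wells: Sequence[RunWell], label: str) -> GroupSummary:
    """Table-style group summary over called wells (sample SD, n-1 denominator)."""
    times = [w.called_time_min for w in wells if w.called_time_min is not None]
    anneals = [w.anneal_temp_c for w in wells
               if w.called_time_min is not None and w.anneal_temp_c is not None]
    if not times:
        raise ValueError(f"group {label!r} has no called wells to summarise")
    t = np.asarray(times, dtype=float)
    a = np.asarray(anneals, dtype=float) if anneals else None
    return GroupSummary(
        label=label,
        n=len(t),
        time_mean=float(t.mean()),
        time_sd=float(t.std(ddof=1)) if len(t) > 1 else None,
        time_min=float(t.min()),
        time_max=float(t.max()),
        anneal_mean=float(a.mean()) if a is not None else None,
        anneal_sd=float(a.std(ddof=1)) if a is not None and len(a) > 1 else None,
        anneal_min=float(a.min()) if a is not None else None,
        anneal_max=float(a.max()) if a is not None else None,
    )


def fit_line(x: Sequence[float], y: Sequence[float],
             x_label: str = "x", y_label: str = "y") -> RegressionResult:
    """Ordinary least squares with R^2 = squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = linregress(x, y)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2, slope_stderr=float(res.stderr),
        x_label=x_label, y_label=y_label,
    )


# -- run-file ingestion ------------------------------------------------------
#
# CSV dialect: columns well, sample, phase ('amplification' or 'anneal'),
# x (minutes or °C), y (fluorescence, a.u.) — one row per observation.

def read_run_csv(path: str | Path) -> list[RunWell]:
    df = pd.read_csv(path)
    required = {"well", "sample", "phase", "x", "y"}
    if not required <= set(df.columns):
        raise RunDataError(f"run CSV must have columns {sorted(required)}")
    wells = []
    for well_id, g in df.groupby("well", sort=True):
        sample = str(g["sample"].iloc[0])
        amp = g[g["phase"] == "amplification"].sort_values("x")
        melt = g[g["phase"] == "anneal"]
        wells.append(RunWell(
            well=str(well_id), sample=sample,
            times_min=amp["x"].to_numpy(float) if len(amp) else None,
            fluorescence=amp["y"].to_numpy(float) if len(amp) else None,
            melt_temps_c=melt["x"].to_numpy(float) if len(melt) else None,
            melt_signal=melt["y"].to_numpy(float) if len(melt) else None,
        ))
    return wells


def analyze_run(wells: Sequence[RunWell], policy: CallPolicy = CallPolicy()) -> pd.DataFrame:
    """Call, peak-find and classify every well in place; return a per-well report."""
    rows = []
    for w in wells:
        if w.times_min is not None:
            w.called_time_min = call_time(w.times_min, w.fluorescence, policy)
        if w.melt_temps_c is not None:
            w.anneal_temp_c = anneal_peak(w.melt_temps_c, w.melt_signal, policy)
        w.classification = classify_well(w.called_time_min, w.anneal_temp_c, policy)
        rows.append({
            "well": w.well, "sample": w.sample,
            "time_min": w.called_time_min, "anneal_c": w.anneal_temp_c,
            "class": w.classification,
        })
    return pd.DataFrame(rows)


def group_summaries(wells: Sequence[RunWell]) -> pd.DataFrame:
    """Group called wells by sample label and render a summary table."""
    by: dict[str, list[RunWell]] = {}
    for w in wells:
        by.setdefault(w.sample, []).append(w)
    rows = []
    for label in sorted(by):
        called = [w for w in by[label] if w.called_time_min is not None]
        if not called:
            rows.append({"group": label, "n": 0, "time_avg": "Nil", "time_sd": "Nil",
                         "time_min_max": "Nil", "anneal_avg": "Nil", "anneal_sd": "Nil",
                         "anneal_min_max": "Nil"})
        else:
            rows.append(summarize_group(by[label], label).to_row())
    return pd.DataFrame(rows)
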