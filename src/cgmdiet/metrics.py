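"""Windowed and daily CGM metrics.

A postprandial analysis window is anchored at food-intake time and spans
2-6 hours; a daily window spans [00:00, 24:00). From each sufficiently
covered window 19 metrics are extracted:

* area metrics: total trapezoidal ``auc`` plus its rise (``auc_rise``,
  intake to peak) and fall (``auc_fall``, global maximum to the following
  local minimum) parts — total area, not baseline-corrected;
* excursion shape: relative amplitude ``amp`` (highest value minus the
  value at intake), window minimum ``amp_min``, rise-time ``t_rise``
  (intake to the highest local maximum), fall-time ``t_fall`` (global
  maximum to the following local minimum);
* slopes: chord slopes ``slope_rise``/``slope_fall``, their ratio
  ``slope_ratio``, mean consecutive finite difference ``slope_avg`` and
  steepest finite difference ``slope_steepest``;
* distribution: ``mean``, ``sd``, ``var``, ``cv`` (percent), bias-corrected
  ``skew`` and excess ``kurtosis``;
* variability: ``mage``, the mean amplitude of glycemic excursions —
  the mean of turning-point excursion amplitudes exceeding one SD of the
  window, measured in the direction of the first qualifying excursion.

Metrics are computed on the observed samples; irregular gaps are handled
by a coverage rule (windows with too few of the expected samples are
flagged insufficient and excluded), never by interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from datetime import date as date_t, datetime, time, timedelta

import numpy as np
import pandas as pd
from scipy import stats

WINDOWED_METRIC_NAMES = (
    "auc",
    "auc_rise",
    "auc_fall",
    "amp",
    "amp_min",
    "t_rise",
    "t_fall",
    "slope_rise",
    "slope_fall",
    "slope_avg",
    "slope_steepest",
    "slope_ratio",
    "mean",
    "sd",
    "mage",
    "cv",
    "var",
    "skew",
    "kurtosis",
)

DAILY_METRIC_NAMES = ("auc", "mean", "sd", "mage", "cv", "var")

WINDOW_HOURS = (2, 3, 4, 5, 6)


@dataclass
class CGMTrace:
    """One participant's timestamped glucose series (mmol/L).

    ``times`` must be strictly increasing; ``nominal_interval`` is the
    sensor's logging cadence in minutes and drives the coverage rule.
    """

    participant_id: str
    times: np.ndarray  # datetime64[s]
    glucose: np.ndarray  # float, mmol/L
    nominal_interval: float = 15.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.times.shape != self.glucose.shape:
            raise ValueError("times and glucose must have equal length")
        if self.times.size and np.any(np.diff(self.times.astype("int64")) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.glucose <= 0):
            raise ValueError("glucose must be > 0 mmol/L")
        if self.nominal_interval <= 0:
            raise ValueError("nominal_interval must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "timestamp": self.times.astype("datetime64[s]"),
                "glucose_mmol_l": self.glucose,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, nominal_interval: float = 15.0) -> "CGMTrace":
        pid = str(df["participant_id"].iloc[0])
        ts = pd.to_datetime(df["timestamp"]).to_numpy().astype("datetime64[s]")
        return cls(pid, ts, df["glucose_mmol_l"].to_numpy(float), nominal_interval)


@dataclass(frozen=True)
class AnalysisWindow:
    """Observation window anchored at food-intake time or midnight."""

    anchor: datetime
    duration_hours: float

    def __post_init__(self) -> None:
        if self.duration_hours <= 0:
            raise ValueError("window duration must be > 0")


@dataclass
class WindowData:
    """Readings of one window with times in minutes since the anchor."""

    t_min: np.ndarray
    glucose: np.ndarray
    sufficient: bool
    coverage: float


@dataclass
class PeakDecomposition:
    """Peak/trough landmarks of a window (times in minutes since anchor)."""

    peak_time: float
    peak_value: float
    global_max_time: float
    global_max_value: float
    trough_time: float
    trough_value: float


@dataclass
class MetricVector:
    auc: float
    auc_rise: float
    auc_fall: float
    amp: float
    amp_min: float
    t_rise: float
    t_fall: float
    slope_rise: float
    slope_fall: float
    slope_avg: float
    slope_steepest: float
    slope_ratio: float
    mean: float
    sd: float
    mage: float
    cv: float
    var: float
    skew: float
    kurtosis: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def extract_window(
    trace: CGMTrace,
    window: AnalysisWindow,
    min_coverage: float = 0.8,
    closed: str = "both",
) -> WindowData:
    """Readings within the window, flagged insufficient when undersampled.

    ``closed='both'`` keeps readings in [anchor, anchor+duration] (meal
    windows); ``closed='left'`` keeps [anchor, anchor+duration) (daily
    windows). Coverage is the fraction of the samples expected at the
    trace's nominal interval that are actually present; insufficiency is
    a value, not an error.
    """
    anchor64 = np.datetime64(window.anchor, "s")
    dur_min = window.duration_hours * 60.0
    end64 = anchor64 + np.timedelta64(int(round(dur_min * 60)), "s")
    if closed == "both":
        mask = (trace.times >= anchor64) & (trace.times <= end64)
        expected = dur_min / trace.nominal_interval + 1
    elif closed == "left":
        mask = (trace.times >= anchor64) & (trace.times < end64)
        expected = dur_min / trace.nominal_interval
    else:
        raise ValueError("closed must be 'both' or 'left'")
    t_min = (trace.times[mask] - anchor64).astype("timedelta64[s]").astype(float) / 60.0
    g = trace.glucose[mask]
    coverage = len(g) / expected
    return WindowData(t_min, g, sufficient=coverage >= min_coverage, coverage=coverage)


def auc_trapezoid(t_min: np.ndarray, glucose: np.ndarray) -> float:
    """Total trapezoidal area of glucose vs time, in mmol*min/L."""
    t = np.asarray(t_min, float)
    g = np.asarray(glucose, float)
    if t.size < 2:
        raise ValueError("AUC needs at least 2 readings")
    return float(np.trapezoid(g, t))


def _interior_local_maxima(g: np.ndarray) -> np.ndarray:
    """Indices of samples strictly greater than both neighbors."""
    if g.size < 3:
        return np.array([], dtype=int)
    inner = np.arange(1, g.size - 1)
    return inner[(g[inner] > g[inner - 1]) & (g[inner] > g[inner + 1])]


def peak_decomposition(t_min: np.ndarray, glucose: np.ndarray) -> PeakDecomposition:
    """Locate the excursion peak and the post-peak trough of a window.

    The peak is the highest interior local maximum (a sample strictly
    greater than both neighbors; value ties broken to the earliest); when
    the window has no interior local maximum (monotone windows) the global
    maximum is used. The trough is the first interior local minimum after
    the global maximum; when none exists it falls back to the window-end
    sample, making the fall-time 0 for windows that end while still rising.
    """
    t = np.asarray(t_min, float)
    g = np.asarray(glucose, float)
    if g.size < 3:
        raise ValueError("peak decomposition needs at least 3 readings")

    locmax = _interior_local_maxima(g)
    if locmax.size:
        peak_idx = int(locmax[np.argmax(g[locmax])])  # argmax -> earliest on ties
    else:
        peak_idx = int(np.argmax(g))
    gmax_idx = int(np.argmax(g))

    trough_idx = g.size - 1
    for i in range(gmax_idx + 1, g.size - 1):
        if g[i] < g[i - 1] and g[i] < g[i + 1]:
            trough_idx = i
            break

    return PeakDecomposition(
        peak_time=float(t[peak_idx]),
        peak_value=float(g[peak_idx]),
        global_max_time=float(t[gmax_idx]),
        global_max_value=float(g[gmax_idx]),
        trough_time=float(t[trough_idx]),
        trough_value=float(g[trough_idx]),
    )


def _chord_slope(delta_g: float, delta_t: float) -> float:
    # Degenerate flat segments (no change over no time) count as slope 0;
    # a nonzero change over zero time is undefined.
    if delta_t > 0:
        return delta_g / delta_t
    return 0.0 if delta_g == 0 else math.nan


def mage(t_min: np.ndarray, glucose: np.ndarray) -> float:
    """Mean amplitude of glycemic excursions on one window.

    Turning points are the alternating local extrema of the raw series
    (plateaus collapsed). An excursion between consecutive turning points
    qualifies when its amplitude exceeds one SD of the window's glucose;
    MAGE is the arithmetic mean of qualifying amplitudes measured in the
    direction (rise or fall) of the first qualifying excursion, and 0 when
    no excursion qualifies. Sub-24 h windows use their own SD.
    """
    g = np.asarray(glucose, float)
    if g.size < 3:
        raise ValueError("MAGE needs at least 3 readings")
    sd = float(g.std(ddof=1))
    if sd == 0:
        return 0.0

    # collapse plateaus so direction changes are well defined
    keep = np.concatenate(([True], np.diff(g) != 0))
    gc = g[keep]
    if gc.size < 2:
        return 0.0

    d = np.sign(np.diff(gc))
    turning = [0]
    for i in range(1, d.size):
        if d[i] != d[i - 1]:
            turning.append(i)
    turning.append(gc.size - 1)
    tp_vals = gc[np.asarray(turning, dtype=int)]

    amps = np.diff(tp_vals)  # signed: + rise, - fall
    qualifying = amps[np.abs(amps) > sd]
    if qualifying.size == 0:
        return 0.0
    direction = np.sign(qualifying[0])
    selected = qualifying[np.sign(qualifying) == direction]
    return float(np.mean(np.abs(selected)))


def windowed_metrics(win: WindowData) -> MetricVector:
    """All 19 postprandial metrics of one sufficiently covered window.

    Zero-variance windows yield 0 for CV and NaN for skew/kurtosis; a
    zero rise- or fall-time makes the corresponding chord slope (and the
    slope ratio) undefined unless the segment is flat.
    """
    if not win.sufficient:
        raise ValueError("window flagged insufficient; metrics undefined")
    t, g = win.t_min, win.glucose
    if g.size < 3:
        raise ValueError("windowed metrics need at least 3 readings")

    pk = peak_decomposition(t, g)
    anchor_glucose = float(g[0])
    amp = pk.peak_value - anchor_glucose
    t_rise = pk.peak_time - float(t[0])
    t_fall = pk.trough_time - pk.global_max_time
    slope_rise = _chord_slope(amp, t_rise)
    fall_drop = pk.trough_value - pk.global_max_value
    slope_fall = _chord_slope(fall_drop, t_fall)
    if math.isnan(slope_rise) or math.isnan(slope_fall):
        slope_ratio = math.nan
    elif slope_fall == 0:
        slope_ratio = 0.0 if slope_rise == 0 else math.nan
    else:
        slope_ratio = slope_rise / abs(slope_fall)

    diffs = np.diff(g) / np.diff(t)
    rise_mask = (t >= t[0]) & (t <= pk.peak_time)
    fall_mask = (t >= pk.global_max_time) & (t <= pk.trough_time)
    auc_rise = float(np.trapezoid(g[rise_mask], t[rise_mask])) if rise_mask.sum() >= 2 else 0.0
    auc_fall = float(np.trapezoid(g[fall_mask], t[fall_mask])) if fall_mask.sum() >= 2 else 0.0

    mean = float(g.mean())
    sd = float(g.std(ddof=1))
    if sd > 0:
        skew = float(stats.skew(g, bias=False))
        kurt = float(stats.kurtosis(g, bias=False, fisher=True))
    else:
        skew = math.nan
        kurt = math.nan

    return MetricVector(
        auc=auc_trapezoid(t, g),
        auc_rise=auc_rise,
        auc_fall=auc_fall,
        amp=amp,
        amp_min=float(g.min()),
        t_rise=t_rise,
        t_fall=t_fall,
        slope_rise=slope_rise,
        slope_fall=slope_fall,
        slope_avg=float(diffs.mean()),
        slope_steepest=float(np.abs(diffs).max()),
        slope_ratio=slope_ratio,
        mean=mean,
        sd=sd,
        mage=mage(t, g),
        cv=100.0 * sd / mean,
        var=sd**2,
        skew=skew,
        kurtosis=kurt,
    )


def daily_metrics(
    trace: CGMTrace, day: date_t, min_coverage: float = 0.8
) -> dict[str, float] | None:
    """The six daily metrics on [00:00, 24:00), or None when undersampled."""
    window = AnalysisWindow(datetime.combine(day, time.min), 24.0)
    win = extract_window(trace, window, min_coverage=min_coverage, closed="left")
    if not win.sufficient or win.glucose.size < 3:
        return None
    g = win.glucose
    mean = float(g.mean())
    sd = float(g.std(ddof=1))
    return {
        "auc": auc_trapezoid(win.t_min, g),
        "mean": mean,
        "sd": sd,
        "mage": mage(win.t_min, g),
        "cv": 100.0 * sd / mean,
        "var": sd**2,
    }
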