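"""OGTT glucose traces and summary metrics.

The central quantity is the incremental area under the curve (iAUC): the
trapezoid-rule area between the glucose trace and the fasting baseline,
counting only excursions above baseline. Segments that cross the baseline
are truncated at the linearly interpolated crossing point; segments
entirely at or below baseline contribute nothing. Units are mmol/L and
minutes throughout (an mg/dL reader converts on ingest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MGDL_PER_MMOLL = 18.016

#: default integration window, minutes post-ingestion (2-hour protocol)
DEFAULT_WINDOW = (0.0, 120.0)


class TraceError(ValueError):
    """Raised for malformed glucose traces."""


@dataclass(frozen=True)
class GlucoseTrace:
    """CGM readings for one participant, times in minutes from ingestion."""

    participant_id: str
    times: np.ndarray
    values: np.ndarray
    baseline: float | None = None  # fasting level; derived from trace if None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.size != v.size:
            raise TraceError("times and values must have equal length")
        if t.size < 2:
            raise TraceError("a glucose trace needs at least 2 readings")
        if not np.all(np.diff(t) > 0):
            raise TraceError("times must be strictly increasing")
        if not np.all(v > 0):
            raise TraceError("glucose values must be positive")
        if self.baseline is not None and self.baseline <= 0:
            raise TraceError("baseline must be positive")


@dataclass(frozen=True)
class GlucoseSummary:
    participant_id: str
    iauc: float  # mmol*min/L
    fasting: float  # mmol/L
    peak: float  # mmol/L
    time_above_baseline: float  # minutes


@dataclass(frozen=True)
class GlucoseCurveParams:
    """Parameters of the synthetic noiseless rise-and-decay glucose bump.

    The noiseless curve is ``fasting + peak_height * g(t; time_to_peak)
    - undershoot_depth * g(t; undershoot_stretch * time_to_peak)`` where
    ``g(t; s) = (t/s) * exp(1 - t/s)`` peaks at 1 when t = s; it rises
    smoothly from baseline, peaks, and decays back (optionally dipping
    below baseline late). ``decay_rate`` rescales the post-peak time
    constant (1.0 = symmetric-in-g decay).
    """

    fasting: float = 5.0  # mmol/L
    peak_height: float = 2.5  # mmol/L above fasting
    time_to_peak: float = 35.0  # minutes
    decay_rate: float = 1.0  # per-minute scale factor on the decay branch
    undershoot_depth: float = 0.0  # mmol/L
    undershoot_stretch: float = 2.5  # undershoot bump peaks at stretch*ttp
    noise_sd: float = 0.25  # mmol/L
    sampling_interval: float = 2.0  # minutes
    duration: float = 120.0  # minutes

    def __post_init__(self) -> None:
        if self.fasting <= 0:
            raise ValueError("fasting glucose must be positive")
        if self.duration < self.time_to_peak:
            raise ValueError("duration must cover time_to_peak")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.peak_height < 0 or self.undershoot_depth < 0:
            raise ValueError("peak_height and undershoot_depth must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def noiseless(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.fasting)
        pos = t > 0
        tp = self.time_to_peak
        # decay_rate != 1 stretches time past the peak
        te = np.where(t[pos] <= tp, t[pos], tp + (t[pos] - tp) * self.decay_rate)
        x = te / tp
        out[pos] = self.fasting + self.peak_height * x * np.exp(1.0 - x)
        if self.undershoot_depth > 0:
            su = self.undershoot_stretch * tp
            xu = te / su
            out[pos] -= self.undershoot_depth * xu * np.exp(1.0 - xu)
        return out

    def true_iauc(self, window: tuple[float, float] = DEFAULT_WINDOW) -> float:
        """Exact iAUC of the noiseless curve above its fasting baseline.

        Computed analytically when the curve cannot dip below baseline,
        otherwise by fine-grid integration of the positive part.
        """
        lo, hi = window
        lo = max(lo, 0.0)
        if self.undershoot_depth == 0 and self.decay_rate == 1.0:
            # closed form: A * integral_0^T (t/tp) e^(1-t/tp) dt
            tp, x = self.time_to_peak, hi / self.time_to_peak
            x0 = lo / self.time_to_peak
            integral = np.e * tp * ((1 + x0) * np.exp(-x0) - (1 + x) * np.exp(-x))
            return float(self.peak_height * integral)
        grid = np.linspace(lo, hi, 200_001)
        excess = np.maximum(self.noiseless(grid) - self.fasting, 0.0)
        return float(np.trapezoid(excess, grid))


def generate_glucose_trace(
    curve: GlucoseCurveParams,
    seed: int | None = None,
    participant_id: str = "p0",
    n_pre_readings: int = 2,
) -> tuple[GlucoseTrace, float]:
    """Sample a noisy CGM trace from a noiseless curve.

    Readings are taken every ``sampling_interval`` minutes over
    ``[-n_pre_readings * interval, duration]`` (pre-ingestion readings sit at
    the fasting level) with iid Gaussian sensor noise. Returns the trace and
    the exact noiseless iAUC as ground truth.
    """
    rng = np.random.default_rng(seed)
    t0 = -n_pre_readings * curve.sampling_interval
    n = int(round((curve.duration - t0) / curve.sampling_interval)) + 1
    times = t0 + curve.sampling_interval * np.arange(n)
    values = curve.noiseless(times)
    if curve.noise_sd > 0:
        values = values + rng.normal(0.0, curve.noise_sd, size=n)
    values = np.maximum(values, 0.1)  # CGM readings are physically positive
    trace = GlucoseTrace(participant_id=participant_id, times=times, values=values)
    return trace, curve.true_iauc()


def fasting_glucose(trace: GlucoseTrace) -> float:
    """Fasting level: the reading at the largest time <= 0.

    Falls back (with a warning) to the first reading when the trace starts
    after ingestion.
    """
    pre = np.nonzero(trace.times <= 0)[0]
    if pre.size == 0:
        warnings.warn(
            f"trace {trace.participant_id!r} has no pre-ingestion reading; "
            "using the first reading as fasting glucose",
            stacklevel=2,
        )
        return float(trace.values[0])
    return float(trace.values[pre[-1]])


def _effective_baseline(trace: GlucoseTrace) -> float:
    return trace.baseline if trace.baseline is not None else fasting_glucose(trace)


def compute_iauc(
    trace: GlucoseTrace,
    window: tuple[float, float] | None = DEFAULT_WINDOW,
) -> float:
    """Incremental AUC above the fasting baseline, mmol*min/L.

    Trapezoid rule per reading pair: ``((y1 + y2) / 2) * (t2 - t1)`` counted
    above baseline. If exactly one endpoint is below baseline the segment is
    split at the linear-interpolation crossing and only the positive part
    counted; if both endpoints are at/below baseline the segment is excluded.
    ``window`` clips integration to the protocol window (default 0-120 min);
    pass None to integrate the whole trace.
    """
    base = _effective_baseline(trace)
    t, y = trace.times, trace.values
    if window is not None:
        t, y = _clip_to_window(t, y, window)
    e = y - base  # excess over baseline
    total = 0.0
    for i in range(len(t) - 1):
        e1, e2 = e[i], e[i + 1]
        dt = t[i + 1] - t[i]
        if e1 <= 0 and e2 <= 0:
            continue
        if e1 >= 0 and e2 >= 0:
            total += 0.5 * (e1 + e2) * dt
        elif e1 > 0:  # crosses downward: positive triangle before the crossing
            total += 0.5 * e1 * dt * e1 / (e1 - e2)
        else:  # crosses upward
            total += 0.5 * e2 * dt * e2 / (e2 - e1)
    return float(total)


def _clip_to_window(
    t: np.ndarray, y: np.ndarray, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict a piecewise-linear trace to a window, interpolating the edges."""
    lo, hi = window
    lo = max(lo, t[0])
    hi = min(hi, t[-1])
    if hi <= lo:
        raise TraceError(f"integration window {window} does not overlap the trace")
    inside = (t > lo) & (t < hi)
    tt = np.concatenate([[lo], t[inside], [hi]])
    yy = np.concatenate([[np.interp(lo, t, y)], y[inside], [np.interp(hi, t, y)]])
    return tt, yy


def summarize_trace(
    trace: GlucoseTrace, window: tuple[float, float] | None = DEFAULT_WINDOW
) -> GlucoseSummary:
    """Bundle iAUC, fasting glucose, peak, and time above baseline."""
    base = _effective_baseline(trace)
    t, y = trace.times, trace.values
    if window is not None:
        t, y = _clip_to_window(t, y, window)
    e = y - base
    above = 0.0
    for i in range(len(t) - 1):
        e1, e2 = e[i], e[i + 1]
        dt = t[i + 1] - t[i]
        if e1 > 0 and e2 > 0:
            above += dt
        elif e1 > 0 or e2 > 0:
            hi_e = max(e1, e2)
            above += dt * hi_e / (hi_e - min(e1, e2))
    return GlucoseSummary(
        participant_id=trace.participant_id,
        iauc=compute_iauc(trace, window=window),
        fasting=fasting_glucose(trace),
        peak=float(np.max(y)),
        time_above_baseline=float(above),
    )


def read_cgm_csv(path_or_buf, units: str = "mmol/L") -> list[GlucoseTrace]:
    """Read CGM exports: columns participant_id, t_min, glucose.

    ``units`` may be 'mmol/L' (stored as-is) or 'mg/dL' (divided by 18.016).
    """
    df = pd.read_csv(path_or_buf)
    required = {"participant_id", "t_min", "glucose"}
    if not required.issubset(df.columns):
        raise TraceError(f"CGM CSV must have columns {sorted(required)}")
    if units == "mg/dL":
        df = df.assign(glucose=df["glucose"] / MGDL_PER_MMOLL)
    elif units != "mmol/L":
        raise ValueError(f"unknown glucose units {units!r}")
    traces = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("t_min")
        traces.append(
            GlucoseTrace(
                participant_id=str(pid),
                times=grp["t_min"].to_numpy(float),
                values=grp["glucose"].to_numpy(float),
            )
        )
    return traces


def traces_to_frame(traces: list[GlucoseTrace]) -> pd.DataFrame:
    """Long-format frame (participant_id, t_min, glucose_mmol_l) for CSV export."""
    parts = [
        pd.DataFrame(
            {
                "participant_id": tr.participant_id,
                "t_min": tr.times,
                "glucose_mmol_l": tr.values,
            }
        )
        for tr in traces
    ]
    return pd.concat(parts, ignore_index=True)
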