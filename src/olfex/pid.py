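"""Photoionization-detector (PID) odor-delivery validation.

A PID samples airborne volatile concentration as a voltage, recorded at
500 Hz while the odor valve cycles (45 s on / 60 s off, ten repeats per
measurement position). Processing: zero-phase Butterworth low-pass
filtering, per-cycle baseline (valve-off) subtraction to cancel sensor
drift, a log-distance regression of voltage increments, and a calibration
curve mapping liquid dilution to voltage increment with an inverse for
concentration estimation.

Negative voltage increments are reported as-is (they diagnose baseline
drift), never clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from scipy.optimize import isotonic_regression

logger = logging.getLogger(__name__)

__all__ = [
    "PIDTrace",
    "DistanceModel",
    "CalibrationCurve",
    "lowpass_filter",
    "cycle_deltas",
    "fit_distance_model",
    "fit_calibration",
    "estimate_concentration",
    "synth_pid_trace",
    "synth_distance_sweep",
]


@dataclass(frozen=True)
class PIDTrace:
    """A PID voltage time series with per-sample valve state."""

    voltage: np.ndarray
    valve_on: np.ndarray
    sample_rate_hz: float = 500.0
    distance_cm: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "voltage", np.asarray(self.voltage, dtype=float))
        object.__setattr__(self, "valve_on", np.asarray(self.valve_on, dtype=bool))
        if len(self.voltage) != len(self.valve_on):
            raise ValueError("voltage and valve_on must have equal length")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")

    def __len__(self) -> int:
        return len(self.voltage)


@dataclass(frozen=True)
class DistanceModel:
    """OLS fit of voltage increment on log10 distance: dV = a log10(d) + b."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    slope_se: float
    intercept_se: float

    def predict(self, distance_cm) -> np.ndarray:
        d = np.asarray(distance_cm, dtype=float)
        if np.any(d <= 0):
            raise ValueError("distance must be > 0")
        return self.slope * np.log10(d) + self.intercept


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone map from log10 liquid dilution to expected voltage increment.

    ``method="linear"`` fits dV = a log10(dilution) + b; ``"isotonic"``
    fits a monotone step/interpolation curve. The inverse is defined only
    inside the fitted voltage range; queries outside it raise.
    """

    method: str
    log_dilutions: np.ndarray  # sorted, fitted support
    fitted_deltas: np.ndarray  # curve values at the support
    slope: float | None = None
    intercept: float | None = None

    @property
    def delta_range(self) -> tuple[float, float]:
        return float(self.fitted_deltas.min()), float(self.fitted_deltas.max())

    def predict_delta(self, dilution) -> np.ndarray:
        d = np.asarray(dilution, dtype=float)
        if np.any(d <= 0):
            raise ValueError("dilution must be > 0")
        x = np.log10(d)
        if self.method == "linear":
            out = self.slope * x + self.intercept
        else:
            out = np.interp(x, self.log_dilutions, self.fitted_deltas)
        return float(out) if out.ndim == 0 else out

    def inverse(self, delta_v) -> np.ndarray:
        dv = np.asarray(delta_v, dtype=float)
        lo, hi = self.delta_range
        if np.any(dv < lo) or np.any(dv > hi):
            raise ValueError(
                f"voltage increment outside calibrated range [{lo:.4g}, {hi:.4g}]"
            )
        if self.method == "linear":
            x = (dv - self.intercept) / self.slope
        else:
            x = np.interp(dv, self.fitted_deltas, self.log_dilutions)
        out = 10.0**x
        return float(out) if out.ndim == 0 else out


def lowpass_filter(trace: PIDTrace, cutoff_scalar: float = 0.01, order: int = 2) -> PIDTrace:
    """Zero-phase Butterworth low-pass at ``cutoff_scalar`` x Nyquist.

    At the default 500 Hz sampling and 0.01 scalar the cutoff is 2.5 Hz.
    Applied forward-backward (filtfilt) so valve transitions keep their
    timing; DC gain is exactly 1, so a constant trace passes unchanged.
    """
    if not 0.0 < cutoff_scalar < 1.0:
        raise ValueError("cutoff_scalar must be in (0, 1)")
    b, a = sps.butter(order, cutoff_scalar)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(trace) <= padlen:
        raise ValueError("trace shorter than filter warm-up")
    filtered = sps.filtfilt(b, a, trace.voltage)
    return PIDTrace(filtered, trace.valve_on, trace.sample_rate_hz, trace.distance_cm)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs."""
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    ends = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def cycle_deltas(trace: PIDTrace, settle_s: float = 5.0) -> pd.DataFrame:
    """Per-cycle voltage increment: mean(valve on) - mean(valve off).

    A cycle is one valve-on run plus the following off run; the per-cycle
    off mean serves as the local baseline so slow sensor drift largely
    cancels. The first ``settle_s`` seconds after each valve transition are
    excluded from the averages (rise/decay transients); if a window is
    shorter than the settle time the full window is used. A final on-run
    with no following off samples is an incomplete cycle and is dropped
    with a log message.

    Returns a DataFrame with columns ``cycle_index``, ``delta_v`` and
    ``distance_cm`` (trace metadata, possibly None).
    """
    settle_n = int(round(settle_s * trace.sample_rate_hz))
    on_runs = _runs(trace.valve_on)
    rows = []
    for i, (s, e) in enumerate(on_runs):
        off_end = len(trace) if i + 1 >= len(on_runs) else on_runs[i + 1][0]
        if e >= off_end:
            logger.warning("dropping truncated final cycle %d (no off samples)", i)
            continue
        on = trace.voltage[min(s + settle_n, e - 1) : e] if e - s > settle_n else trace.voltage[s:e]
        off = (
            trace.voltage[min(e + settle_n, off_end - 1) : off_end]
            if off_end - e > settle_n
            else trace.voltage[e:off_end]
        )
        rows.append(
            {
                "cycle_index": len(rows),
                "delta_v": float(on.mean() - off.mean()),
                "distance_cm": trace.distance_cm,
            }
        )
    return pd.DataFrame(rows, columns=["cycle_index", "delta_v", "distance_cm"])


def fit_distance_model(deltas: pd.DataFrame, aggregate: str = "per_cycle") -> DistanceModel:
    """Least-squares fit of voltage increment on log10 distance.

    ``deltas`` needs columns ``distance_cm`` and ``delta_v`` with at least
    3 distinct distances. ``aggregate="per_distance"`` averages cycles
    within a distance before fitting (``"per_cycle"``, the default, uses
    every cycle as a point).
    """
    df = deltas.dropna(subset=["distance_cm", "delta_v"])
    if df["distance_cm"].nunique() < 3:
        raise ValueError("need deltas at >= 3 distinct distances")
    if aggregate == "per_distance":
        df = df.groupby("distance_cm", as_index=False)["delta_v"].mean()
    elif aggregate != "per_cycle":
        raise ValueError(f"unknown aggregate {aggregate!r}")
    x = np.log10(df["distance_cm"].to_numpy(dtype=float))
    y = df["delta_v"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in distance")
    res = stats.linregress(x, y)
    return DistanceModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(x),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
    )


def fit_calibration(
    dilutions: Sequence[float], deltas: Sequence[float], method: str = "linear"
) -> CalibrationCurve:
    """Fit the dilution -> voltage-increment calibration curve.

    Needs >= 3 distinct dilution levels spanning the query range. The
    default form is linear in log10 dilution; ``method="isotonic"`` fits a
    monotone non-parametric curve instead (useful when the PID response
    saturates).
    """
    d = np.asarray(dilutions, dtype=float)
    v = np.asarray(deltas, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dilutions must be > 0")
    if d.shape != v.shape:
        raise ValueError("dilutions and deltas must have equal length")
    if len(np.unique(d)) < 3:
        raise ValueError("need >= 3 distinct dilution levels")
    x = np.log10(d)
    order = np.argsort(x)
    x, v = x[order], v[order]
    # collapse replicate levels to their mean
    xs, inv = np.unique(x, return_inverse=True)
    vs = np.bincount(inv, weights=v) / np.bincount(inv)
    if method == "linear":
        res = stats.linregress(xs, vs)
        if res.slope == 0:
            raise ValueError("calibration curve is not monotone (zero slope)")
        fitted = res.slope * xs + res.intercept
        return CalibrationCurve("linear", xs, fitted, float(res.slope), float(res.intercept))
    if method == "isotonic":
        iso = isotonic_regression(vs, increasing=True)
        fitted = np.asarray(iso.x, dtype=float)
        if fitted.min() == fitted.max():
            raise ValueError("calibration curve is not monotone (flat isotonic fit)")
        return CalibrationCurve("isotonic", xs, fitted)
    raise ValueError(f"unknown calibration method {method!r}")


def estimate_concentration(curve: CalibrationCurve, delta_v):
    """Estimate liquid dilution (v/v) from a voltage increment.

    Inverse of the calibration curve; raises for increments outside the
    fitted range (no extrapolation).
    """
    return curve.inverse(delta_v)


# ---------------------------------------------------------------------------
# synthetic fixtures


def synth_pid_trace(
    on_s: float = 45.0,
    off_s: float = 60.0,
    cycles: int = 10,
    on_level: float | Sequence[float] = 0.3,
    off_level: float = 0.1,
    rise_tau_s: float = 0.5,
    drift_per_s: float = 0.0,
    noise_sd: float = 0.0,
    sample_rate_hz: float = 500.0,
    seed: int | np.random.Generator | None = None,
    distance_cm: float | None = None,
) -> PIDTrace:
    """Generate a synthetic valve-cycled PID trace.

    Square wave between ``off_level`` and ``on_level`` (scalar, or one
    level per cycle) with first-order exponential rise/decay edges of time
    constant ``rise_tau_s`` (0 for ideal edges), plus linear baseline drift
    and additive Gaussian noise. Reproducible from ``seed``.
    """
    if on_s <= 0 or off_s <= 0 or cycles < 1:
        raise ValueError("durations must be positive and cycles >= 1")
    n_on = int(round(on_s * sample_rate_hz))
    n_off = int(round(off_s * sample_rate_hz))
    levels = np.broadcast_to(np.asarray(on_level, dtype=float), (cycles,))
    segments: list[tuple[float, int, bool]] = []
    for lv in levels:
        segments.append((lv, n_on, True))
        segments.append((off_level, n_off, False))

    volts, valve = [], []
    v = off_level
    for target, n, state in segments:
        t = np.arange(1, n + 1) / sample_rate_hz
        if rise_tau_s > 0:
            seg = target + (v - target) * np.exp(-t / rise_tau_s)
        else:
            seg = np.full(n, target)
        volts.append(seg)
        valve.append(np.full(n, state))
        v = seg[-1]
    voltage = np.concatenate(volts)
    valve_on = np.concatenate(valve)
    n_total = len(voltage)
    if drift_per_s:
        voltage = voltage + drift_per_s * np.arange(n_total) / sample_rate_hz
    if noise_sd:
        rng = np.random.default_rng(seed)
        voltage = voltage + rng.normal(0.0, noise_sd, size=n_total)
    return PIDTrace(voltage, valve_on, sample_rate_hz, distance_cm)


def synth_distance_sweep(
    distances: Sequence[float],
    slope: float = -0.0795,
    intercept: float = 0.255,
    off_level: float = 0.1,
    noise_sd: float = 0.0,
    seed: int | None = None,
    settle_s: float = 5.0,
    **trace_kwargs,
) -> pd.DataFrame:
    """Per-cycle deltas for traces recorded at several distances.

    Each distance gets a synthetic trace whose programmed voltage increment
    follows dV = slope * log10(distance) + intercept; extra keyword
    arguments go to :func:`synth_pid_trace` and ``settle_s`` to
    :func:`cycle_deltas`. Returns the concatenated per-cycle delta table,
    ready for :func:`fit_distance_model`.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for d in distances:
        dv = slope * np.log10(d) + intercept
        trace = synth_pid_trace(
            on_level=off_level + dv,
            off_level=off_level,
            noise_sd=noise_sd,
            seed=rng,
            distance_cm=float(d),
            **trace_kwargs,
        )
        frames.append(cycle_deltas(trace, settle_s=settle_s))
    return pd.concat(frames, ignore_index=True)
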