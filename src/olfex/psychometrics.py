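"""Summary statistics for Go/no-go threshold sessions.

Hit and correct-rejection rates, censored latencies, non-parametric signal
detection indices (A' sensitivity, B'' response bias), descending-series
threshold determination, dilution-step rescaling relative to an individual
threshold, trial-block and session-time binning, and per-trial heart-rate
averaging.

A' and B'' follow the Stanislaw & Todorov formulation:

    A'  = 0.5 + sgn(H - F) * [(H - F)^2 + |H - F|] / [4 max(H, F) - 4 H F]
    B'' = sgn(H - F) * [H(1-H) - F(1-F)] / [H(1-H) + F(1-F)]

with A' in [0, 1] (0.5 = chance, 1 = perfect) and B'' in [-1, 1]
(0 = unbiased; positive = no-go bias, negative = go bias).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SDTResult",
    "ThresholdResult",
    "a_prime",
    "b_double_prime",
    "adjust_extreme_rates",
    "outcome_rates",
    "determine_threshold",
    "dilution_steps",
    "bin_results",
    "latency_summary",
    "hr_per_trial",
]


@dataclass(frozen=True)
class SDTResult:
    H: float
    F: float
    a_prime: float
    b_double_prime: float
    n_signal: int
    n_noise: int


@dataclass(frozen=True)
class ThresholdResult:
    """Individual detection threshold and the dilution-step scale built on it.

    ``status`` is ``"reached"`` or ``"not_reached"``; when not reached the
    threshold is None and no dilution steps are reported (a value is never
    fabricated). ``dilution_steps`` maps each tested concentration to its
    log10 ratio to the threshold (0 at threshold, +0.5 per half-log step up).
    """

    status: str
    threshold_concentration: float | None = None
    intensity: int | None = None  # intensity whose hit rate met the criterion
    dilution_steps: Mapping[float, float] | None = None

    @property
    def reached(self) -> bool:
        return self.status == "reached"


def _check_rate(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError(f"{name} must be in [0, 1]")
    return arr


def a_prime(h, f):
    """Non-parametric sensitivity A' in [0, 1].

    Accepts scalars or arrays. A'(H, H) = 0.5 (no discrimination),
    A'(1, 0) = 1 (perfect), and A'(F, H) = 1 - A'(H, F).
    """
    h = _check_rate(h, "H")
    f = _check_rate(f, "F")
    diff = h - f
    num = diff**2 + np.abs(diff)
    den = 4.0 * np.maximum(h, f) - 4.0 * h * f
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 + np.sign(diff) * num / den
    out = np.where(den == 0, 0.5, out)  # H == F == 0 or 1: chance
    return float(out) if out.ndim == 0 else out


def b_double_prime(h, f, n_signal: int | None = None, n_noise: int | None = None):
    """Non-parametric response bias B'' in [-1, 1].

    B''(H, 1-H) = 0 and B''(H, F) = -B''(F, H). When H and F are both
    extreme the denominator vanishes; if trial counts are supplied the
    1/(2N) extreme-rate adjustment is applied first, otherwise a ValueError
    is raised.
    """
    h = _check_rate(h, "H")
    f = _check_rate(f, "F")
    den = h * (1 - h) + f * (1 - f)
    if np.any(den == 0):
        if n_signal is None or n_noise is None:
            raise ValueError(
                "B'' undefined for extreme H and F; supply n_signal/n_noise "
                "for the 1/(2N) adjustment"
            )
        h, f = adjust_extreme_rates(h, f, n_signal, n_noise)
        den = h * (1 - h) + f * (1 - f)
    out = np.sign(h - f) * (h * (1 - h) - f * (1 - f)) / den
    return float(out) if out.ndim == 0 else out


def adjust_extreme_rates(h, f, n_signal: int, n_noise: int):
    """Replace rates of 0 with 1/(2N) and 1 with 1 - 1/(2N).

    The standard correction for extreme proportions before computing signal
    detection indices; N is the number of trials behind each rate.
    """
    if n_signal < 1 or n_noise < 1:
        raise ValueError("trial counts must be >= 1")
    h = np.asarray(h, dtype=float)
    f = np.asarray(f, dtype=float)
    hs = np.clip(h, 1.0 / (2 * n_signal), 1.0 - 1.0 / (2 * n_signal))
    fs = np.clip(f, 1.0 / (2 * n_noise), 1.0 - 1.0 / (2 * n_noise))
    if h.ndim == 0:
        return float(hs), float(fs)
    return hs, fs


# ---------------------------------------------------------------------------
# event-log summaries


def _require_columns(trials: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = [c for c in cols if c not in trials.columns]
    if missing:
        raise ValueError(f"trials table missing columns: {missing}")


def outcome_rates(
    trials: pd.DataFrame, correction: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hit rates, latencies and SDT indices per concentration x intensity.

    ``trials`` is the event-log table (one row per trial, columns
    ``stimulus_class``, ``concentration_vv``, ``intensity_kmh``,
    ``outcome``, ``latency_s``). Diluent trials are not concentration
    specific, so the false-alert rate F is pooled per intensity and shared
    by every concentration cell at that intensity.

    Returns ``(summary, sdt)``: per-cell hit rate / mean latency / counts,
    and per-cell H, F, A', B'' with trial counts. With ``correction`` the
    1/(2N) extreme-rate adjustment is applied before the SDT formulas
    (required whenever a cell has H of 0 or 1, e.g. total late-session
    collapse). Cells with no trials are simply absent, never reported as 0.
    """
    _require_columns(
        trials,
        ["stimulus_class", "concentration_vv", "intensity_kmh", "outcome", "latency_s"],
    )
    target = trials[trials["stimulus_class"] == "target"]
    diluent = trials[trials["stimulus_class"] == "diluent"]

    noise: dict[int, tuple[float, int]] = {}
    for inten, grp in diluent.groupby("intensity_kmh"):
        n = len(grp)
        f = (grp["outcome"] == "false_alert").sum() / n
        noise[int(inten)] = (f, n)

    srows, drows = [], []
    for (conc, inten), grp in target.groupby(["concentration_vv", "intensity_kmh"]):
        inten = int(inten)
        n = len(grp)
        hits = int((grp["outcome"] == "hit").sum())
        h = hits / n
        srows.append(
            {
                "concentration_vv": conc,
                "intensity_kmh": inten,
                "hit_rate": h,
                "mean_latency_s": grp["latency_s"].mean(),
                "n_trials": n,
            }
        )
        if inten in noise:
            f, n_noise = noise[inten]
            hh, ff = (h, f)
            if correction:
                hh, ff = adjust_extreme_rates(h, f, n, n_noise)
            drows.append(
                {
                    "concentration_vv": conc,
                    "intensity_kmh": inten,
                    "H": h,
                    "F": f,
                    "a_prime": a_prime(hh, ff),
                    "b_double_prime": b_double_prime(hh, ff, n, n_noise),
                    "n_signal": n,
                    "n_noise": n_noise,
                }
            )
    order = ["concentration_vv", "intensity_kmh"]
    summary = pd.DataFrame(srows).sort_values(order, ascending=[False, True], ignore_index=True)
    sdt = pd.DataFrame(drows)
    if not sdt.empty:
        sdt = sdt.sort_values(order, ascending=[False, True], ignore_index=True)
    return summary, sdt


def determine_threshold(
    summary: pd.DataFrame,
    intensity: int | str = "either",
    inclusive: bool = True,
) -> ThresholdResult:
    """Find the individual detection threshold from a descending series.

    The threshold is the first (highest) concentration whose hit rate is
    <= 0.5 under the determining ``intensity`` — a specific speed, or
    ``"either"`` (default, matching the stopping rule: any intensity
    qualifies a concentration). Returns an explicit ``"not_reached"``
    result when no concentration qualifies.
    """
    _require_columns(summary, ["concentration_vv", "intensity_kmh", "hit_rate"])
    df = summary
    if intensity != "either":
        df = df[df["intensity_kmh"] == int(intensity)]
        if df.empty:
            raise ValueError(f"no rows at intensity {intensity}")

    def qualifies(rate: float) -> bool:
        return rate <= 0.5 if inclusive else rate < 0.5

    concs = sorted(df["concentration_vv"].unique(), reverse=True)
    for c in concs:
        cell = df[df["concentration_vv"] == c]
        hit = cell.loc[cell["hit_rate"].apply(qualifies)]
        if not hit.empty:
            # prefer the moderate intensity when both qualify (the condition
            # under which thresholds are reached first)
            row = hit.sort_values("intensity_kmh", ascending=False).iloc[0]
            steps = {cc: float(np.log10(cc / c)) for cc in sorted(df["concentration_vv"].unique())}
            return ThresholdResult(
                status="reached",
                threshold_concentration=float(c),
                intensity=int(row["intensity_kmh"]),
                dilution_steps=steps,
            )
    return ThresholdResult(status="not_reached")


def dilution_steps(concentration, threshold):
    """Log10 ratio of a concentration to an individual's threshold.

    0 at threshold; +0.5 per half-log concentration increase. Accepts
    scalars or arrays; both inputs must be positive.
    """
    c = np.asarray(concentration, dtype=float)
    t = np.asarray(threshold, dtype=float)
    if np.any(c <= 0) or np.any(t <= 0):
        raise ValueError("concentration and threshold must be > 0")
    out = np.log10(c / t)
    return float(out) if out.ndim == 0 else out


def bin_results(trials: pd.DataFrame, kind: str = "trial_block_25") -> pd.DataFrame:
    """Per-bin hit rates and latencies within sessions.

    ``kind="trial_block_25"`` partitions trials 1-100 into four 25-trial
    blocks (1-25, 26-50, 51-75, 76-100). ``kind="time_bin_10min"``
    partitions by trial start time into [0, 10), [10, 20) and [20, 30+)
    minute bins (the last bin is open-ended). Rates are per concentration x
    intensity within bins, computed as in :func:`outcome_rates`.
    """
    if kind == "trial_block_25":
        _require_columns(trials, ["trial_index"])
        bins = (trials["trial_index"] - 1) // 25 + 1
    elif kind == "time_bin_10min":
        _require_columns(trials, ["start_s"])
        bins = np.minimum(trials["start_s"] // 600.0, 2).astype(int) + 1
    else:
        raise ValueError(f"unknown bin kind {kind!r}")

    target = trials[trials["stimulus_class"] == "target"].copy()
    target["bin_index"] = bins[target.index]
    rows = []
    for (b, conc, inten), grp in target.groupby(
        ["bin_index", "concentration_vv", "intensity_kmh"]
    ):
        rows.append(
            {
                "bin_kind": kind,
                "bin_index": int(b),
                "concentration_vv": conc,
                "intensity_kmh": int(inten),
                "hit_rate": (grp["outcome"] == "hit").mean(),
                "mean_latency_s": grp["latency_s"].mean(),
                "n_trials": len(grp),
            }
        )
    return pd.DataFrame(rows)


def latency_summary(
    trials: pd.DataFrame, by: tuple[str, ...] = ("concentration_vv", "intensity_kmh")
) -> pd.DataFrame:
    """Mean censored latency per cell on target trials.

    Non-responses enter at the censoring value of 10 s, already applied at
    scoring time, so a cell of all misses averages exactly 10.
    """
    _require_columns(trials, ["stimulus_class", "latency_s", *by])
    target = trials[trials["stimulus_class"] == "target"]
    out = (
        target.groupby(list(by))["latency_s"]
        .agg(mean_latency_s="mean", n_trials="size")
        .reset_index()
    )
    return out


def hr_per_trial(
    hr: pd.DataFrame, trials: pd.DataFrame, offset_s: float = 0.0
) -> pd.DataFrame:
    """Average heart rate from the beginning to the end of each trial.

    ``hr`` holds 1 Hz samples (``timestamp_s``, ``bpm``) sharing the
    session-clock origin with ``trials`` up to ``offset_s`` (added to the
    HR timestamps). Trials with no overlapping samples get ``NaN`` and
    ``n_samples = 0`` — flagged missing, never reported as 0 bpm.
    """
    _require_columns(hr, ["timestamp_s", "bpm"])
    _require_columns(trials, ["trial_index", "start_s", "end_s"])
    ts = hr["timestamp_s"].to_numpy(dtype=float) + offset_s
    if np.any(np.diff(ts) < 0):
        raise ValueError("heart-rate timestamps must be ordered")
    bpm = hr["bpm"].to_numpy(dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(bpm)])
    lo = np.searchsorted(ts, trials["start_s"].to_numpy(dtype=float), side="left")
    hi = np.searchsorted(ts, trials["end_s"].to_numpy(dtype=float), side="right")
    n = hi - lo
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
    return pd.DataFrame(
        {
            "trial_index": trials["trial_index"].to_numpy(),
            "mean_bpm": means,
            "n_samples": n,
        }
    )
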