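"""Generative model of a dog's detection behavior during treadmill exercise.

The model stands in for the study's animals so the whole pipeline runs with
no external data. Per-trial hit probability follows a psychometric function
of log10 concentration whose midpoint (detection threshold) degrades
linearly with exercise duration at moderate intensity only; false-alert
rates depend on intensity but not concentration; response latencies grow
with dilution and with intensity; heart rate is a stationary AR(1) series
around an intensity-specific steady-state mean.

Default parameters are illustrative, loosely matched to the printed summary
statistics of the study this paradigm models (low/moderate heart rates of
95.9 and 121.2 bpm, false-alert proportion about 0.05, miss proportion
about 0.02, near-ceiling detection in the first 10 minutes of a moderate
session collapsing to ~0 after 20 minutes). They are not fitted to any
animal's data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import norm

from .session import (
    INTENSITY_MODERATE,
    DEFAULT_TIMING,
    BlockDesign,
    PokeEvent,
    SessionPlan,
    SessionResult,
    TrialSpec,
    TrialTiming,
    make_block_design,
    randomize_session,
    run_session,
    stop_rule,
)

__all__ = [
    "DogModel",
    "StudyResult",
    "p_hit",
    "sample_latency",
    "sample_response",
    "generate_hr",
    "generate_study",
]


@dataclass(frozen=True)
class DogModel:
    """Parameters of one simulated subject.

    Psychometric: ``mu0`` is the resting midpoint of the detection function
    in log10 v/v units; ``sigma`` its slope scale (log10 units); ``lapse``
    the probability of missing a clearly supra-threshold odor; ``guess`` a
    lower asymptote (0 by default). At moderate intensity the midpoint is
    elevated by ``decay_rate`` log10 units per minute once
    ``decay_onset_min`` minutes of exercise have elapsed; low-intensity
    sessions do not decay.

    False alerts: one rate per intensity (``fa_rate_low``/``fa_rate_mod``),
    independent of concentration — matching a bias shift with speed but not
    with dilution.

    Latency: expected alert latency is ``latency_base_s +
    latency_conc_slope * (-log10 c) + latency_intensity_offset_s`` (offset
    applied at moderate intensity), with multiplicative log-normal noise,
    truncated to the scoreable range [0.4, 10] s.

    Heart rate: AR(1) around ``hr_mean_low``/``hr_mean_mod`` with marginal
    SD ``hr_sd`` and lag-1 autocorrelation ``hr_ar``.
    """

    mu0: float = -5.4
    sigma: float = 0.35
    lapse: float = 0.02
    guess: float = 0.0
    fa_rate_low: float = 0.07
    fa_rate_mod: float = 0.03
    decay_rate: float = 0.1
    decay_onset_min: float = 10.0
    decay_form: str = "linear"  # or "exponential"
    decay_tau_min: float = 10.0
    sigmoid: str = "gaussian"  # or "logistic"
    latency_base_s: float = 0.8
    latency_conc_slope: float = 0.6
    latency_intensity_offset_s: float = 1.0
    latency_noise_sd: float = 0.3
    hr_mean_low: float = 95.9
    hr_mean_mod: float = 121.2
    hr_sd: float = 6.6
    hr_ar: float = 0.9

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for name in ("lapse", "guess", "fa_rate_low", "fa_rate_mod"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")
        if self.hr_mean_low <= 0 or self.hr_mean_mod <= 0:
            raise ValueError("heart-rate means must be positive")
        if not 0.0 <= self.hr_ar < 1.0:
            raise ValueError("hr_ar must be in [0, 1)")
        if self.sigmoid not in ("gaussian", "logistic"):
            raise ValueError(f"unknown sigmoid family {self.sigmoid!r}")
        if self.decay_form not in ("linear", "exponential"):
            raise ValueError(f"unknown decay form {self.decay_form!r}")

    def fa_rate(self, intensity: int) -> float:
        return self.fa_rate_mod if intensity == INTENSITY_MODERATE else self.fa_rate_low

    def hr_mean(self, intensity: int) -> float:
        return self.hr_mean_mod if intensity == INTENSITY_MODERATE else self.hr_mean_low


def _midpoint(model: DogModel, intensity: int, elapsed_min: float) -> float:
    """Time-varying psychometric midpoint mu(t) in log10 v/v units."""
    if intensity != INTENSITY_MODERATE or model.decay_rate == 0:
        return model.mu0
    t = max(0.0, elapsed_min - model.decay_onset_min)
    if model.decay_form == "linear":
        shift = model.decay_rate * t
    else:  # saturating elevation with initial slope decay_rate
        shift = model.decay_rate * model.decay_tau_min * (
            1.0 - np.exp(-t / model.decay_tau_min)
        )
    return model.mu0 + shift


def p_hit(
    model: DogModel, concentration: float, intensity: int, elapsed_min: float = 0.0
) -> float:
    """Probability of an alert on a target trial.

    A lapse-adjusted sigmoid of (log10 c - mu(t)) / sigma, where the
    midpoint mu(t) is elevated by exercise duration at moderate intensity
    only. Monotone non-decreasing in concentration and non-increasing in
    elapsed time at moderate intensity; independent of time at low
    intensity.
    """
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    z = (np.log10(concentration) - _midpoint(model, intensity, elapsed_min)) / model.sigma
    base = norm.cdf(z) if model.sigmoid == "gaussian" else 1.0 / (1.0 + np.exp(-z))
    return float(model.guess + (1.0 - model.guess - model.lapse) * base)


def sample_latency(
    model: DogModel,
    concentration: float,
    intensity: int,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> float:
    """Draw one alert latency (seconds), truncated to [criterion, 10]."""
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    mean = (
        model.latency_base_s
        + model.latency_conc_slope * (-np.log10(concentration))
        + (model.latency_intensity_offset_s if intensity == INTENSITY_MODERATE else 0.0)
    )
    if model.latency_noise_sd > 0:
        sd = model.latency_noise_sd
        # mean-preserving multiplicative log-normal noise
        lat = mean * np.exp(rng.normal(-0.5 * sd * sd, sd))
    else:
        lat = mean
    return float(np.clip(lat, DEFAULT_TIMING.poke_criterion_s, 10.0))


def sample_response(
    model: DogModel,
    spec: TrialSpec,
    intensity: int,
    elapsed_min: float = 0.0,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> list[PokeEvent]:
    """Draw the poke stream for one trial.

    Target trials emit a criterion-satisfying poke with probability
    ``p_hit`` at a sampled latency; diluent trials emit one with the
    intensity's false-alert rate (latency drawn at the resting midpoint
    concentration, since no dilution is present to time against).
    """
    rng = np.random.default_rng(seed)
    if spec.is_target:
        p = p_hit(model, spec.concentration, intensity, elapsed_min)
        if rng.random() >= p:
            return []
        conc = spec.concentration
    else:
        if rng.random() >= model.fa_rate(intensity):
            return []
        conc = 10.0 ** model.mu0
    lat = sample_latency(model, conc, intensity, rng)
    onset = max(0.0, lat - DEFAULT_TIMING.poke_criterion_s)
    duration = DEFAULT_TIMING.poke_criterion_s + rng.uniform(0.2, 1.0)
    return [PokeEvent(onset_s=onset, duration_s=duration)]


def generate_hr(
    model: DogModel,
    intensity: int,
    duration_min: float,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Simulate a 1 Hz steady-state heart-rate series.

    Stationary AR(1) around the intensity's mean with marginal SD
    ``hr_sd``: innovations have SD ``hr_sd * sqrt(1 - hr_ar**2)``. Returns
    a DataFrame with columns ``timestamp_s`` (seconds from session start)
    and ``bpm``.
    """
    if duration_min <= 0:
        raise ValueError("duration_min must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(60.0 * duration_min))
    mean = model.hr_mean(intensity)
    if model.hr_sd == 0:
        bpm = np.full(n, mean)
    else:
        innov_sd = model.hr_sd * np.sqrt(1.0 - model.hr_ar**2)
        e = rng.normal(0.0, innov_sd, size=n)
        e[0] = rng.normal(0.0, model.hr_sd)  # stationary start
        bpm = mean + sps.lfilter([1.0], [1.0, -model.hr_ar], e)
    return pd.DataFrame({"timestamp_s": np.arange(n, dtype=float), "bpm": bpm})


# ---------------------------------------------------------------------------
# full study


@dataclass(frozen=True)
class StudyResult:
    """Everything a simulated descending-block threshold study produced."""

    sessions: tuple[SessionResult, ...]
    hr: tuple[pd.DataFrame, ...]
    block_tables: tuple[pd.DataFrame, ...]  # pooled hit rates per block
    stopped_block: int | None  # None -> criterion never fired
    threshold: "object | None" = None  # psychometrics.ThresholdResult

    @property
    def stopped(self) -> bool:
        return self.stopped_block is not None


def generate_study(
    model: DogModel,
    seed: int | np.random.SeedSequence,
    *,
    first_top_concentration: float = 1e-2,
    max_blocks: int = 3,
    intensity_orders: Sequence[str] | None = None,
    timing: TrialTiming = DEFAULT_TIMING,
    cr_rate: float = 0.40,
    stop_inclusive: bool = True,
    out_dir=None,
) -> StudyResult:
    """Run blocks of four sessions until the stopping rule fires.

    Blocks descend in half-log concentration steps starting at
    ``first_top_concentration`` (10^-2 by default), overlapping one
    concentration between blocks; each block runs four 100-trial sessions
    in a counterbalanced 8-4-8-4 / 4-8-4-8 intensity order. After each
    block the two sessions per intensity are pooled and testing stops once
    any concentration at either intensity shows a hit rate <= 0.5.

    If ``out_dir`` is given, the event-log and heart-rate CSVs are written
    there as a dataset directory. Fully reproducible from ``seed``.
    """
    from . import psychometrics as psy

    if intensity_orders is None:
        intensity_orders = ["8-4-8-4" if b % 2 == 1 else "4-8-4-8" for b in range(1, max_blocks + 1)]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)

    sessions: list[SessionResult] = []
    hrs: list[pd.DataFrame] = []
    tables: list[pd.DataFrame] = []
    stopped_block: int | None = None
    threshold = None
    top = first_top_concentration

    for b in range(1, max_blocks + 1):
        design = make_block_design(b, top, order=intensity_orders[b - 1])
        block_sessions: list[SessionResult] = []
        for speed in design.intensity_sequence:
            plan_ss, run_ss, hr_ss = ss.spawn(3)
            plan = randomize_session(design, speed, plan_ss, timing=timing, cr_rate=cr_rate)
            sres = run_session(plan, model, run_ss)
            block_sessions.append(sres)
            hrs.append(generate_hr(model, speed, sres.duration_min, hr_ss))
        sessions.extend(block_sessions)

        from .io import sessions_to_frame  # late import to avoid cycle

        trials = sessions_to_frame(block_sessions)
        summary, _ = psy.outcome_rates(trials, correction=False)
        table = summary[["concentration_vv", "intensity_kmh", "hit_rate", "n_trials"]]
        tables.append(table)
        if stop_rule(table, inclusive=stop_inclusive):
            stopped_block = b
            threshold = psy.determine_threshold(summary, inclusive=stop_inclusive)
            break
        top = design.concentrations[-1]

    study = StudyResult(
        sessions=tuple(sessions),
        hr=tuple(hrs),
        block_tables=tuple(tables),
        stopped_block=stopped_block,
        threshold=threshold,
    )
    if out_dir is not None:
        from .io import write_study

        write_study(out_dir, study)
    return study
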