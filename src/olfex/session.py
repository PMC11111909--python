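"""Go/no-go session scheduling and trial scoring.

A testing session is 100 trials at 50% target frequency: 50 trials present
the diluent (mineral oil) and 50 present one of four half-log serial
dilutions of the target odorant. Scheduling is constrained in sets of ten
trials (5 diluent, every concentration at least once, one concentration
doubled) so that concentrations are spread evenly across the session.

Scoring follows the olfactometer's trial state machine: a continuous nose
poke of at least 0.4 s inside the active response window is a Go ("alert");
10 s without a criterion poke is a No-go ("all clear"); a sub-criterion poke
inside the initial window extends the window once by 10 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialTiming",
    "PokeEvent",
    "TrialSpec",
    "BlockDesign",
    "SessionPlan",
    "TrialResult",
    "SessionResult",
    "make_block_design",
    "randomize_session",
    "assign_cr_reinforcement",
    "score_trial",
    "run_session",
    "stop_rule",
    "INTENSITY_LOW",
    "INTENSITY_MODERATE",
]

#: Treadmill speeds (km/h) corresponding to low and moderate exercise
#: intensity for medium-sized dogs.
INTENSITY_LOW = 4
INTENSITY_MODERATE = 8

_HALF_LOG = 10.0 ** -0.5
_EPS = 1e-9

_ORDER_MAP = {
    "8-4-8-4": (8, 4, 8, 4),
    "4-8-4-8": (4, 8, 4, 8),
}


@dataclass(frozen=True)
class TrialTiming:
    """Trial state-machine parameters (seconds).

    Defaults are the final-phase trial parameters: 0.4 s poke criterion,
    10 s response window, a single 10 s extension granted by a sub-criterion
    poke, and a 10 s inter-trial interval for odor clearance.
    """

    poke_criterion_s: float = 0.4
    window_s: float = 10.0
    extension_s: float = 10.0
    max_extensions: int = 1
    iti_s: float = 10.0

    def __post_init__(self) -> None:
        if self.poke_criterion_s <= 0 or self.window_s <= 0:
            raise ValueError("poke criterion and window must be positive")
        if self.extension_s < 0 or self.max_extensions < 0 or self.iti_s < 0:
            raise ValueError("extension, max_extensions and ITI must be >= 0")


DEFAULT_TIMING = TrialTiming()


@dataclass(frozen=True)
class PokeEvent:
    """One continuous IR-beam break, timed from odor onset."""

    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"poke onset must be >= 0, got {self.onset_s}")
        if self.duration_s <= 0:
            raise ValueError(f"poke duration must be > 0, got {self.duration_s}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class TrialSpec:
    """Scheduled stimulus for one trial.

    ``concentration`` is the v/v liquid dilution of the target odorant, or
    ``None`` for a diluent (distractor) trial. ``cr_reinforced`` pre-assigns
    whether a correct rejection on this trial would be reinforced; it is
    meaningful only for diluent trials.
    """

    trial_index: int
    concentration: float | None
    cr_reinforced: bool = False

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise ValueError("trial_index starts at 1")
        if self.concentration is not None and self.concentration <= 0:
            raise ValueError("target concentration must be > 0")

    @property
    def is_target(self) -> bool:
        return self.concentration is not None


@dataclass(frozen=True)
class BlockDesign:
    """Four half-log concentrations and the intensity order for one block.

    Concentrations descend in half-log (10^-0.5) steps, spanning 1.5 log10
    units; consecutive blocks overlap at one concentration so the subject
    always has one detectable stimulus.
    """

    block_index: int
    concentrations: tuple[float, float, float, float]
    intensity_sequence: tuple[int, int, int, int]


@dataclass(frozen=True)
class SessionPlan:
    """The scheduled 100-trial sequence for one session."""

    trials: tuple[TrialSpec, ...]
    intensity: int
    block_index: int
    concentrations: tuple[float, ...]
    timing: TrialTiming = DEFAULT_TIMING
    warmup_min: float = 2.0

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_diluent(self) -> int:
        return sum(1 for t in self.trials if not t.is_target)


@dataclass(frozen=True)
class TrialResult:
    """Scored outcome of one trial.

    ``latency_s`` is the alert time on the odor-onset clock for responses
    (it can exceed the 10 s window when the extension was used) and exactly
    ``window_s`` for non-responses (censored). ``start_s``/``end_s`` are on
    the session clock and exclude the following ITI.
    """

    trial_index: int
    outcome: str  # hit | miss | false_alert | correct_rejection
    latency_s: float
    reinforced: bool
    start_s: float
    end_s: float


@dataclass(frozen=True)
class SessionResult:
    """One scored session: plan, per-trial results and raw poke streams."""

    plan: SessionPlan
    results: tuple[TrialResult, ...]
    pokes: tuple[tuple[PokeEvent, ...], ...] = ()

    @property
    def duration_min(self) -> float:
        """Session duration in minutes, first odor onset to last trial end
        (trailing ITI and the 2-min treadmill warm-up excluded)."""
        return self.results[-1].end_s / 60.0


# ---------------------------------------------------------------------------
# scheduling


def make_block_design(
    block_index: int,
    top_concentration: float,
    order: str | Sequence[int] = "8-4-8-4",
) -> BlockDesign:
    """Build one block of four descending half-log concentrations.

    Parameters
    ----------
    block_index : int
        1-based block number.
    top_concentration : float
        Highest v/v dilution of the block. For block k > 1 this should be
        the bottom concentration of block k - 1 (overlap rule).
    order : str or sequence of int
        Intensity sequence for the four sessions, ``"8-4-8-4"`` or
        ``"4-8-4-8"`` (or an explicit 4-tuple of speeds).
    """
    if block_index < 1:
        raise ValueError("block_index must be >= 1")
    if top_concentration <= 0:
        raise ValueError("top_concentration must be > 0")
    if isinstance(order, str):
        try:
            speeds = _ORDER_MAP[order]
        except KeyError:
            raise ValueError(f"unknown intensity order {order!r}") from None
    else:
        speeds = tuple(int(s) for s in order)
        if len(speeds) != 4:
            raise ValueError("intensity sequence must have 4 entries")
    concs = tuple(top_concentration * _HALF_LOG**i for i in range(4))
    return BlockDesign(block_index, concs, speeds)


def randomize_session(
    design: BlockDesign,
    intensity: int,
    seed: int | np.random.Generator | np.random.SeedSequence,
    *,
    timing: TrialTiming = DEFAULT_TIMING,
    cr_rate: float = 0.40,
) -> SessionPlan:
    """Draw a constrained 100-trial schedule.

    Randomization runs in sets of 10 trials: each set holds 5 diluent
    trials, each of the 4 concentrations at least once, and one doubled
    concentration for the tenth slot. The doubled concentration is allocated
    in a balanced way across the 10 sets (each concentration doubled 2 or 3
    times), which yields the per-session presentation counts of 12-13.
    Correct-rejection reinforcement is pre-assigned at ``cr_rate``.

    The plan is a deterministic function of ``seed``.
    """
    concs = design.concentrations
    if len(set(concs)) != 4:
        raise ValueError("block design must have 4 distinct concentrations")
    rng = np.random.default_rng(seed)

    # balanced allocation of the per-set doubled concentration: 10 doublings
    # over 4 concentrations -> two concentrations doubled 3x, two doubled 2x
    counts = np.full(4, 2)
    counts[rng.choice(4, size=2, replace=False)] += 1
    doubled = np.repeat(np.arange(4), counts)
    rng.shuffle(doubled)

    trials: list[TrialSpec] = []
    index = 1
    for set_i in range(10):
        stimuli: list[float | None] = list(concs) + [concs[doubled[set_i]]]
        stimuli += [None] * 5
        order = rng.permutation(10)
        for j in order:
            trials.append(TrialSpec(index, stimuli[j]))
            index += 1

    plan = SessionPlan(
        trials=tuple(trials),
        intensity=int(intensity),
        block_index=design.block_index,
        concentrations=concs,
        timing=timing,
    )
    return assign_cr_reinforcement(plan, rate=cr_rate, seed=rng)


def assign_cr_reinforcement(
    plan: SessionPlan,
    rate: float = 0.40,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> SessionPlan:
    """Pre-assign reinforced correct rejections on diluent trials.

    Exactly ``round(rate * n_diluent)`` diluent trials are flagged, chosen
    uniformly at random. Correct alerts to the target are always reinforced
    and are not affected by this assignment.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"reinforcement rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    diluent_pos = [i for i, t in enumerate(plan.trials) if not t.is_target]
    n_flag = int(round(rate * len(diluent_pos)))
    flagged = set(rng.choice(diluent_pos, size=n_flag, replace=False).tolist()) if n_flag else set()
    new_trials = tuple(
        replace(t, cr_reinforced=(i in flagged)) for i, t in enumerate(plan.trials)
    )
    return replace(plan, trials=new_trials)


# ---------------------------------------------------------------------------
# trial state machine


def _validate_pokes(pokes: Sequence[PokeEvent]) -> None:
    prev_end = -np.inf
    for p in pokes:
        if p.duration_s <= 0:
            raise ValueError("poke duration must be > 0")
        if p.onset_s < prev_end - _EPS:
            raise ValueError("pokes must be sorted and non-overlapping")
        prev_end = p.end_s


def score_trial(
    spec: TrialSpec,
    pokes: Sequence[PokeEvent],
    timing: TrialTiming = DEFAULT_TIMING,
    start_s: float = 0.0,
) -> TrialResult:
    """Score one trial with the Go/no-go state machine.

    An alert is declared at the first instant a single continuous poke
    reaches the 0.4 s criterion inside the active window; its time on the
    odor-onset clock is the latency. A poke starting inside the active
    window before any extension has been used arms one 10 s extension
    (window never exceeds 20 s by default). Diluent trials run the same
    machine, so a sub-criterion poke extends them identically. With no alert
    by window end the trial is an all-clear; latency is censored at the
    nominal 10 s window.

    Alerts terminate the trial (hit or false alert); otherwise the trial
    runs to the window end. ``end_s`` excludes the following ITI.
    """
    _validate_pokes(pokes)
    window = timing.window_s
    extensions = 0
    alert_t: float | None = None
    for p in pokes:
        if p.onset_s >= window - _EPS:
            break  # poke starts after the active window closed
        if extensions < timing.max_extensions:
            # the olfactometer arms the extension when a poke begins: a poke
            # still sub-criterion at window close would otherwise be cut off
            window += timing.extension_s
            extensions += 1
        if p.duration_s >= timing.poke_criterion_s - _EPS:
            t = p.onset_s + timing.poke_criterion_s
            if t <= window + _EPS:
                alert_t = t
                break

    if alert_t is not None:
        outcome = "hit" if spec.is_target else "false_alert"
        latency = alert_t
        end = start_s + alert_t
    else:
        outcome = "miss" if spec.is_target else "correct_rejection"
        latency = timing.window_s
        end = start_s + window

    if outcome == "hit":
        reinforced = True
    elif outcome == "correct_rejection":
        reinforced = spec.cr_reinforced
    else:
        reinforced = False

    return TrialResult(
        trial_index=spec.trial_index,
        outcome=outcome,
        latency_s=latency,
        reinforced=reinforced,
        start_s=start_s,
        end_s=end,
    )


def run_session(
    plan: SessionPlan,
    dog,
    seed: int | np.random.Generator | np.random.SeedSequence,
) -> SessionResult:
    """Run a full session of a simulated subject through the state machine.

    The session clock accumulates trial durations plus ITIs; the elapsed
    time (minutes since the first odor onset) is passed to the subject model
    on every trial so duration-dependent sensitivity decay acts within the
    session.
    """
    from . import dog as dog_mod  # local import: avoid cycle at import time

    rng = np.random.default_rng(seed)
    clock = 0.0
    results: list[TrialResult] = []
    all_pokes: list[tuple[PokeEvent, ...]] = []
    for spec in plan.trials:
        pokes = dog_mod.sample_response(
            dog, spec, plan.intensity, elapsed_min=clock / 60.0, seed=rng
        )
        res = score_trial(spec, pokes, plan.timing, start_s=clock)
        results.append(res)
        all_pokes.append(tuple(pokes))
        clock = res.end_s + plan.timing.iti_s
    return SessionResult(plan=plan, results=tuple(results), pokes=tuple(all_pokes))


# ---------------------------------------------------------------------------
# stopping rule


def stop_rule(
    hit_rates: Mapping[tuple[float, int], float] | pd.DataFrame,
    inclusive: bool = True,
) -> bool:
    """Decide whether threshold testing stops after a block.

    ``hit_rates`` maps (concentration, intensity) to the pooled hit rate, or
    is a DataFrame with columns ``concentration_vv``, ``intensity_kmh`` and
    ``hit_rate``. Testing stops once any concentration at either intensity
    falls to a hit rate <= 0.5 (inclusive by default; set
    ``inclusive=False`` for a strict < 0.5 rule). Every concentration must
    be present at both intensities.
    """
    if isinstance(hit_rates, pd.DataFrame):
        table = {
            (row.concentration_vv, int(row.intensity_kmh)): row.hit_rate
            for row in hit_rates.itertuples()
        }
    else:
        table = dict(hit_rates)
    concs = sorted({c for c, _ in table})
    intensities = sorted({i for _, i in table})
    if len(intensities) < 2:
        raise ValueError("hit rates must cover both exercise intensities")
    for c in concs:
        for i in intensities:
            if (c, i) not in table or pd.isna(table[(c, i)]):
                raise ValueError(f"missing hit rate for concentration {c} at {i} km/h")
    rates = np.array(list(table.values()), dtype=float)
    return bool((rates <= 0.5).any()) if inclusive else bool((rates < 0.5).any())
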