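"""Independent reference implementations used only by the tests.

These deliberately share no code with the package: the trial oracle is a
literal 1 ms time-stepped simulation of the response-window logic, and the
A' oracle is the geometric one-point ROC construction (mean of the areas
under the two extreme proper ROC curves through (F, H)) rather than the
closed-form index.
"""

from __future__ import annotations

import numpy as np

CRIT_MS = 400
WINDOW_MS = 10_000
EXT_MS = 10_000


def streams_to_activity(streams, t_max_ms: int) -> np.ndarray:
    """Boolean activity matrix (stream x ms) from integer-ms poke lists."""
    act = np.zeros((len(streams), t_max_ms), dtype=bool)
    for i, pokes in enumerate(streams):
        for onset, dur in pokes:
            act[i, onset : min(onset + dur, t_max_ms)] = True
    return act


def brute_force_alerts(streams, t_max_ms: int = 23_000) -> np.ndarray:
    """Step the window/extension state machine at 1 ms for many poke streams.

    ``streams`` is a list of poke lists [(onset_ms, duration_ms), ...].
    Returns alert times in ms (-1 for no alert). Semantics: a poke beginning
    inside the initial 10 s window arms a single 10 s extension; an alert
    fires at the first instant a continuous poke reaches 0.4 s, provided
    that instant is no later than the (possibly extended) window end.
    """
    act = streams_to_activity(streams, t_max_ms)
    n = act.shape[0]
    run = np.zeros(n, dtype=np.int32)
    window = np.full(n, WINDOW_MS, dtype=np.int32)
    extended = np.zeros(n, dtype=bool)
    alert = np.full(n, -1, dtype=np.int32)
    prev = np.zeros(n, dtype=bool)
    for t in range(t_max_ms):
        a = act[:, t]
        live = alert < 0
        rising = a & ~prev & live
        if t < WINDOW_MS:
            arm = rising & ~extended
            window[arm] += EXT_MS
            extended[arm] = True
        run = np.where(a, run + 1, 0)
        fire = live & (run == CRIT_MS) & (t + 1 <= window)
        alert[fire] = t + 1
        prev = a
    return alert


def a_prime_roc_area(h: float, f: float) -> float:
    """A' as the mean area under the two extreme proper one-point ROCs."""
    if h == f:
        return 0.5
    if h < f:
        return 1.0 - a_prime_roc_area(f, h)
    # curve (a): chance line steepened through (F, H), saturating at 1
    area_a = 1.0 if f == 0 else 1.0 - f / (2.0 * h)
    # curve (b): vertical jump at x = 0, then the line through (F,H)-(1,1)
    y0 = h - f * (1.0 - h) / (1.0 - f) if f < 1 else h
    area_b = (y0 + 1.0) / 2.0
    return 0.5 * (area_a + area_b)


def random_poke_streams(rng: np.random.Generator, n: int, max_pokes: int = 4):
    """Random sorted, non-overlapping integer-ms poke streams."""
    streams = []
    for _ in range(n):
        k = int(rng.integers(0, max_pokes + 1))
        onsets = np.sort(rng.integers(0, 21_000, size=k))
        durs = rng.integers(10, 1_500, size=k)
        pokes = []
        prev_end = -2
        for o, d in zip(onsets, durs):
            if o >= prev_end + 2:  # keep pokes clearly separated on the grid
                pokes.append((int(o), int(d)))
                prev_end = o + d
        streams.append(pokes)
    return streams
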