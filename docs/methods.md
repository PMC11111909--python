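# Methods

This note documents the models, numerical conventions and design choices
behind `olfex`, and what the synthetic-subject pipeline does and does not
establish about real animals.

## The paradigm

A subject performs 100-trial Go/no-go sessions while exercising on a
treadmill at 4 km/h (low intensity, a walk) or 8 km/h (moderate intensity,
a trot). Half the trials present the diluent (mineral oil) headspace, half
present one of four half-log serial dilutions of the target odorant. A
continuous nose poke of ≥ 0.4 s within the response window is an alert
(Go); 10 s without one is an all-clear (No-go). Testing proceeds in blocks
of four sessions (two per intensity, counterbalanced 8-4-8-4 / 4-8-4-8)
over descending concentration ranges spanning 1.5 log₁₀ units each, with
one overlapping concentration between blocks so the subject always has a
detectable stimulus; the first block runs 10⁻² … 10⁻³·⁵ v/v. After each
block the two sessions per intensity are pooled; once any concentration at
either intensity shows a hit rate ≤ 0.5, that concentration is the
detection threshold and testing stops.

## Trial state machine

Scoring is event-driven and exact; its conventions are:

- **Alert instant.** The alert fires at the first instant a *single*
  continuous poke reaches the 0.4 s criterion inside the active window;
  latency is that instant on the odor-onset clock. Criterion time does not
  accumulate across separate pokes.
- **Extension arming.** A poke *beginning* inside the initial 10 s window
  arms one 10 s extension (active window never exceeds 20 s). Arming at
  poke onset rather than poke end means a poke straddling the window close
  is not cut off: onset 9.8 s, duration 0.2 s followed by a poke at 14.0 s
  yields an alert at 14.4 s. One extension only by default
  (`TrialTiming.max_extensions`); pokes during the extension do not extend
  again.
- **Diluent trials run the same machine**, so a sub-criterion poke extends
  a no-go trial identically; go and no-go share one code path.
- **Censoring.** Non-responses carry a latency of exactly 10 s (the
  nominal window) regardless of extension. Responses keep their true alert
  time, which can exceed 10 s inside an extended window.
- **Session clock.** Trial start is odor-valve activation; an alert
  terminates the trial, otherwise it runs to window end; a 10 s ITI
  follows every trial. Reported session duration runs from the first odor
  onset to the last trial's end (trailing ITI and the 2-min treadmill
  warm-up excluded). Boundary comparisons use a 1 ns tolerance so
  grid-aligned event times are classified deterministically.

The suite validates the scorer against an independent, literal 1 ms
time-stepped simulation of these rules on 10,000 random poke streams
(agreement in outcome and latency to 1 ms).

## Constrained randomization

Within each disjoint set of ten trials: five diluent trials, each of the
four concentrations at least once, and one concentration doubled to fill
the tenth slot. The doubled concentration is allocated in a balanced way
across the ten sets — two concentrations doubled three times, two doubled
twice, assignment and order drawn from a seeded generator — which is the
only allocation consistent with per-session presentation counts of 12–13.
Exactly 20 of the 50 diluent trials (40%) are pre-assigned reinforced
correct rejections. All randomness flows through
`numpy.random.Generator`/`SeedSequence`; identical seeds give
byte-identical datasets.

## Signal detection

A′ and B″ are the standard non-parametric indices:

    A′  = 0.5 + sgn(H−F)·[(H−F)² + |H−F|] / [4·max(H,F) − 4HF]
    B″  = sgn(H−F)·[H(1−H) − F(1−F)] / [H(1−H) + F(1−F)]

Conventions and degenerate cases:

- H = F (including both 0 or both 1, where the A′ ratio is 0/0) → A′ = 0.5.
- Because of the sgn(H−F) prefactor, both indices are *invariant* under
  swapping H and F up to A′'s complement identity A′(F,H) = 1 − A′(H,F);
  B″(F,H) = B″(H,F). B″'s sign encodes direction (negative = go bias,
  positive = no-go bias), its magnitude the strength.
- Extreme rates (0 or 1) make B″ undefined and pin A′ to its bounds; the
  standard 1/(2N) adjustment (0 → 1/(2N), 1 → 1 − 1/(2N)) is applied
  before the formulas by `outcome_rates` (default on, configurable). It is
  required in practice: total late-session collapse produces H = 0 cells.
- Diluent trials are not concentration-specific, so every concentration
  cell at an intensity shares that intensity's pooled false-alert rate.
- When both sessions of an intensity are pooled, trials are pooled before
  rates are computed (not averaged rates), because per-session
  concentration counts are unequal (12 vs 13).

A′ is cross-checked against an independent geometric oracle: the mean of
the areas under the two extreme proper one-point ROC curves through
(F, H), which equals the closed form to numerical precision.

## Threshold and dilution steps

The detection threshold is the first concentration, descending, with a
hit rate ≤ 0.5 (inclusive; configurable to strict <). The determining
intensity defaults to "either", matching the stopping rule; when both
intensities qualify at the threshold concentration the moderate intensity
is recorded as the trigger (the condition under which thresholds are
reached first). If no concentration qualifies the result is an explicit
"not reached" — no value is fabricated. Dilution steps are
log₁₀(c / threshold): 0 at threshold, +0.5 per half-log step; note that a
printed concentration like 0.00316 is a rounded 10⁻²·⁵, so its step score
is 0.49969…, i.e. 0.5 at printed precision.

## The synthetic subject

`DogModel` generates behavior, not physiology. Defaults describe an
illustrative subject loosely matched to the printed summary statistics of
the study this paradigm models; they are not fits to any animal.

| parameter | default | units | rationale |
|---|---|---|---|
| `mu0` | −5.4 | log₁₀ v/v | resting midpoint ~0.4 log below a block-2 floor, so the lowest tested concentration is detected at ≈ 0.87 at rest |
| `sigma` | 0.35 | log₁₀ | steep threshold slope typical of liquid-dilution psychometric functions (most of the transition inside one half-log step) |
| `lapse` | 0.02 | — | printed training-criterion miss proportion 0.02 ± 0.01 |
| `guess` | 0 | — | lower asymptote; diluent responding is modeled separately |
| `fa_rate_low/mod` | 0.07 / 0.03 | per trial | overall false-alert proportion ≈ 0.05 ± 0.02 split to give a go bias at low and a no-go bias at moderate intensity |
| `decay_rate` | 0.1 | log₁₀/min | with onset 10 min: near-ceiling detection in the first 10 min, ≈ 50% in the 10–20 min range, ≈ 0 past 20 min at a near-threshold concentration |
| `decay_onset_min` | 10 | min | duration before any moderate-intensity impairment |
| `latency_base_s`, `latency_conc_slope`, `latency_intensity_offset_s` | 0.8, 0.6, 1.0 | s, s/log₁₀, s | hit latencies ≈ 2 s at high concentrations rising to ≈ 4–5 s near threshold, ~1 s slower at a trot; reproduces printed mean session durations of ≈ 29 min (observed 28.4 ± 1.6 over 12 seeded sessions) |
| `latency_noise_sd` | 0.3 | log | mean-preserving multiplicative log-normal noise, truncated to [0.4, 10] s |
| `hr_mean_low/mod`, `hr_sd`, `hr_ar` | 95.9 / 121.2, 6.6, 0.9 | bpm, bpm, — | printed steady-state means; one SD field (the larger printed low-intensity SD mixes between-subject variance) |

Model structure and the choices behind it:

- **Sigmoid family**: cumulative Gaussian in log₁₀ concentration
  (standard psychophysics); logistic available via `sigmoid="logistic"`.
- **Decay form**: linear midpoint elevation after onset, gated to 8 km/h —
  the simplest form consistent with intensity-indistinguishable
  performance in the first 10 min and collapse by 20–30 min. A saturating
  exponential with matched initial slope is available
  (`decay_form="exponential"`, time constant `decay_tau_min`). The decay
  clock starts at the first odor onset (not the warm-up), since exercise
  duration is what the time-binned analyses plot.
- **False alerts** depend on intensity but not concentration: response
  bias is approximately constant across dilutions but shifts with speed.
  Diluent-alert latencies are drawn at the resting midpoint concentration
  (there is no dilution to time against); this choice only affects
  false-alert latencies, which enter no summary.
- **Latency noise family**: the underlying study reports no latency
  distribution; a truncated log-normal is our choice (positive, skewed,
  mean-preserving before truncation).
- **Heart rate** is a stationary AR(1) with innovation SD
  hr_sd·√(1−ar²), i.e. marginal SD `hr_sd` — steady-state exercise with
  persistent fluctuations; no warm-up ramp or drift is modeled.

What the generator does *not* emulate: within-subject day-to-day
variability, motivational drift and satiation, odor-port approach
dynamics (pokes are single rectangular events at the sampled latency),
panting/sniffing mechanics, thermoregulation, and any recovery of
sensitivity after exercise ends. Passing tests therefore show that the
*pipeline* — scheduling, scoring, summaries, threshold logic — behaves
correctly and recovers known generating parameters; they are not evidence
about real dogs.

## PID calibration

- **Filter**: Butterworth low-pass at `cutoff_scalar` × Nyquist (0.01,
  i.e. 2.5 Hz at 500 Hz sampling). The order is unspecified upstream; we
  use order 2 applied forward-backward (`filtfilt`) for zero phase, so
  valve transitions keep their timing; traces must exceed the filter
  warm-up length.
- **Cycle deltas**: one ΔV per valve on/off cycle, mean(on) − mean(off),
  with the off mean acting as a per-cycle baseline so slow drift largely
  cancels. The first `settle_s` = 5 s after *each* valve transition is
  excluded (rise and decay transients; windows shorter than the settle
  time are used whole). A final on-run with no off samples is dropped with
  a log message. Negative deltas are reported, never clipped — they
  diagnose baseline drift.
- **Distance model**: OLS of ΔV on log₁₀ distance, per-cycle points by
  default (`aggregate="per_distance"` averages within distance first);
  needs ≥ 3 distinct distances. Slope/intercept standard errors come from
  the regression; the suite checks ~95% CI coverage over seeded fixtures.
- **Calibration curve**: linear in log₁₀ liquid dilution by default, with
  a monotone isotonic alternative (`method="isotonic"`, via PAVA) for
  saturating responses; inversion is refused outside the fitted ΔV range
  (no extrapolation).
- The synthetic trace generator produces square waves with first-order
  exponential edges, linear drift and Gaussian noise on the stated
  protocol (45 s on / 60 s off, 10 cycles, 500 Hz); tests run a
  time-scaled version (5 s / 5 s at 100 Hz) where only the geometry, not
  the protocol duration, matters.

## Problem sizes and runtime choices

The default suite exercises: 1,000 seeded sessions for the scheduler
guarantees, 10,000 poke streams against the 1 ms oracle, 1,000 random
(H, F) pairs against the ROC oracle, 2 × 50 seeded full studies for
threshold recovery (decay off) and for the moderate-intensity-first
ordering (decay on), 100 paired sessions for the decay-specificity sign
test, and 200 seeded regressions for CI coverage. These sizes keep the
full suite under a minute on one core while leaving binomial noise well
inside the asserted margins.

## Known limitations

- The threshold estimate is grid-limited to half-log resolution and, at
  8 km/h, reflects a session-averaged (duration-dependent) sensitivity,
  not an instantaneous one.
- Statistical inference (hypothesis tests, mixed models across subjects)
  is out of scope; the upstream design is n = 3 and explicitly
  descriptive.
- Hardware control (valves, IR sensors, treadmill, HR straps) and
  training-phase shaping schedules are not modeled; the package consumes
  and produces event logs only.
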