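# olfex

Olfactory Go/no-go detection thresholds under treadmill exercise.

Working dogs often have to detect trace odorants *while* physically
working, yet olfactory thresholds are almost always measured at rest.
`olfex` implements the analysis and simulation pipeline for an
olfacto-treadmill paradigm in which a dog exercises on a treadmill at a low
(4 km/h, walk) or moderate (8 km/h, trot) intensity while performing
100-trial Go/no-go liquid-dilution threshold sessions against an
olfactometer: nose-poking an odor port for at least 0.4 s within a 10 s
window signals "odor present"; withholding for 10 s signals "all clear".
Blocks of four sessions descend through half-log (10⁻⁰·⁵) dilution steps
until the hit rate at some concentration falls to 0.5 or below — that
concentration is the dog's detection threshold under that exercise
condition.

The package provides, with no external data required:

- **`olfex.session`** — the constrained stimulus randomizer (sets of ten
  trials: five diluent, every concentration at least once, balanced
  doubling, so each concentration appears 12–13 times per session) and the
  trial-scoring state machine (0.4 s poke criterion, 10 s window, single
  10 s extension after a sub-criterion poke, 10 s inter-trial interval).
- **`olfex.dog`** — a generative subject model: per-trial hit probability
  is a psychometric function of log₁₀ concentration,

  p(c, t) = γ + (1 − γ − λ) · Φ((log₁₀ c − μ(t)) / σ),

  whose midpoint μ(t) = μ₀ + r · max(0, t − t₀) · 1[8 km/h] rises with
  exercise duration at moderate intensity only; plus censored response
  latencies, intensity-dependent false-alert rates, and AR(1) steady-state
  heart rate.
- **`olfex.psychometrics`** — hit/false-alert rates, latency censoring at
  10 s, non-parametric signal detection indices

  A′ = ½ + sgn(H−F) · [(H−F)² + |H−F|] / [4·max(H,F) − 4HF],
  B″ = sgn(H−F) · [H(1−H) − F(1−F)] / [H(1−H) + F(1−F)],

  descending-series threshold determination, dilution-step rescaling
  log₁₀(c / threshold), 25-trial and 10-minute binning, and per-trial
  heart-rate averaging.
- **`olfex.pid`** — photoionization-detector odor-delivery validation:
  zero-phase Butterworth low-pass at 0.01 × Nyquist, per-cycle valve-off
  baseline subtraction, ΔV = a·log₁₀(distance) + b regression, and a
  calibration curve with inverse concentration estimation.
- **`olfex.cli`** — `olfex simulate | analyze | calibrate-pid | report`.

## Worked example

Simulate a full study with the default subject (resting midpoint
μ₀ = −5.4 log₁₀ v/v, decay 0.1 log₁₀/min after 10 min at 8 km/h) and
analyze it:

```python
from olfex import DogModel, generate_study
from olfex.io import sessions_to_frame
from olfex.psychometrics import outcome_rates

study = generate_study(DogModel(), seed=42)
print(study.stopped_block)                      # 2
thr = study.threshold
print(f"{thr.threshold_concentration:.3g} v/v at {thr.intensity} km/h")
# 1e-05 v/v at 8 km/h
print(study.block_tables[-1].to_string(index=False))
```

```
 concentration_vv  intensity_kmh  hit_rate  n_trials
         0.000316              4  0.958333        24
         0.000316              8  0.960000        25
         0.000100              4  1.000000        26
         0.000100              8  0.680000        25
         0.000032              4  0.920000        25
         0.000032              8  0.720000        25
         0.000010              4  0.960000        25
         0.000010              8  0.280000        25
```

The study stops after block 2 (concentrations 10⁻³·⁵ … 10⁻⁵ v/v): at
10⁻⁵ the pooled hit rate at 8 km/h has fallen to 0.28, while the same
concentration at 4 km/h is still detected at 0.96 — the dog reaches
threshold under moderate exercise while remaining above threshold at a
walk. Signal detection on the last block shows the same dissociation as a
bias-free sensitivity loss:

```python
summary, sdt = outcome_rates(sessions_to_frame(study.sessions[-4:]))
```

At 4 km/h A′ stays ≥ 0.94 at every concentration with B″ ≈ −0.1 … −0.7
(a go bias: more false alerts), whereas at 8 km/h A′ falls to 0.78 at the
lowest concentration with B″ ≈ +0.7 (a no-go bias: misses), so the
moderate-intensity decrement is a sensitivity change, not merely a
response-criterion shift.

The same pipeline from the shell:

```sh
olfex simulate --config examples/study.yaml --seed 42 --out data/
olfex analyze --data data/ --out analysis/
olfex report --data analysis/
```

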