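# Full study configuration: a simulated subject, the descending-block
# design, trial timing, and analysis options. All fields are required.
analysis:
  determining_intensity: either
  hr_offset_s: 0.0
  sdt_correction: true
dog:
  decay_form: linear
  decay_onset_min: 10.0
  decay_rate: 0.1
  decay_tau_min: 10.0
  fa_rate_low: 0.07
  fa_rate_mod: 0.03
  guess: 0.0
  hr_ar: 0.9
  hr_mean_low: 95.9
  hr_mean_mod: 121.2
  hr_sd: 6.6
  lapse: 0.02
  latency_base_s: 0.8
  latency_conc_slope: 0.6
  latency_intensity_offset_s: 1.0
  latency_noise_sd: 0.3
  mu0: -5.4
  sigma: 0.35
  sigmoid: gaussian
seed: 0
study:
  cr_reinforcement_rate: 0.4
  first_top_concentration: 0.01
  max_blocks: 3
  stop_rule_inclusive: true
timing:
  extension_s: 10.0
  iti_s: 10.0
  max_extensions: 1
  poke_criterion_s: 0.4
  window_s: 10.0
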