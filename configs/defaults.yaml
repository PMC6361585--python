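# Default analysis configuration.
#
# The response windows are the pipeline's core analytic commitments:
# reward-cue responses are scored 200-400 ms post-onset, phasic aversive
# responses 0-100 ms, putative-dopamine (pDA) typing 0-200 ms, ramping
# typing 200-2000 ms, and pDA aversive inhibition 100-500 ms. Sustained
# stimuli use 5 min bins against a 15 min baseline with stimulus-specific
# initial/rebound phase windows (see rmtg_valence.response_stats).

seed: 0
alpha: 0.05
normalization: zscore      # or "fold"
output_dir: null

windows:                    # seconds post-onset
  reward_cue: [0.2, 0.4]
  neutral_tone: [0.0, 0.1]
  footshock: [0.0, 0.1]
  siren: [0.0, 0.1]
  bright_light: [0.0, 0.1]
  pda: [0.0, 0.2]
  ramping: [0.2, 2.0]
  aversive_inhibition: [0.1, 0.5]

phasic:
  bin_width_s: 0.05
  baseline_s: 1.0
  n_reward_trials: 50
  n_aversive_trials: 30
  trial_interval_s: 30.0
  baseline_rate_hz: 10.0
  gain_excite: 3.0
  gain_inhibit: 0.2
  gain_scale_sd: 0.4   # shared per-unit magnitude factor across stimuli
  population:
    valence_encoding: 8
    aversive_only: 4
    reward_inhibited_only: 3
    unresponsive: 5

sustained:
  stimulus: licl
  baseline_min: 15.0
  population:
    licl_biphasic: 8
    saline: 8

cpp:
  n_animals: 8
  bias_pre: 0.5
  bias_post: 0.3
  mean_dwell_s: 20.0
  session_length_s: 900.0
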