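# Demo configuration for `betaadapt run --config examples/run_config.yaml`.
# Omitted fields fall back to the documented defaults (docs/methods.md).
mode: human
seed: 7
task:
  n_baseline: 200
  n_adaptation: 200
  n_washout: 200
  rotation_deg: 30.0
adaptation:
  retention: 0.98
  learning_rate: 0.10
  motor_noise_sd_deg: 4.0
neural:
  fs_raw: 1000.0        # reduced from the 2500 Hz acquisition default for speed
  beta_epoch_gain:
    EA: 0.8             # the emulated early-adaptation amplitude drop
window:
  mode: reaction_time
n_boot: 1000
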