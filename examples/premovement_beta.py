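"""From a coupled synthetic EEG recording to the per-trial pre-movement
beta statistic.

The chain is: Hjorth Laplacian at C3 -> 30 Hz low-pass, resample to 500 Hz,
10 Hz high-pass -> 2 s windows centred on movement initiation, z-scored ->
Morlet (omega0 = 6) log power on a 15-25 Hz grid -> mean over each trial's
reaction-time interval.  The generator injects an amplitude gain of 0.8 on
the early-adaptation (EA) epoch, i.e. a true log-power deficit of
2 ln 0.8 = -0.446.
"""

import numpy as np

from betaadapt import (
    AdaptationParams,
    PreMovementWindowSpec,
    TaskConfig,
    extract_windows,
    filter_chain,
    hjorth_laplacian,
    premovement_beta,
    simulate_behavior,
    simulate_recording,
    transform_windows,
    zscore_window,
)
from betaadapt.synth import default_human_neural_config

task = TaskConfig(n_baseline=100, n_adaptation=100, n_washout=100, epoch_len=36)
trials, _ = simulate_behavior(task, AdaptationParams(), seed=2)
neural = default_human_neural_config(fs_raw=1000.0)  # reduced rate for speed
rec, truth = simulate_recording(trials, neural, seed=3)
print(f"recording: {rec.samples.shape[0]} channels x {rec.duration_s:.0f} s "
      f"at {rec.fs:.0f} Hz")

lap = hjorth_laplacian(rec, "C3")
filtered, fs = filter_chain(lap, rec.fs)
windows = [zscore_window(w) for w in extract_windows(filtered, fs, rec.events)]
tf = transform_windows(windows)
beta = premovement_beta(tf, trials, PreMovementWindowSpec(mode="reaction_time"))
trials["beta_logpower"] = trials["trial_index"].map(beta)

means = trials.groupby("epoch", sort=False)["beta_logpower"].mean()
print("\nmean pre-movement beta log-power by epoch:")
print(means.round(3))
deficit = means["EA"] - means["Baseline"]
print(f"\nEA - Baseline: {deficit:+.3f} log-power units "
      f"(injected 2 ln 0.8 = {2 * np.log(0.8):+.3f}; the z-scored window "
      "normalisation absorbs a small part of the injected change)")
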