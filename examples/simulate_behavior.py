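"""Simulate one human joystick adaptation session and summarise the
behavioural curve.

A 200/200/200 baseline/rotation/washout session is generated with the
single-rate learner.  Expect: an initial endpoint error near the full 30
degree rotation (clockwise = negative), exponential decay to a small
asymptote, and a sign-reversed "negative aftereffect" when the rotation is
removed.
"""

import numpy as np

from betaadapt import AdaptationParams, TaskConfig, simulate_behavior

trials, truth = simulate_behavior(TaskConfig(), AdaptationParams(), seed=1)

adapt = trials.loc[trials.phase == "adaptation", "endpoint_error_deg"]
wash = trials.loc[trials.phase == "washout", "endpoint_error_deg"]

print(f"trials generated:            {len(trials)}")
print(f"first adaptation error:      {adapt.iloc[0]:+.2f} deg  (rotation is 30 deg clockwise)")
print(f"asymptote (last 10 trials):  {adapt.iloc[-10:].abs().mean():.2f} deg")
print(f"first washout error:         {wash.iloc[0]:+.2f} deg  (negative aftereffect: sign flips)")
print(f"final washout (last 10):     {wash.iloc[-10:].mean():+.2f} deg  (back to baseline)")
print(f"internal state at block end: {truth.state_deg[399]:.2f} deg of the 30 deg rotation learned")
print()
print(trials.groupby("epoch", sort=False)["endpoint_error_deg"].mean().round(2))
print("per-epoch mean endpoint error (deg); EA is large and clockwise, "
      "EAft is the counterclockwise aftereffect.")
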