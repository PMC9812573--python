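"""Run the target achievement control (TAC) test on a decoded trajectory.

The TAC test asks the decoded hand to reach each target posture within
+/-5 degrees on all three DOFs simultaneously and hold it for 0.5 s,
within a 30 s trial.  Here a scripted ideal trajectory demonstrates the
state machine; example 05 decodes one from synthetic EMG end to end.
"""

import numpy as np

import myodecode as md

config = md.TACConfig.trial("TAC-1")
print("postures:", [(n, t) for n, t in config.postures])

# trajectory that travels 1 s to each target and holds it 2 s
truth = md.render_posture_sequence(
    [t for _, t in config.postures], hold_s=2.0, travel_s=1.0,
    rate=120.0, min_total_s=31.0,
)
result = md.tac_evaluate(truth, config)
bp, cr = md.completion_rate_curve(result, config)

for name, ok, t in zip(result.posture_names, result.achieved, result.completion_times):
    print(f"  {name:10s} achieved={ok} completion={t if t is None else round(t, 2)} s")
print("trial ended at", round(result.trial_end, 2), "s")
print("completion rate at 30 s:", md.completion_rate_at(30.0, bp, cr))
# Each posture completes 0.5 s (the dwell time) after the hand settles
# inside the tolerance box; CR(t) steps by 1/4 per completed posture.
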