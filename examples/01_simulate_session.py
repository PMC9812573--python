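"""Generate a synthetic recording session: EMG, angles, and an MVC burst.

A motion script drives a 3-DOF wrist/hand trajectory; six virtual muscles
(one agonist/antagonist pair per DOF) modulate a 32-channel white-noise
carrier through a nonnegative synergy mixing matrix.
"""

import myodecode as md

script = md.MotionScript.from_pairs(
    [("M0", 1.0), ("M1", 2.0), ("M0", 1.0), ("M5", 2.0), ("M0", 1.0)]
)
synergy = md.default_synergy_model(seed=0)

angles, emg = md.simulate_session(script, synergy, seed=42)
mvc = md.synthesize_mvc(synergy, duration=5.0, seed=43)

print(f"script duration: {script.total_duration:.1f} s")
print(f"angle stream: {angles.angles.shape[0]} samples at {angles.rate:.0f} Hz")
print(f"EMG stream:   {emg.samples.shape[0]} samples x {emg.samples.shape[1]} channels at {emg.rate:.0f} Hz")
print(f"MVC burst:    {mvc.samples.shape[0]} samples")
print(f"peak wrist flexion angle: {angles.angles[:, 0].max():.1f} deg (target 30)")
# The EMG is zero-mean noise whose per-channel amplitude follows muscle
# activation; the angle stream is the motion-capture ground truth.
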