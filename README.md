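# myodecode

Real-time decoding of wrist and hand joint angles from multichannel surface
EMG (sEMG), end to end and fully replayable: no acquisition hardware needed.

Myoelectric prostheses are usually driven by motion *classification*; this
package implements the alternative — continuous *regression* of three
degrees of freedom (DOF1 wrist flexion/extension, DOF2 pronation/supination,
DOF3 hand grip) from a 32-channel electrode sleeve sampled at 500 Hz. It is
aimed at researchers in myoelectric control who want a tested reference
pipeline they can run, probe, and extend from Python.

## The pipeline

1. **Envelope extraction.** Each 120 ms sliding window (60 samples × 32
   channels) is rectified and low-pass FIR filtered to an integrated-EMG
   (IEMG) envelope, then min–max normalized per channel against a maximum
   voluntary contraction (MVC) recording:

       IEMG_i     = filter(|EMG_i|)
       IEMGnorm_i = (IEMG_i − min IMVC_i) / (max IMVC_i − min IMVC_i)

2. **Channel-wise CNN regression.** Six temporal filters of length 60 are
   applied channel-wise, compressing each channel's time axis to one value
   per filter — a 6 × 32 "force pattern" map, flattened to 192 features and
   mapped by a fully connected layer to the 3 joint angles (degrees).
   Trained with MSE/Adam; k-fold cross-validation grouped by trial.

3. **Adaptive Kalman smoothing.** One scalar filter per DOF,

       K(k) = P(k−1)/(P(k−1)+R),  x(k) = x(k−1) + K(k)(z(k) − x(k−1)),
       P(k) = (1−K(k))P(k−1) + Q,

   with Q, R adapted online as running means of innovation-based variance
   estimates (initial Q = 0.05, R = 0.4 deg²).

4. **Session transfer.** On a new day the sleeve sits differently; the
   convolutional layer is frozen bit-exactly and only the fully connected
   layer is retrained on a few new trials ("layer transfer").

5. **Evaluation.** Pearson correlation per DOF and per motion class,
   one-way ANOVA stability check of per-minute computational latency, and
   the target achievement control (TAC) test: reach each target posture
   within ±5° on all three DOFs simultaneously and hold 0.5 s, within a
   30 s trial, summarized by the completion-rate curve CR(t).

A synthetic-data module stands in for the hardware: scripted daily motions
(M0 rest through M13 triple-mixture) drive six virtual muscles whose
activations modulate a 32-channel noise carrier through a nonnegative
synergy mixing matrix, plus MVC burst recordings — all seeded and
reproducible.

## Worked example

```python
import myodecode as md
from myodecode.model import TrainingConfig
from myodecode.pipeline import run_two_day_experiment

exp = run_two_day_experiment(seed=7, n_initial_trials=3, n_transfer_trials=5,
                             initial_config=TrainingConfig(folds=3, seed=7))
print(exp.initial_report.mean_cc.round(4))
print(exp.stale_cc.round(4))
print(exp.transferred_cc.round(4))
```

prints (exactly, for this seed):

```
[0.9823 0.9834 0.9746]
[0.923  0.8551 0.9247]
[0.9844 0.9828 0.9763]
```

Reading: cross-validated correlation per DOF is ≈0.98 on day-1 data; the
stale day-1 model drops (to 0.86 on pronation/supination) on day-2 data
where the sleeve is rotated and gains have drifted; retraining only the
fully connected layer restores all three DOFs to ≈0.98 — with the
convolutional filters untouched.

The `examples/` directory has one short script per capability: session
simulation, training + transfer, real-time replay with latency logging,
the TAC test, and Kalman adaptation. A thin CLI mirrors the same steps
(`myodecode simulate / train / transfer / run / evaluate / tac /
latency-check`).

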