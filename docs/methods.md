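# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `myodecode`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Signal model and envelope extraction

Raw sEMG is modeled per channel as a zero-mean carrier amplitude-modulated
by a nonnegative envelope proportional to muscle activation. The envelope
is recovered by full-wave rectification followed by a causal low-pass FIR
filter ("integrated EMG", IEMG). The default filter is a linear-phase
windowed-sinc low-pass, **cutoff 3 Hz at 500 Hz sampling, 101 taps, unit DC
gain**. The published system used a lab-specific filter whose coefficients
are not available; ours is a documented stand-in with the same role, and
coefficients are loadable from config. Note the group delay is 50 samples
(100 ms) — envelope estimates lag muscle activity accordingly.

Normalization maps each channel's IEMG onto [0, 1] via the min and max of
the filtered MVC recording for that channel, then clips. Clipping is
needed because live activation can exceed the recorded MVC; the regressor
was trained on inputs in [0, 1]. The min/max are taken over the settled
region only (after one filter length), avoiding the cold-start transient.

Streaming contract: filtering a long recording window by window with
carried state is **bit-identical** to filtering it in one shot. The filter
is therefore implemented as an explicit raw-input delay line whose
per-sample dot products are the same arithmetic in both modes (generic
IIR routines reassociate differently across chunk boundaries at the
10⁻¹⁶ level, which would break replay determinism guarantees).

## CW-CNN regressor

Input is one normalized window W ∈ [0,1]^(60×32). Six channel-wise
temporal filters w_j ∈ R^60 with biases produce the force-pattern map
F[j,c] = φ(w_j·W[:,c] + b_j); φ is ReLU by default (config-switchable to
identity so the linear case can be tested analytically). F is flattened
row-major — filter-major, then channel — to 192 features, fixed and
documented so serialized weights are portable. A fully connected layer
maps the features to the 3 joint angles in degrees.

Training: mean-squared error, Adam (lr 1e−3, 100 epochs, batch 64),
seeded; these are standard defaults for a two-layer regressor — the
original training hyperparameters are not public. Cross-validation folds
are **grouped by trial**, never shuffled samples: neighbouring windows
overlap in time, and sample-level splits would leak. Initial training uses
10-fold CV over 10 trials; transfer uses 5-fold CV over 5 trials.

Supervision pairs: joint angles recorded at 120 Hz are up-sampled to the
EMG timeline (500 Hz) by linear interpolation; each 60-sample window is
labeled with the angle at its **last** sample — the causal choice, matching
real-time use where only past EMG exists. Window stride is 30 samples
(60 ms) by default, balancing pair count against redundancy.

Layer transfer freezes the convolutional filters and biases bit-exactly
and retrains only the fully connected layer. Rationale: the temporal
structure of activation envelopes is a property of muscle physiology and
the envelope pipeline, stable across days, while the channel-to-DOF mixing
depends on where each electrode sits — which changes when the sleeve is
re-donned.

## Adaptive Kalman smoother

Each DOF is smoothed by an independent scalar filter with a random-walk
state model (gain K = P/(P+R); covariance update P ← (1−K)P + Q). Initial
Q = 0.05 deg², R = 0.4 deg²; state starts at the first observation with
P = R, avoiding a startup transient toward zero.

Q and R adapt after every step as running means (weight 1/(k+1)) of
instantaneous innovation-based estimates, with innovation d = z − x(k−1):

    R̂ = max(d² − P(k−1), 1e−4)     Q̂ = max(K² d², 1e−6)

This is classical moment matching: the innovation variance is P + R, and
K²d² is the variance the update injects into the state. Floors guarantee
positivity. The running-mean form implies |Q(k+1) − Q(k)| ≤ span/(k+1), so
the traces are Cauchy-convergent on stationary inputs.

**Behavior on fast transitions (known limitation).** The estimators assume
stationary innovations. When the decoded angle ramps 30° in ~0.3 s at an
~8 Hz output rate, per-cycle innovations reach ~12°, and d² − P attributes
them to observation noise: R's running mean grows, the gain shrinks, lag
grows, and innovations grow further. On synthetic sessions with dense fast
transitions R can reach ~10² deg² and the smoothed output lags visibly
(the acceptance script reports both smoothed and raw correlations so this
is quantified, not hidden). On signals whose innovations are small and
stationary — slower motions, higher output rates — the same recursion
shrinks Q and R instead. Where tracking matters more than oscillation
suppression, adaptation can be disabled (`KalmanConfig(adapt=False)`),
which keeps the hand-tuned Q = 0.05 / R = 0.4.

With adaptation off, the covariance recursion has the closed-form fixed
point P* = (Q + √(Q² + 4QR))/2, used as an analytic test anchor.

## Real-time engine

The loop always grabs the **latest** 60-sample window: samples arriving
while the previous cycle computed are never queued (lossy policy — command
latency stays bounded; the effective output rate is what the hardware
allows). Replay mode advances a virtual clock by a fixed number of samples
per cycle (default 60, configurable to emulate slower cycles), making
sessions deterministic and machine-independent. Skipped samples still pass
through the FIR filter so the streaming state always reflects the
contiguous signal history; each emitted window is then bit-identical to
the offline pipeline's slice at the same position.

Per-cycle computational latency is measured strictly around the three
processing stages (envelope → regression → smoothing), excluding source
I/O and output writing, so the number is comparable across machines. A
failed cycle is logged and skipped rather than crashing the session.

## Synthetic data generator

What it emulates: a 32-channel sleeve at 500 Hz and a motion-capture angle
stream at 120 Hz, driven by scripted daily motions (M0 rest; M1–M5 single;
M6–M9 double-mixture; M10–M13 triple-mixture). Six virtual muscles — one
agonist/antagonist pair per DOF, the smallest set that separates all 13
motions — map to channel envelopes through a nonnegative 32 × 6 synergy
mixing matrix (block structure: each muscle dominates a band of
electrodes, mild random crosstalk elsewhere). Angle targets scale at
30°/DOF, the largest TAC target; transitions are cosine ramps (default
0.3 s) so "measured" angles have no steps. The carrier is white noise:
the pipeline consumes only the rectified-filtered envelope, so carrier
spectrum is irrelevant to the correctness being tested — a deliberate
simplification.

MVC recordings are **bursts**: rest → all muscles maximal → rest, with
cosine on/off ramps. The plateau anchors each channel's envelope maximum
(row-sum of mixing + baseline) and the rest phases anchor the minimum
(baseline). A constant-maximum recording would make min ≈ max and the
min–max normalizer would clip away nearly the whole dynamic range.

Day-two sessions perturb the synergy model by a cyclic 2-channel sleeve
rotation plus ±35% multiplicative gain drift — re-donning effects that
degrade a stale model's channel mixing while leaving temporal structure
intact, i.e. exactly the situation layer transfer addresses.

What it does **not** emulate: motor-unit recruitment, conduction velocity,
EMG spectral shape, electrode lift-off, fatigue, or closed-loop user
correction. Passing tests therefore demonstrate pipeline correctness and
the transfer mechanism under the stated signal model, not physiological
realism or human-in-the-loop performance.

## Evaluation conventions

* Pearson CC uses the sample (N−1) standard deviations, consistent with
  its 1/(N−1) prefactor; zero-variance series raise rather than return a
  silent NaN (except per-class scoring, where a constant DOF inside a
  motion class is skipped as information-free).
* Predictions and measurements are aligned by linear interpolation of the
  120 Hz measured stream onto prediction timestamps.
* Latency stability uses one-way ANOVA over per-minute groups and declares
  stability when **p > 0.5** — an unusually strict no-difference criterion
  reproduced as a domain convention; note that under a true null, p > 0.5
  occurs only half the time by construction.
* TAC: tolerance ±5° is a closed interval (|Δ| ≤ 5 counts as inside); the
  dwell must be continuous — any excursion resets the timer; dwell timing
  uses the trajectory's own timestamps, tolerating irregular output rates;
  posture j+1's evaluation starts at the sample where posture j completed.
  The three trials use the standard posture tables (Central 1 → Target 1 →
  Target 2 → Central 2), 4 postures each, trial limit 30 s.

## Problem sizes

The acceptance script trains on 10 trials × 40 s (motion 2 s, rest 1 s
per entry) per day — ≈6,650 supervised pairs at stride 30 — transfers on
5 trials, and scores real-time replays of one full trial and a 5-minute
latency stream. These sizes give stable statistics (CV fold CCs agree to
~0.01) at a few minutes of CPU time.
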