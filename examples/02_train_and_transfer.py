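"""Train the CW-CNN on day-1 data, then adapt it to day 2 by layer transfer.

Day 2 emulates re-donning the electrode sleeve (rotated channels, gain
drift).  The temporal convolution filters transfer unchanged; only the
fully connected channel-mixing layer is retrained on new trials.  This
example uses 3 initial trials / 3 folds to keep runtime to ~1 minute; the
full protocol uses 10 trials with 10-fold cross-validation.
"""

from myodecode.model import TrainingConfig
from myodecode.pipeline import run_two_day_experiment

exp = run_two_day_experiment(
    seed=7,
    n_initial_trials=3,
    n_transfer_trials=5,
    initial_config=TrainingConfig(folds=3, seed=7),
)

print("initial CV validation CC per DOF (wrist flex/ext, pron/sup, grip):")
print(" ", exp.initial_report.mean_cc.round(4))
print("day-2 held-out CC, stale day-1 model:   ", exp.stale_cc.round(4))
print("day-2 held-out CC, after layer transfer:", exp.transferred_cc.round(4))
# The stale model degrades on the rotated sleeve; retraining only the fully
# connected layer (conv weights bit-identical) restores accuracy.
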