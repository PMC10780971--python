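"""Train the stacked-LSTM regressor and reconstruct an unseen waveform.

A deliberately small run (4 participants, 60 s, 8 epochs) so it finishes
in about a minute; the full protocol uses 300 epochs and 480 s recordings.
"""

import dataclasses

import bedpress as bp
from bedpress.config import ExperimentConfig
from bedpress.pipeline import prepare_datasets

recs = bp.simulate_cohort(4, master_seed=11, duration=60.0, fs=100.0)
cfg = dataclasses.replace(
    ExperimentConfig(),
    split_fractions=(0.5, 0.25, 0.25), split_seed=3,
    train=bp.TrainConfig(epochs=8, batch_size=256, seed=1))

train_ds, val_ds, split, scaler = prepare_datasets(recs, cfg)
print(f"split: {split}")
print(f"training windows: {len(train_ds)}, validation: {len(val_ds)}")

model = bp.build_model(seed=1)
print(f"trainable parameters: {model.count_params()}")

history = bp.train(model, train_ds, val_ds, cfg.train)
print(f"validation MSE by epoch (normalized targets): "
      f"{[round(v, 4) for v in history.val_loss]}")
print(f"best epoch: {history.best_epoch} (those weights are kept)")

test_rec = next(r for r in recs if r.participant_id in split["test"])
wf = bp.reconstruct(model, scaler, test_rec)
m = bp.waveform_metrics(test_rec.bp[50:], wf.values)
print(f"unseen participant {test_rec.participant_id}: "
      f"R^2 {m.r2:.3f}, MAE {m.mae:.2f} mmHg, MSE {m.mse:.2f} mmHg^2")

# R^2 well above 0 on a participant the network never saw shows the
# load-cell -> BP mapping generalizes across people; errors concentrate at
# the systolic/diastolic extremes of each beat.
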