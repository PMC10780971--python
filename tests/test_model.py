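"""Training protocol, target scaling, checkpointing and reconstruction."""

import dataclasses

import numpy as np
import pytest

import bedpress as bp
from bedpress.model import TargetScaler, load_model, save_model
from bedpress.windowing import concat_datasets


def _tiny_cohort(n, duration, seed, noiseless=False):
    cfg = bp.CohortConfig(noise_sd=0.0, drift_amplitude=0.0) if noiseless \
        else bp.CohortConfig()
    return bp.simulate_cohort(n, cfg, master_seed=seed, duration=duration)


def _datasets(recs, scaler=None):
    dss = [bp.build_windows(r) for r in recs]
    ds = concat_datasets(dss)
    if scaler is not None:
        ds.targets = scaler.transform(ds.targets).astype(np.float32)
    return ds


class TestTargetScaler:
    def test_minmax_endpoints(self):
        scaler, transformed = bp.normalize_targets(np.array([60.0, 160.0]))
        assert np.allclose(transformed, [0.0, 1.0])

    def test_roundtrip_exact(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(60, 160, size=200)
        scaler, fwd = bp.normalize_targets(x)
        assert np.allclose(scaler.inverse_transform(fwd), x, atol=1e-9)

    def test_extrapolates_beyond_training_range(self):
        scaler, _ = bp.normalize_targets(np.array([80.0, 120.0]))
        assert scaler.transform(np.array([170.0]))[0] > 1.0

    def test_constant_targets_rejected(self):
        with pytest.raises(ValueError):
            bp.normalize_targets(np.full(10, 100.0))

    def test_serialization_roundtrip(self):
        scaler, _ = bp.normalize_targets(np.array([70.0, 150.0, 90.0]))
        clone = TargetScaler.from_dict(scaler.to_dict())
        x = np.array([60.0, 100.0, 200.0])
        assert np.allclose(clone.transform(x), scaler.transform(x))


@pytest.fixture(scope="module")
def trained():
    """Seeded run on a noiseless cohort: 3 train / 1 val participants,
    60 s each, 30 epochs."""
    recs = _tiny_cohort(4, 60.0, seed=11, noiseless=True)
    train_targets = np.concatenate([r.bp[50:] for r in recs[:3]])
    scaler, _ = bp.normalize_targets(train_targets)
    train_ds = _datasets(recs[:3], scaler)
    val_ds = _datasets(recs[3:], scaler)
    model = bp.build_model(seed=1)
    tcfg = bp.TrainConfig(epochs=30, batch_size=256, seed=1)
    history = bp.train(model, train_ds, val_ds, tcfg)
    return model, history, scaler, recs


class TestTraining:

    def test_history_has_one_entry_per_epoch(self, trained):
        _, history, _, _ = trained
        assert len(history.train_loss) == 30
        assert len(history.val_loss) == 30

    def test_validation_error_improves_from_first_epoch(self, trained):
        _, history, _, _ = trained
        assert history.val_loss[-1] < history.val_loss[0] or \
            min(history.val_loss) < history.val_loss[0]

    def test_best_epoch_is_argmin_of_validation_loss(self, trained):
        _, history, _, _ = trained
        assert history.best_epoch == int(np.argmin(history.val_loss)) + 1

    def test_checkpoint_dominates_last_epoch(self, trained):
        """The returned weights achieve validation MSE <= the last epoch's
        (the checkpoint rule keeps the best epoch, not the final one)."""
        model, history, scaler, recs = trained
        val_ds = _datasets(recs[3:], scaler)
        val_mse = model.evaluate_mse(val_ds.inputs, val_ds.targets)
        assert val_mse <= history.val_loss[-1] + 1e-9
        assert val_mse == pytest.approx(
            history.val_loss[history.best_epoch - 1], rel=1e-5)

    def test_reconstruction_length_and_alignment(self, trained):
        model, _, scaler, recs = trained
        rec = recs[3]
        wf = bp.reconstruct(model, scaler, rec)
        assert len(wf.values) == rec.n_samples - 50
        assert wf.start_index == 50

    def test_shift_equivariance_of_reconstruction(self, trained):
        """Dropping the first s samples of the input shifts the output by
        exactly s samples on the overlap."""
        model, _, scaler, recs = trained
        rec = recs[3]
        s = 17
        shifted = bp.Recording(participant_id=rec.participant_id, fs=rec.fs,
                               load_cells=rec.load_cells[:, s:],
                               bp=rec.bp[s:])
        a = bp.reconstruct(model, scaler, rec)
        b = bp.reconstruct(model, scaler, shifted)
        assert np.allclose(a.values[s:], b.values, atol=1e-3)

    def test_save_load_roundtrip(self, trained, tmp_path):
        model, history, scaler, recs = trained
        save_model(tmp_path / "m", model, scaler, bp.ModelConfig(),
                   bp.TrainConfig(epochs=30, seed=1), history=history)
        clone, scaler2, meta = load_model(tmp_path / "m")
        X = np.random.default_rng(0).normal(size=(10, 50, 4)) \
            .astype(np.float32)
        assert np.allclose(model.predict(X), clone.predict(X), atol=1e-6)
        assert meta["history"]["best_epoch"] == history.best_epoch


class TestTrainingErrors:
    def test_empty_dataset_rejected(self):
        recs = _tiny_cohort(2, 10.0, seed=0)
        ds = _datasets(recs[:1])
        empty = dataclasses.replace(ds) if False else ds
        model = bp.build_model()
        bad = bp.WindowDataset(inputs=ds.inputs[:0], targets=ds.targets[:0],
                               target_indices=ds.target_indices[:0],
                               participant_id="none", N=50)
        with pytest.raises(ValueError):
            bp.train(model, bad, ds, bp.TrainConfig(epochs=1))

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ValueError):
            bp.TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            bp.TrainConfig(loss="mae")
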