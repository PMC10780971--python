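"""The recurrent BP-waveform regressor: build, train, checkpoint, apply.

The network maps a 50-step x 4-channel load-cell window to the concurrent
BP sample: three stacked 30-unit LSTM layers (the first two returning full
sequences, the third its last hidden state) followed by a single linear
dense unit — 18,871 trainable parameters with the default configuration.
Training minimizes mean squared error with Adam (batch 256) from
Glorot-normal initialization, and the returned model carries the weights
of the epoch with the lowest validation error, not the last epoch.

Targets are min-max normalized to [0, 1] using statistics of the training
set only (the same fitted map is applied to validation/test); all mmHg
metrics downstream are computed after the inverse transform.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.preprocessing import MinMaxScaler

from .nn import Adam, LSTMRegressor
from .synthetic import Recording
from .windowing import WindowDataset, build_windows

__all__ = ["ModelConfig", "TrainConfig", "TrainHistory", "TargetScaler",
           "ReconstructedWaveform", "build_model", "normalize_targets",
           "train", "reconstruct", "save_model", "load_model"]


@dataclass(frozen=True)
class ModelConfig:
    lstm_units: int = 30
    n_lstm_layers: int = 3
    input_steps: int = 50
    input_features: int = 4
    output_dim: int = 1
    #: optional per-recording z-scoring of load-cell channels before
    #: windowing; off by default (raw filtered units are fed to the net)
    normalize_inputs: bool = False

    def __post_init__(self) -> None:
        for name in ("lstm_units", "n_lstm_layers", "input_steps",
                     "input_features", "output_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.output_dim != 1:
            raise ValueError("only a single-output head is supported")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 300
    batch_size: int = 256
    loss: str = "mean_squared_error"
    optimizer: str = "adam"
    init: str = "glorot_normal"
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss != "mean_squared_error":
            raise ValueError("only mean_squared_error loss is supported")
        if self.optimizer != "adam":
            raise ValueError("only adam is supported")
        if self.init != "glorot_normal":
            raise ValueError("only glorot_normal init is supported")


@dataclass
class TrainHistory:
    """Per-epoch losses plus the best-validation checkpoint."""

    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int                      # 1-based; earliest on ties
    checkpoint: list[np.ndarray]         # weights at best_epoch

    def __post_init__(self) -> None:
        if len(self.train_loss) != len(self.val_loss):
            raise ValueError("loss histories must have equal length")
        if not 1 <= self.best_epoch <= len(self.val_loss):
            raise ValueError("best_epoch out of range")


@dataclass
class ReconstructedWaveform:
    """Estimated BP waveform aligned to its source recording.

    ``values[k]`` estimates BP at source sample index ``start_index + k``;
    the first N samples of the source cannot be reconstructed.
    """

    values: np.ndarray
    start_index: int
    fs: float
    participant_id: str

    @property
    def duration(self) -> float:
        return len(self.values) / self.fs


class TargetScaler:
    """Affine min-max map of BP targets to [0, 1], fit on training data only.

    The inverse restores mmHg exactly; values outside the training range
    map outside [0, 1] (no clipping).
    """

    def __init__(self) -> None:
        self._scaler = MinMaxScaler(clip=False)

    def fit(self, targets: np.ndarray) -> "TargetScaler":
        targets = np.asarray(targets, dtype=float)
        if targets.size < 2 or np.ptp(targets) == 0:
            raise ValueError("need >= 2 distinct target values to fit scaler")
        self._scaler.fit(targets.reshape(-1, 1))
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return self._scaler.transform(
            np.asarray(x, dtype=float).reshape(-1, 1))[:, 0]

    def inverse_transform(self, x: np.ndarray) -> np.ndarray:
        return self._scaler.inverse_transform(
            np.asarray(x, dtype=float).reshape(-1, 1))[:, 0]

    @property
    def data_min(self) -> float:
        return float(self._scaler.data_min_[0])

    @property
    def data_max(self) -> float:
        return float(self._scaler.data_max_[0])

    def to_dict(self) -> dict:
        return {"data_min": self.data_min, "data_max": self.data_max}

    @classmethod
    def from_dict(cls, d: dict) -> "TargetScaler":
        s = cls()
        s._scaler.fit(np.array([[d["data_min"]], [d["data_max"]]]))
        return s


class IdentityScaler:
    """No-op stand-in for TargetScaler when normalization is disabled."""

    def transform(self, x):
        return np.asarray(x, dtype=float)

    def inverse_transform(self, x):
        return np.asarray(x, dtype=float)

    def to_dict(self):
        return {"identity": True}


def build_model(cfg: ModelConfig | None = None, seed: int = 0
                ) -> LSTMRegressor:
    """Construct the stacked-LSTM regressor (default: 18,871 parameters)."""
    cfg = cfg or ModelConfig()
    units = [cfg.lstm_units] * cfg.n_lstm_layers
    return LSTMRegressor(layer_units=units,
                         input_features=cfg.input_features, seed=seed)


def normalize_targets(train_targets: np.ndarray
                      ) -> tuple[TargetScaler, np.ndarray]:
    """Fit the min-max target scaler on training targets; return both."""
    scaler = TargetScaler().fit(train_targets)
    return scaler, scaler.transform(train_targets)


def train(model: LSTMRegressor, train_ds: WindowDataset,
          val_ds: WindowDataset, tcfg: TrainConfig | None = None,
          verbose: bool = False) -> TrainHistory:
    """Minibatch MSE training with best-validation checkpointing.

    Runs ``tcfg.epochs`` epochs of Adam over seeded shuffles of the
    training windows; after each epoch the validation MSE is evaluated and
    the weights of the epoch with the lowest validation loss (earliest on
    ties) are kept. On return the model carries the checkpoint weights.
    """
    tcfg = tcfg or TrainConfig()
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("datasets must be non-empty")
    Xtr = np.asarray(train_ds.inputs, dtype=model.dtype)
    ytr = np.asarray(train_ds.targets, dtype=model.dtype)
    Xva = np.asarray(val_ds.inputs, dtype=model.dtype)
    yva = np.asarray(val_ds.targets, dtype=np.float64)

    rng = np.random.default_rng(tcfg.seed)
    opt = Adam(model.params, lr=tcfg.learning_rate)
    train_hist: list[float] = []
    val_hist: list[float] = []
    best_val = np.inf
    best_epoch = 1
    checkpoint = model.get_params_copy()

    M = len(Xtr)
    for epoch in range(1, tcfg.epochs + 1):
        order = rng.permutation(M)
        epoch_loss = 0.0
        n_seen = 0
        for s in range(0, M, tcfg.batch_size):
            idx = order[s:s + tcfg.batch_size]
            loss, grads = model.loss_and_grads(Xtr[idx], ytr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, "
                    f"batch offset {s}")
            opt.step(model.params, grads)
            epoch_loss += loss * len(idx)
            n_seen += len(idx)
        train_hist.append(epoch_loss / n_seen)
        val_mse = model.evaluate_mse(Xva, yva)
        if not np.isfinite(val_mse):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        val_hist.append(val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best_epoch = epoch
            checkpoint = model.get_params_copy()
        if verbose:
            print(f"epoch {epoch:3d}  train {train_hist[-1]:.6f}  "
                  f"val {val_mse:.6f}")

    model.set_params(checkpoint)
    return TrainHistory(train_loss=train_hist, val_loss=val_hist,
                        best_epoch=best_epoch, checkpoint=checkpoint)


def reconstruct(model: LSTMRegressor, scaler, rec: Recording,
                N: int = 50) -> ReconstructedWaveform:
    """Reconstruct a recording's BP waveform from its load cells.

    Applies the sliding-window transform, batch-predicts, and inverts the
    target scaling; output sample k estimates BP at source index N + k.
    """
    ds = build_windows(rec, N=N)
    pred = model.predict(ds.inputs)
    values = scaler.inverse_transform(pred)
    return ReconstructedWaveform(values=values, start_index=N, fs=rec.fs,
                                 participant_id=rec.participant_id)


def save_model(path: str | os.PathLike, model: LSTMRegressor, scaler,
               model_cfg: ModelConfig, train_cfg: TrainConfig,
               split: dict | None = None,
               history: TrainHistory | None = None) -> None:
    """Serialize weights (npz) plus a JSON sidecar with configs and split."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz",
             **{f"p{i}": p for i, p in enumerate(model.params)})
    meta = {
        "model_config": asdict(model_cfg),
        "train_config": asdict(train_cfg),
        "scaler": scaler.to_dict(),
        "split": split or {},
    }
    if history is not None:
        meta["history"] = {
            "train_loss": history.train_loss,
            "val_loss": history.val_loss,
            "best_epoch": history.best_epoch,
        }
    (path / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | os.PathLike
               ) -> tuple[LSTMRegressor, TargetScaler, dict]:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    cfg = ModelConfig(**meta["model_config"])
    model = build_model(cfg)
    with np.load(path / "weights.npz") as z:
        model.set_params([z[f"p{i}"] for i in range(len(z.files))])
    if meta["scaler"].get("identity"):
        scaler = IdentityScaler()
    else:
        scaler = TargetScaler.from_dict(meta["scaler"])
    return model, scaler, meta
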