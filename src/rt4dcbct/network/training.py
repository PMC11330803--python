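"""Training loop, weighted loss and prediction for the ConvLSTM regressor.

The loss is a coefficient-weighted mean squared error

    L = (1/N) sum_i || wcoeff o (y_i - G(x_i, W)) ||^2

with ``wcoeff`` defaulting to [2/6, 1/6, 1/6]: the first PCA coefficient
carries most of the motion information, so it is weighted highest to give
it the best estimation accuracy.  Targets are standardised per component
before the loss (raw coefficients span orders of magnitude) and the weights
act in that standardised space; predictions are mapped back to raw
coefficient units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .convlstm import ConvLSTMRegressor, NetworkConfig
from .ops import Adam


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation settings (ADAM, lr 0.001 with step decay, batch 8)."""

    learning_rate: float = 1e-3
    lr_decay: float = 0.5
    lr_decay_every: int = 50       # epochs between decay steps
    batch_size: int = 8
    epochs: int = 200              # full-scale default; desk runs use <= 20
    wcoeff: tuple[float, ...] = (2.0 / 6.0, 1.0 / 6.0, 1.0 / 6.0)
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if any(w <= 0 for w in self.wcoeff):
            raise ValueError("loss weights must be positive")


@dataclass
class TargetScaler:
    """Per-component standardisation of the coefficient targets."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, y: np.ndarray) -> "TargetScaler":
        std = y.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        return cls(mean=y.mean(axis=0), std=std)

    def transform(self, y: np.ndarray) -> np.ndarray:
        return (y - self.mean) / self.std

    def inverse(self, y: np.ndarray) -> np.ndarray:
        return y * self.std + self.mean


def weighted_loss(
    y: np.ndarray, y_hat: np.ndarray, wcoeff: np.ndarray | tuple
) -> float:
    """(1/N) sum_i ||wcoeff o (y_i - y_hat_i)||^2."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    y_hat = np.atleast_2d(np.asarray(y_hat, dtype=float))
    w = np.asarray(wcoeff, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("label/prediction shape mismatch")
    if w.shape != (y.shape[1],):
        raise ValueError("weight length must equal the coefficient count")
    r = w[None, :] * (y - y_hat)
    return float(np.mean(np.sum(r * r, axis=1)))


def _loss_and_grad(y, y_hat, w):
    r = w[None, :] * (y - y_hat)
    loss = float(np.mean(np.sum(r * r, axis=1)))
    dy_hat = -2.0 / y.shape[0] * (w[None, :] ** 2) * (y - y_hat)
    return loss, dy_hat


@dataclass
class TrainedModel:
    """Network weights plus everything needed to reuse them consistently."""

    model: ConvLSTMRegressor
    scaler: TargetScaler
    net_config: NetworkConfig
    train_config: TrainingConfig

    def predict(self, sequences: np.ndarray) -> np.ndarray:
        """De-standardised coefficient predictions for (N, T, H, W) input."""
        return predict(self, sequences)

    def save(self, path) -> None:
        meta = {
            "net_config": vars(self.net_config) | {},
            "train_config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.train_config).items()
            },
            "input_shape": list(self.model.input_shape),
            "in_channels": self.model.in_channels,
        }
        np.savez_compressed(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            scaler_mean=self.scaler.mean,
            scaler_std=self.scaler.std,
            **{f"param_{k}": v for k, v in self.model.params.items()},
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            nc = dict(meta["net_config"])
            net_config = NetworkConfig(**nc)
            tc = dict(meta["train_config"])
            tc["wcoeff"] = tuple(tc["wcoeff"])
            train_config = TrainingConfig(**tc)
            model = ConvLSTMRegressor(
                net_config,
                input_shape=tuple(meta["input_shape"]),
                in_channels=int(meta["in_channels"]),
            )
            for k in model.params:
                model.params[k] = z[f"param_{k}"]
            scaler = TargetScaler(mean=z["scaler_mean"], std=z["scaler_std"])
        return cls(model=model, scaler=scaler, net_config=net_config,
                   train_config=train_config)


def train(
    sequences: np.ndarray,
    labels: np.ndarray,
    net_config: NetworkConfig,
    train_config: TrainingConfig,
) -> tuple[TrainedModel, dict]:
    """Train the regressor on (N, T, H, W) sequences with (N, k) raw labels.

    Returns the trained model and a history dict with per-epoch training
    (and, when ``val_fraction`` > 0, validation) loss.  Runs are
    reproducible for a fixed seed on one machine.
    """
    sequences = np.asarray(sequences, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.float64)
    if sequences.ndim != 4:
        raise ValueError("sequences must be (N, T, H, W)")
    if sequences.shape[0] == 0:
        raise ValueError("empty dataset")
    if labels.shape != (sequences.shape[0], net_config.k):
        raise ValueError("label shape mismatch")
    N, T, Hh, Ww = sequences.shape
    if T != net_config.sequence_length:
        raise ValueError("sequence length does not match the network config")

    rng = np.random.default_rng(train_config.seed)
    perm = rng.permutation(N)
    n_val = int(round(train_config.val_fraction * N))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        raise ValueError("no training samples left after validation split")

    scaler = TargetScaler.fit(labels[tr_idx])
    y_all = scaler.transform(labels)
    w = np.asarray(train_config.wcoeff, dtype=np.float64)
    if w.shape != (net_config.k,):
        raise ValueError("wcoeff length must equal k")

    model = ConvLSTMRegressor(
        net_config, input_shape=(Hh, Ww), in_channels=1, seed=train_config.seed
    )
    opt = Adam(model.params, lr=train_config.learning_rate)
    history: dict[str, list] = {"train_loss": [], "val_loss": [], "lr": []}

    x_all = sequences[..., None]            # add the channels-last axis
    for epoch in range(train_config.epochs):
        lr = train_config.learning_rate * (
            train_config.lr_decay ** (epoch // train_config.lr_decay_every)
        )
        order = rng.permutation(tr_idx)
        losses = []
        for start in range(0, order.size, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            xb = x_all[idx]
            yb = y_all[idx]
            y_hat, cache = model.forward(xb, want_cache=True)
            loss, dy = _loss_and_grad(yb, y_hat.astype(np.float64), w)
            grads = model.backward(cache, dy)
            opt.step(model.params, grads, lr=lr)
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        history["lr"].append(lr)
        if val_idx.size:
            vy = _predict_standardised(model, x_all[val_idx])
            vloss = weighted_loss(y_all[val_idx], vy, w)
            history["val_loss"].append(float(vloss))
    trained = TrainedModel(
        model=model, scaler=scaler, net_config=net_config, train_config=train_config
    )
    return trained, history


def _predict_standardised(
    model: ConvLSTMRegressor, x: np.ndarray, batch: int = 32
) -> np.ndarray:
    outs = [
        model.forward(x[s : s + batch]) for s in range(0, x.shape[0], batch)
    ]
    return np.concatenate(outs, axis=0).astype(np.float64)


def predict(trained: TrainedModel, sequences: np.ndarray) -> np.ndarray:
    """Coefficients in raw units for (N, T, H, W) or (T, H, W) input."""
    if trained.scaler is None:
        raise ValueError("model is missing target-scaling metadata")
    x = np.asarray(sequences, dtype=np.float32)
    single = x.ndim == 3
    if single:
        x = x[None]
    y = _predict_standardised(trained.model, x[..., None])
    y = trained.scaler.inverse(y)
    return y[0] if single else y
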