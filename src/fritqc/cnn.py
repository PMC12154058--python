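"""The 1-D spectral CNN for origin classification and adulteration regression.

Architecture (fixed): five convolutional blocks with 16, 32, 64, 128 and 256
filters of length 3, each block = convolution -> batch normalisation -> ReLU,
with length-2 max downsampling after the first four blocks for full-spectrum
(801-point) input and no downsampling for short PCA-score input; head =
global average pooling -> dense(64, ReLU) -> output (4-way softmax for
classification, one linear unit for regression).

Training: Adam, initial learning rate 1e-4 decayed by 20% every 50 epochs,
mini-batches of 10, up to 1500 epochs, per-feature z-score input
normalisation from training-set statistics.  One integer seed controls
weight initialisation and batch shuffling; training is fully deterministic
on one device.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from . import nn
from .grid import SpectraSet, Spectrum

__all__ = [
    "ConfigurationError",
    "CNNSpec",
    "TrainConfig",
    "build_model",
    "BuiltModel",
    "SpectralCNN",
    "CNNResults",
    "CNNClassifier",
    "CNNRegressor",
    "svm_baseline",
    "dt_baseline",
]


class ConfigurationError(ValueError):
    """Architecture/input-length combination is invalid."""


@dataclass(frozen=True)
class CNNSpec:
    """Fixed five-block architecture; only pooling placement is adjustable."""

    conv_filters: Tuple[int, ...] = (16, 32, 64, 128, 256)
    kernel_size: int = 3
    pool_after: Tuple[bool, ...] = (True, True, True, True, False)
    dense_units: int = 64

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 5:
            raise ConfigurationError("exactly five convolutional blocks required")
        if len(self.pool_after) != len(self.conv_filters):
            raise ConfigurationError("pool_after must have one flag per block")

    @classmethod
    def for_input(cls, input_length: int) -> "CNNSpec":
        """Default pooling for long spectra, none for short PCA-score input."""
        if input_length >= 32:
            return cls()
        return cls(pool_after=(False,) * 5)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule; defaults follow the training protocol."""

    lr0: float = 1e-4
    lr_decay: float = 0.8
    decay_every: int = 50
    batch_size: int = 10
    max_epochs: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def learning_rate(self, epoch: int) -> float:
        """Closed form lr(epoch) = lr0 * lr_decay ** (epoch // decay_every)."""
        return self.lr0 * self.lr_decay ** (epoch // self.decay_every)


@dataclass
class BuiltModel:
    """An untrained network plus the bookkeeping Grad-CAM needs."""

    net: nn.Sequential
    task: str
    input_length: int
    spec: CNNSpec
    cam_layer_index: int   # index (in net.layers) of the last conv block output

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def shape_trace(self):
        return self.net.shape_trace(self.input_length)


def build_model(spec: CNNSpec, task: str, input_length: int,
                rng: Optional[np.random.Generator] = None) -> BuiltModel:
    """Assemble the untrained network for the given task and input length."""
    if task not in ("classify", "regress"):
        raise ValueError(f"unknown task {task!r}")
    if input_length < 1:
        raise ConfigurationError("input_length must be positive")
    rng = rng or np.random.default_rng(0)
    layers = []
    c_in = 1
    length = input_length
    cam_index = -1
    for i, (c_out, pool) in enumerate(zip(spec.conv_filters, spec.pool_after)):
        layers.append(nn.Conv1d(c_in, c_out, spec.kernel_size, rng))
        layers.append(nn.BatchNorm1d(c_out))
        layers.append(nn.ReLU())
        cam_index = len(layers) - 1
        if pool:
            if length // 2 < 2:
                raise ConfigurationError(
                    f"input of length {input_length} is too short to survive "
                    f"downsampling at block {i + 1} (length {length} before "
                    f"pooling); disable pooling for short inputs")
            layers.append(nn.MaxPool1d(2))
            length //= 2
        c_in = c_out
    layers.append(nn.GlobalAvgPool1d())
    layers.append(nn.Dense(c_in, spec.dense_units, rng))
    layers.append(nn.ReLU())
    n_out = 4 if task == "classify" else 1
    layers.append(nn.Dense(spec.dense_units, n_out, rng))
    return BuiltModel(nn.Sequential(layers), task, input_length, spec, cam_index)


@dataclass
class CNNResults:
    """A trained spectral CNN: parameters, normalisation statistics, history."""

    model: BuiltModel
    config: TrainConfig
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    history: pd.DataFrame

    @property
    def task(self) -> str:
        return self.model.task

    def _features(self, X) -> np.ndarray:
        if isinstance(X, SpectraSet):
            X = X.X
        elif isinstance(X, Spectrum):
            X = X.absorbance[None, :]
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.model.input_length:
            raise ValueError(
                f"input has {X.shape[1]} features, model expects "
                f"{self.model.input_length}")
        return ((X - self.x_mean) / self.x_sd).astype(nn.DTYPE)

    def _forward(self, Z: np.ndarray, batch: int = 256) -> np.ndarray:
        outs = []
        for i in range(0, Z.shape[0], batch):
            x = Z[i:i + batch][:, None, :]
            outs.append(self.model.net.forward(x, train=False))
        return np.vstack(outs)

    def predict_proba(self, X) -> np.ndarray:
        if self.task != "classify":
            raise ValueError("predict_proba requires a classification model")
        return nn.softmax(self._forward(self._features(X)))

    def predict_classes(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def predict_raw(self, X) -> np.ndarray:
        """Regression output on the original fraction scale (unclipped)."""
        if self.task != "regress":
            raise ValueError("predict_raw requires a regression model")
        out = self._forward(self._features(X))[:, 0]
        return out * self.y_sd + self.y_mean

    def predict(self, X) -> np.ndarray:
        """Class labels (classification) or fractions clipped to [0, 1]."""
        if self.task == "classify":
            return self.predict_classes(X)
        return np.clip(self.predict_raw(X), 0.0, 1.0)

    def summary(self) -> pd.DataFrame:
        rows = [
            ("task", self.task),
            ("input_length", self.model.input_length),
            ("trainable_parameters", self.model.n_params),
            ("epochs_trained", len(self.history)),
            ("final_train_loss", float(self.history["train_loss"].iloc[-1])),
        ]
        if "val_metric" in self.history and self.history["val_metric"].notna().any():
            rows.append(("final_val_metric",
                         float(self.history["val_metric"].iloc[-1])))
        return pd.DataFrame(rows, columns=["quantity", "value"])

    # -- persistence ------------------------------------------------------
    def save(self, path) -> Path:
        """Checkpoint: parameters + normalisation stats + spec (npz + json)."""
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.model.net.params())}
        bn_state = {}
        for i, layer in enumerate(self.model.net.layers):
            if isinstance(layer, nn.BatchNorm1d):
                bn_state[f"rm{i}"] = layer.running_mean
                bn_state[f"rv{i}"] = layer.running_var
        np.savez(path.with_suffix(".npz"), x_mean=self.x_mean, x_sd=self.x_sd,
                 **arrays, **bn_state)
        meta = {
            "task": self.task,
            "input_length": self.model.input_length,
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "spec": {
                "conv_filters": list(self.model.spec.conv_filters),
                "kernel_size": self.model.spec.kernel_size,
                "pool_after": list(self.model.spec.pool_after),
                "dense_units": self.model.spec.dense_units,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        self.history.to_csv(path.with_suffix(".history.csv"), index=False)
        return path

    @classmethod
    def load(cls, path) -> "CNNResults":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        spec = CNNSpec(tuple(meta["spec"]["conv_filters"]),
                       meta["spec"]["kernel_size"],
                       tuple(meta["spec"]["pool_after"]),
                       meta["spec"]["dense_units"])
        built = build_model(spec, meta["task"], meta["input_length"])
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(built.net.params()):
            p[...] = data[f"p{i}"]
        for i, layer in enumerate(built.net.layers):
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean[...] = data[f"rm{i}"]
                layer.running_var[...] = data[f"rv{i}"]
        hist_path = path.with_suffix(".history.csv")
        history = pd.read_csv(hist_path) if hist_path.exists() else pd.DataFrame()
        return cls(built, TrainConfig(), data["x_mean"], data["x_sd"],
                   float(meta["y_mean"]), float(meta["y_sd"]), history)


class SpectralCNN:
    """Model object: data in, ``fit()`` out a :class:`CNNResults`.

    Parameters
    ----------
    train : SpectraSet, or (X, y) arrays
    task : "classify" or "regress"; inferred from the SpectraSet label kind
        when not given.
    spec : architecture; defaults to :meth:`CNNSpec.for_input`.
    """

    def __init__(self, train, task: Optional[str] = None,
                 spec: Optional[CNNSpec] = None,
                 config: TrainConfig = TrainConfig(),
                 input_norm: str = "per_feature"):
        if isinstance(train, SpectraSet):
            X, y = train.X, train.labels
            if task is None:
                task = "classify" if train.label_kind == "origin" else "regress"
        else:
            X, y = train
        if task is None:
            raise ValueError("task must be given for array input")
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.task = task
        self.spec = spec or CNNSpec.for_input(self.X.shape[1])
        self.config = config
        if input_norm not in ("per_feature", "global"):
            raise ValueError(f"unknown input_norm {input_norm!r}")
        self.input_norm = input_norm

    def fit(self, val=None, epochs: Optional[int] = None,
            record_val: bool = True, keep_best: bool = True) -> CNNResults:
        """Train with Adam + the stepped learning-rate schedule.

        ``epochs`` overrides ``config.max_epochs`` downward for desk-scale
        runs.  ``val`` (SpectraSet or (X, y)) is only monitored, never
        trained on.

        With ``keep_best`` (default) the returned parameters are those of
        the epoch with the lowest mean training loss — metrics are
        monitored after every epoch and mini-batch training is noisy, so
        the final epoch is not necessarily the converged one.  After
        training, batch-norm statistics are recalibrated with one pass over
        the full training set so inference matches the kept weights.  No
        validation or test data is involved in either step.
        """
        cfg = self.config
        n_epochs = min(epochs, cfg.max_epochs) if epochs else cfg.max_epochs
        rng = np.random.default_rng(cfg.seed)
        built = build_model(self.spec, self.task, self.X.shape[1], rng)

        if self.input_norm == "per_feature":
            x_mean = self.X.mean(axis=0)
            x_sd = self.X.std(axis=0)
            x_sd[x_sd == 0] = 1.0
        else:  # one mean/sd for the whole training matrix, keeps band shape
            x_mean = np.full(self.X.shape[1], self.X.mean())
            x_sd = np.full(self.X.shape[1], self.X.std() or 1.0)
        Z = ((self.X - x_mean) / x_sd).astype(nn.DTYPE)
        if self.task == "regress":
            y = self.y.astype(float)
            y_mean, y_sd = float(y.mean()), float(y.std()) or 1.0
            t = ((y - y_mean) / y_sd).astype(nn.DTYPE)
        else:
            y_mean, y_sd = 0.0, 1.0
            t = self.y.astype(int)

        val_xy = None
        if val is not None:
            if isinstance(val, SpectraSet):
                val_xy = (val.X, val.labels)
            else:
                val_xy = (np.asarray(val[0], float), np.asarray(val[1]))

        opt = nn.Adam(built.net.params())
        n = Z.shape[0]
        history = []
        results = CNNResults(built, cfg, x_mean, x_sd, y_mean, y_sd,
                             pd.DataFrame())
        best_loss = np.inf
        best_params: Optional[list] = None
        for epoch in range(n_epochs):
            lr = cfg.learning_rate(epoch)
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                x = Z[idx][:, None, :]
                out = built.net.forward(x, train=True)
                if self.task == "classify":
                    loss, dout = nn.cross_entropy_grad(out, t[idx])
                else:
                    loss, dout = nn.mse_grad(out, t[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch}"
                        f" (lr={lr:g})")
                built.net.backward(dout)
                opt.step(built.net.grads(), lr)
                losses.append(loss)
            epoch_loss = float(np.mean(losses))
            if keep_best and epoch_loss < best_loss:
                best_loss = epoch_loss
                best_params = [p.copy() for p in built.net.params()]
            row = {"epoch": epoch, "lr": lr,
                   "train_loss": epoch_loss,
                   "val_metric": np.nan}
            if val_xy is not None and record_val:
                if self.task == "classify":
                    pred = results.predict_classes(val_xy[0])
                    row["val_metric"] = float(np.mean(pred == val_xy[1]))
                else:
                    pred = results.predict_raw(val_xy[0])
                    row["val_metric"] = float(
                        np.sqrt(np.mean((pred - val_xy[1]) ** 2)))
            history.append(row)
        if keep_best and best_params is not None:
            for p, b in zip(built.net.params(), best_params):
                p[...] = b
            _recalibrate_batchnorm(built.net, Z)
        results.history = pd.DataFrame(history)
        return results


def _recalibrate_batchnorm(net: nn.Sequential, Z: np.ndarray) -> None:
    """Replace batch-norm running statistics with full-dataset statistics.

    One forward pass over the whole training matrix as a single batch with
    BN momentum set to 1: every layer's running mean/variance becomes the
    exact per-channel moments of its input under the kept weights (with
    upstream layers already using their full-data statistics), so
    eval-mode inference reproduces this pass exactly.
    """
    bn_layers = [l for l in net.layers if isinstance(l, nn.BatchNorm1d)]
    saved = [l.momentum for l in bn_layers]
    for l in bn_layers:
        l.momentum = 1.0
    try:
        net.forward(Z[:, None, :].astype(nn.DTYPE), train=True)
    finally:
        for l, m in zip(bn_layers, saved):
            l.momentum = m


# ---------------------------------------------------------------------------
# sklearn-style adapters used by the Monte Carlo evaluation harness.

class CNNClassifier:
    """fit/predict wrapper over SpectralCNN for the evaluation registry.

    Defaults are the desk-scale schedule (few epochs at a proportionally
    larger initial rate); pass an explicit :class:`TrainConfig` for the
    instrument-scale protocol.
    """

    def __init__(self, epochs: int = 15, seed: int = 0,
                 config: Optional[TrainConfig] = None,
                 input_norm: str = "global"):
        self.epochs = epochs
        self.config = config or TrainConfig(seed=seed, lr0=3e-3)
        self.input_norm = input_norm
        self.results_: Optional[CNNResults] = None

    def fit(self, X, y):
        self.results_ = SpectralCNN(
            (X, y), task="classify", config=self.config,
            input_norm=self.input_norm).fit(epochs=self.epochs,
                                            record_val=False)
        return self

    def predict(self, X):
        return self.results_.predict(X)


class CNNRegressor:
    """Desk-scale regression wrapper (global input standardisation)."""

    def __init__(self, epochs: int = 300, seed: int = 0,
                 config: Optional[TrainConfig] = None,
                 input_norm: str = "global"):
        self.epochs = epochs
        self.config = config or TrainConfig(seed=seed, lr0=1e-3,
                                            decay_every=30)
        self.input_norm = input_norm
        self.results_: Optional[CNNResults] = None

    def fit(self, X, y):
        self.results_ = SpectralCNN(
            (X, y), task="regress", config=self.config,
            input_norm=self.input_norm).fit(epochs=self.epochs,
                                            record_val=False)
        return self

    def predict(self, X):
        return self.results_.predict(X)


# ---------------------------------------------------------------------------
# Contractual baselines (maximum-margin and recursive-partitioning learners),
# hyperparameters tuned by the same k-fold CV harness as the PLS models.

def _cv_for(task, folds, y, seed):
    if task == "classify":
        _, counts = np.unique(y, return_counts=True)
        n_splits = max(2, min(folds, int(counts.min())))
        return StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return KFold(n_splits=min(folds, len(y)), shuffle=True, random_state=seed)


def _check_train_labels(y, task):
    y = np.asarray(y)
    if task == "classify" and np.unique(y).size < 2:
        raise ValueError("baseline training input has a single class")
    return y


def svm_baseline(train_X, train_y, test_X, task: str = "classify",
                 folds: int = 10, seed: int = 0):
    """SVM predictions for the test block, tuned by k-fold CV over C."""
    train_y = _check_train_labels(train_y, task)
    est = SVC() if task == "classify" else SVR()
    cv = _cv_for(task, folds, train_y, seed)
    gs = GridSearchCV(est, {"C": [1.0, 10.0, 100.0]}, cv=cv)
    gs.fit(np.asarray(train_X, float), train_y)
    return gs.predict(np.asarray(test_X, float))


def dt_baseline(train_X, train_y, test_X, task: str = "classify",
                folds: int = 10, seed: int = 0):
    """Decision-tree predictions, depth tuned by k-fold CV."""
    train_y = _check_train_labels(train_y, task)
    est = (DecisionTreeClassifier(random_state=seed) if task == "classify"
           else DecisionTreeRegressor(random_state=seed))
    cv = _cv_for(task, folds, train_y, seed)
    gs = GridSearchCV(est, {"max_depth": [3, 5, 10, None]}, cv=cv)
    gs.fit(np.asarray(train_X, float), train_y)
    return gs.predict(np.asarray(test_X, float))
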