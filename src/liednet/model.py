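"""The CNN regressor mapping difference-DCS images to structure labels.

Organised like a statsmodels model: :class:`DCSRegressor` is built from a
:class:`~liednet.prep.Dataset`; calling :meth:`~DCSRegressor.fit` trains the
network and returns a :class:`DCSRegressorResults` object carrying the
per-epoch mean-absolute-error history, the held-out test error, the trained
weights, and ``summary()``/``predict()``/``save()``.

Architecture (configurable): three convolution blocks (32 filters of 5x5,
then twice 32 of 3x3), each followed by batch normalization, ReLU and 2x2 max
pooling; the feature maps are flattened into a deep fully connected stack
(default depth 30, width 64) ending in a linear regression head.  Training
minimises the quadratic cost 0.5 (y_pre - y_real)^2 by mini-batch gradient
descent, w <- w - alpha dCost/dw; an Adam variant is available and is what
the bundled pipelines use (see docs).

Labels are min-max scaled to [0, 1] per dimension using training-split
statistics only and unscaled on output, so reported errors are in physical
units (Angstrom / degrees).  Inputs are divided by a single scalar (the
training-split standard deviation) to bring the tiny difference-map
amplitudes into a numerically comfortable range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .prep import Dataset, DiffMap

__all__ = [
    "CNNConfig", "TrainReport", "Prediction", "TrainingDiverged",
    "build_network", "DCSRegressor", "DCSRegressorResults",
    "load_results", "ensemble_retrieve",
]


class TrainingDiverged(RuntimeError):
    """Raised when the training cost becomes non-finite; carries the epoch."""

    def __init__(self, epoch: int):
        super().__init__(f"training cost became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass
class CNNConfig:
    """Hyperparameters of the regressor.

    ``conv_layers`` is a sequence of (filter count, kernel size); ``fc_depth``
    counts the hidden fully connected layers of width ``fc_width`` before the
    linear output.  ``optimizer`` is ``"sgd"`` (plain gradient descent, the
    default update rule) or ``"adam"``.
    """

    conv_layers: tuple = ((32, 5), (32, 3), (32, 3))
    fc_depth: int = 30
    fc_width: int = 64
    batch_size: int = 120
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_norm: bool = True
    optimizer: str = "sgd"
    lr_schedule: str = "constant"
    n_pool: int | None = None    # 2x2 max pools, applied to the first n conv blocks
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1 or self.fc_depth < 0 or self.fc_width < 1:
            raise ValueError("all architecture counts must be positive")
        if any(c < 1 or k < 1 for c, k in self.conv_layers):
            raise ValueError("conv filter counts and kernel sizes must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_layers"] = [list(x) for x in self.conv_layers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CNNConfig":
        d = dict(d)
        d["conv_layers"] = tuple(tuple(x) for x in d.get("conv_layers",
                                                         ((32, 5), (32, 3), (32, 3))))
        return cls(**d)


def build_network(config: CNNConfig, input_shape: tuple[int, int],
                  n_labels: int, rng: np.random.Generator | None = None,
                  dtype=np.float32) -> nn.Sequential:
    """Construct the (untrained) network for a given image shape and label size.

    Each convolution block is conv -> [batch norm] -> ReLU -> 2x2 max pool;
    then flatten and ``fc_depth`` hidden dense layers (each with optional
    batch norm and ReLU) and a linear output of ``n_labels``.  Initialization
    is seeded through ``rng``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = input_shape
    layers: list[nn.Layer] = []
    c_in = 1
    n_pool = len(config.conv_layers) if config.n_pool is None else config.n_pool
    for block, (c_out, k) in enumerate(config.conv_layers):
        if k > h or k > w:
            raise ValueError(f"kernel {k} larger than remaining input {h}x{w}")
        layers.append(nn.Conv2D(c_in, c_out, k, rng, dtype=dtype))
        h, w = h - k + 1, w - k + 1
        if config.batch_norm:
            layers.append(nn.BatchNorm(c_out, dtype=dtype))
        layers.append(nn.ReLU())
        if block < n_pool:
            layers.append(nn.MaxPool2())
            h, w = h // 2, w // 2
        if h < 1 or w < 1:
            raise ValueError("input too small for the convolution stack")
        c_in = c_out
    layers.append(nn.Flatten())
    n_in = c_in * h * w
    for _ in range(config.fc_depth):
        layers.append(nn.Dense(n_in, config.fc_width, rng, dtype=dtype))
        if config.batch_norm:
            layers.append(nn.BatchNorm(config.fc_width, dtype=dtype))
        layers.append(nn.ReLU())
        n_in = config.fc_width
    layers.append(nn.Dense(n_in, n_labels, rng, dtype=dtype))
    return nn.Sequential(layers)


@dataclass
class TrainReport:
    """Per-epoch MAE history (label units) plus the final test error."""

    train_mae: np.ndarray
    val_mae: np.ndarray
    test_mae: float
    test_mae_per_label: np.ndarray
    seed: int
    config: CNNConfig

    @property
    def epochs(self) -> int:
        return len(self.train_mae)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(1, self.epochs + 1),
                             "train_mae": self.train_mae,
                             "val_mae": self.val_mae})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _mae(pred: np.ndarray, true: np.ndarray) -> float:
    return float(np.mean(np.abs(pred - true)))


class DCSRegressor:
    """CNN regression model for a prepared difference-map dataset.

    Parameters
    ----------
    dataset : Dataset
        Difference maps, labels and splits from :func:`liednet.prep.assemble_dataset`.
    config : CNNConfig, optional
        Architecture and training hyperparameters.
    """

    #: cap on how many training samples are scored per epoch for the MAE curve
    _TRAIN_EVAL_CAP = 512

    def __init__(self, dataset: Dataset, config: CNNConfig | None = None):
        self.dataset = dataset
        self.config = config or CNNConfig()
        lmin, lmax = dataset.label_min, dataset.label_max
        rng_ = np.asarray(lmax - lmin, dtype=float)
        rng_[rng_ == 0] = 1.0     # constant label dimension: leave unscaled
        self._label_scale = rng_
        self._label_offset = np.asarray(lmin, dtype=float)
        x_train = dataset.inputs[dataset.train_idx]
        scale = float(x_train.std())
        self._input_scale = scale if scale > 0 else 1.0

    # -- scaling helpers -----------------------------------------------------
    def _scale_x(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32) / self._input_scale
        return x[:, None, :, :]

    def _scale_y(self, y: np.ndarray) -> np.ndarray:
        return ((y - self._label_offset) / self._label_scale).astype(np.float32)

    def _unscale_y(self, y01: np.ndarray) -> np.ndarray:
        return y01.astype(float) * self._label_scale + self._label_offset

    def fit(self, verbose: bool = False) -> "DCSRegressorResults":
        """Train the network and return a results object.

        Deterministic for a fixed config seed and dataset.  Raises
        :class:`TrainingDiverged` if the cost becomes non-finite.
        """
        cfg = self.config
        ds = self.dataset
        rng = np.random.default_rng(cfg.seed)
        net = build_network(cfg, ds.grid.shape, ds.n_labels, rng)

        x_train, y_train = ds.split("train")
        x_val, y_val = ds.split("validation")
        xt = self._scale_x(x_train)
        yt = self._scale_y(y_train)
        xv = self._scale_x(x_val)

        opt = (nn.SGD(net, cfg.learning_rate) if cfg.optimizer == "sgd"
               else nn.Adam(net, cfg.learning_rate))

        n = len(xt)
        eval_idx = (np.arange(n) if n <= self._TRAIN_EVAL_CAP
                    else rng.choice(n, self._TRAIN_EVAL_CAP, replace=False))
        train_hist, val_hist = [], []
        for epoch in range(cfg.epochs):
            if cfg.lr_schedule == "cosine":
                # anneal the step size to zero over the run; reduces the
                # late-epoch gradient-noise floor of a constant step
                opt.alpha = cfg.learning_rate * 0.5 * (
                    1.0 + np.cos(np.pi * epoch / cfg.epochs))
            order = rng.permutation(n)
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo:lo + cfg.batch_size]
                pred = net.forward(xt[idx], training=True)
                cost, grad = nn.half_squared_error(pred, yt[idx])
                if not np.isfinite(cost):
                    raise TrainingDiverged(epoch + 1)
                net.backward(grad)
                opt.step()
            p_tr = self._predict_net(net, xt[eval_idx])
            p_va = self._predict_net(net, xv)
            train_hist.append(_mae(p_tr, y_train[eval_idx]))
            val_hist.append(_mae(p_va, y_val))
            if verbose:
                print(f"epoch {epoch + 1:3d}  train MAE {train_hist[-1]:.5f}  "
                      f"val MAE {val_hist[-1]:.5f}")

        x_test, y_test = ds.split("test")
        p_te = self._predict_net(net, self._scale_x(x_test))
        report = TrainReport(np.array(train_hist), np.array(val_hist),
                             _mae(p_te, y_test),
                             np.mean(np.abs(p_te - y_test), axis=0),
                             cfg.seed, cfg)
        return DCSRegressorResults(self, net, report)

    def _predict_net(self, net: nn.Sequential, x_scaled: np.ndarray,
                     batch: int = 512) -> np.ndarray:
        outs = [net.forward(x_scaled[lo:lo + batch], training=False)
                for lo in range(0, len(x_scaled), batch)]
        return self._unscale_y(np.concatenate(outs))


class DCSRegressorResults:
    """Fitted-regressor results: weights, error history, prediction interface."""

    def __init__(self, model: DCSRegressor, net: nn.Sequential, report: TrainReport):
        self.model = model
        self.net = net
        self.report = report

    # -- prediction ----------------------------------------------------------
    def predict(self, inputs) -> np.ndarray:
        """Predict label vectors (physical units) for difference-map input(s).

        Accepts a :class:`DiffMap`, a single 2D array, or a stack of maps.
        """
        if isinstance(inputs, DiffMap):
            inputs = inputs.values
        x = np.asarray(inputs, dtype=float)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.shape[1:] != self.model.dataset.grid.shape:
            raise ValueError(f"input shape {x.shape[1:]} does not match the "
                             f"model grid {self.model.dataset.grid.shape}")
        out = self.model._predict_net(self.net, self.model._scale_x(x))
        return out[0] if single else out

    @property
    def test_mae(self) -> float:
        return self.report.test_mae

    @property
    def test_mae_per_label(self) -> np.ndarray:
        return self.report.test_mae_per_label

    def summary(self) -> str:
        cfg = self.model.config
        ds = self.model.dataset
        scheme = ds.scheme
        names = (scheme.names if scheme is not None
                 else tuple(f"label_{i}" for i in range(ds.n_labels)))
        lines = [
            "                      DCS Regressor Results",
            "=" * 64,
            f"Input grid:        {ds.grid.shape[0]} x {ds.grid.shape[1]} "
            "(return energy x rescattering angle)",
            f"Labels:            {ds.n_labels}",
            f"Samples:           {len(ds.inputs)} "
            f"(train {len(ds.train_idx)} / val {len(ds.val_idx)} / test {len(ds.test_idx)})",
            f"Conv layers:       {list(cfg.conv_layers)}",
            f"FC stack:          depth {cfg.fc_depth}, width {cfg.fc_width}",
            f"Parameters:        {self.net.n_parameters()}",
            f"Optimizer:         {cfg.optimizer}, alpha={cfg.learning_rate}, "
            f"batch={cfg.batch_size}, epochs={cfg.epochs}, seed={cfg.seed}",
            "-" * 64,
            f"Final train MAE:   {self.report.train_mae[-1]:.5f}",
            f"Final val MAE:     {self.report.val_mae[-1]:.5f}",
            f"Test MAE:          {self.report.test_mae:.5f}",
            "-" * 64,
            "Test MAE per label:",
        ]
        for nme, v in zip(names, self.report.test_mae_per_label):
            lines.append(f"  {nme:<16s} {v:.5f}")
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """MAE-vs-epoch convergence curves (train and validation)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ep = np.arange(1, self.report.epochs + 1)
        ax.plot(ep, self.report.train_mae, label="training")
        ax.plot(ep, self.report.val_mae, label="validation")
        ax.scatter([ep[-1]], [self.report.test_mae], marker="x", color="red",
                   label="test", zorder=3)
        ax.set_xlabel("iteration number (epochs)")
        ax.set_ylabel("MAE (label units)")
        ax.legend()
        return ax

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: weights + scaling stats + config + history."""
        path = Path(path)
        meta = {
            "config": self.model.config.to_dict(),
            "input_scale": self.model._input_scale,
            "label_scale": self.model._label_scale.tolist(),
            "label_offset": self.model._label_offset.tolist(),
            "grid_shape": list(self.model.dataset.grid.shape),
            "n_labels": int(self.model.dataset.n_labels),
            "seed": self.report.seed,
            "test_mae": self.report.test_mae,
        }
        arrays = dict(self.net.state_arrays())
        arrays["_train_mae"] = self.report.train_mae
        arrays["_val_mae"] = self.report.val_mae
        arrays["_test_mae_per_label"] = self.report.test_mae_per_label
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def load_results(path, dataset: Dataset) -> DCSRegressorResults:
    """Reload a saved checkpoint against its dataset; predictions are bit-identical."""
    data = np.load(path)
    meta = json.loads(bytes(data["_meta"]).decode())
    cfg = CNNConfig.from_dict(meta["config"])
    model = DCSRegressor(dataset, cfg)
    model._input_scale = float(meta["input_scale"])
    model._label_scale = np.array(meta["label_scale"])
    model._label_offset = np.array(meta["label_offset"])
    net = build_network(cfg, tuple(meta["grid_shape"]), meta["n_labels"])
    net.load_state_arrays({k: data[k] for k in data.files if not k.startswith("_")})
    report = TrainReport(data["_train_mae"], data["_val_mae"], meta["test_mae"],
                         data["_test_mae_per_label"], meta["seed"], cfg)
    return DCSRegressorResults(model, net, report)


@dataclass
class Prediction:
    """An ensemble-retrieved structure with its error budget.

    ``labels`` is the mean prediction over the ensemble members;
    ``model_error`` the per-dimension test MAE averaged over members;
    ``experimental_error`` the Poisson-statistics contribution (zero when no
    counts map is supplied).  The total is their element-wise sum.
    """

    labels: np.ndarray
    model_error: np.ndarray
    experimental_error: np.ndarray
    label_names: tuple = ()
    member_labels: np.ndarray | None = None

    @property
    def total_error(self) -> np.ndarray:
        return self.model_error + self.experimental_error

    def to_frame(self) -> pd.DataFrame:
        names = (self.label_names if self.label_names
                 else tuple(f"label_{i}" for i in range(len(self.labels))))
        return pd.DataFrame({"parameter": names, "value": self.labels,
                             "model_error": self.model_error,
                             "experimental_error": self.experimental_error,
                             "total_error": self.total_error})

    def __str__(self) -> str:
        rows = ["Retrieved structure (value +- model + experimental error):"]
        for _, r in self.to_frame().iterrows():
            rows.append(f"  {r['parameter']:<16s} {r['value']:8.3f} "
                        f"+- {r['total_error']:.3f} "
                        f"(model {r['model_error']:.3f}, "
                        f"experimental {r['experimental_error']:.3f})")
        return "\n".join(rows)


def ensemble_retrieve(dataset_builder, config: CNNConfig, seeds,
                      input_map: DiffMap | np.ndarray,
                      label_names: tuple = ()) -> tuple[Prediction, list[DCSRegressorResults]]:
    """Retrieve a structure with an ensemble of independently trained models.

    ``dataset_builder(seed)`` must return the Dataset for that training
    occasion (independent shuffles/splits); one model is trained per seed
    (the seed also drives weight initialization and batch order).  The
    retrieved labels are the mean member prediction and the model error is
    the per-dimension test MAE averaged over members.  The experimental-error
    component is filled in separately by :func:`liednet.evaluate.error_budget`.
    """
    seeds = list(seeds)
    if len(seeds) < 2:
        raise ValueError("an ensemble needs at least 2 members")
    members = []
    for s in seeds:
        ds = dataset_builder(int(s))
        cfg = CNNConfig.from_dict({**config.to_dict(), "seed": int(s)})
        members.append(DCSRegressor(ds, cfg).fit())
    preds = np.stack([m.predict(input_map) for m in members])
    model_error = np.mean([m.test_mae_per_label for m in members], axis=0)
    pred = Prediction(labels=preds.mean(axis=0), model_error=model_error,
                      experimental_error=np.zeros_like(model_error),
                      label_names=tuple(label_names), member_labels=preds)
    return pred, members
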