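"""The 4-block 2D CNN for binary ischemia classification.

Architecture: four [3x3 conv, stride 2x2, ReLU, 'same' padding -> 2x2 max
pool] blocks with 12/16/32/64 filters, so a 256x256 input is halved eight
times (256 -> 128 -> 64 -> 32 -> 16 -> 8 -> 4 -> 2 -> 1) down to 1x1x64;
then flatten(64) -> dense 512 (ReLU) -> dense 128 (ReLU) -> dense 1 with a
sigmoid output and L2(0.1) kernel regularization on the output layer only.
Total: 124,289 trainable parameters.

Training: SGD (lr 0.005, decay 1e-8, momentum 0.9), class-weighted binary
cross-entropy (weight 1 for non-ischemic, 3 for ischemic), batch size 20,
35 epochs, training data reshuffled every epoch, no early stopping and no
checkpoint selection — the monitored metric (AUC by default, ACC as an
alternative) is recorded per epoch but never steers optimization. The
decision rule is sigmoid output > 0.5, with the tie at exactly 0.5 going
to non-ischemic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .data import LabeledCase, PolarMapImage
from .network import (
    SGD,
    Conv2D,
    Dense,
    Flatten,
    MaxPool2D,
    sigmoid,
    weighted_bce_with_logits,
)
from .synth import ConfigError


@dataclass(frozen=True)
class TrainingConfig:
    filters: tuple = (12, 16, 32, 64)
    kernel: int = 3
    conv_stride: int = 2
    pool_window: int = 2
    fc_sizes: tuple = (512, 128)
    l2_penalty_output: float = 0.1
    learning_rate: float = 0.005
    decay: float = 1e-8
    momentum: float = 0.9
    monitored_metric: str = "AUC"  # or "ACC"
    batch_size: int = 20
    epochs: int = 35
    class_weights: dict = field(default_factory=lambda: {0: 1.0, 1: 3.0})
    shuffle_each_epoch: bool = True
    decision_threshold: float = 0.5
    input_size: int = 256
    seed: int = 0

    def validate(self) -> "TrainingConfig":
        if len(self.filters) != 4 or list(self.filters) != sorted(
            set(self.filters)
        ):
            raise ConfigError("filters must be strictly increasing, length 4")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ConfigError("decision_threshold must lie in (0, 1)")
        if self.monitored_metric not in ("AUC", "ACC"):
            raise ConfigError("monitored_metric must be 'AUC' or 'ACC'")
        s = self.input_size
        for _ in self.filters:
            s = -(-s // self.conv_stride)  # conv, 'same'
            if s % self.pool_window:
                raise ConfigError(
                    f"input size {self.input_size} is not reducible to 1x1 "
                    "by the stride/pool cascade"
                )
            s //= self.pool_window
        if s != 1:
            raise ConfigError(
                f"input size {self.input_size} is not reducible to 1x1 "
                "by the stride/pool cascade"
            )
        return self


@dataclass
class ModelHandle:
    """Opaque trained-model reference plus its shape/parameter ledger."""

    layers: list
    layer_shape_report: list
    parameter_count: int
    config: TrainingConfig
    trained: bool = False


def build_model(config: TrainingConfig) -> ModelHandle:
    """Construct the network with seeded Glorot-uniform initialization."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    layers = []
    report = []
    shape = (config.input_size, config.input_size, 3)
    report.append(("input", shape))
    in_ch = 3
    for f in config.filters:
        conv = Conv2D(
            in_ch, f, kernel=config.kernel, stride=config.conv_stride, rng=rng
        )
        layers.append(conv)
        shape = conv.out_shape(shape)
        report.append((conv.name, shape))
        pool = MaxPool2D(config.pool_window)
        layers.append(pool)
        shape = pool.out_shape(shape)
        report.append((f"maxpool_{f}", shape))
        in_ch = f
    flat = Flatten()
    layers.append(flat)
    shape = flat.out_shape(shape)
    report.append(("flatten", shape))
    dim = shape[0]
    for units in config.fc_sizes:
        fc = Dense(dim, units, relu=True, rng=rng)
        layers.append(fc)
        report.append((fc.name, (units,)))
        dim = units
    out = Dense(dim, 1, relu=False, l2=config.l2_penalty_output, rng=rng)
    out.name = "dense_out_sigmoid"
    layers.append(out)
    report.append(("dense_out_sigmoid", (1,)))
    n_params = sum(l.n_params for l in layers)
    return ModelHandle(layers, report, n_params, config)


def stack_cases(cases) -> tuple[np.ndarray, np.ndarray]:
    """Stack LabeledCases (or PolarMapImages) into (X, y) float32 arrays."""
    xs, ys = [], []
    for c in cases:
        if isinstance(c, LabeledCase):
            xs.append(c.image.pixels)
            ys.append(c.label)
        elif isinstance(c, PolarMapImage):
            xs.append(c.pixels)
            ys.append(0)
        else:
            xs.append(np.asarray(c, dtype=np.float32))
            ys.append(0)
    return np.stack(xs), np.asarray(ys, dtype=np.float32)


def _forward(model, X, training=False, batch=64):
    outs = []
    for i in range(0, X.shape[0], batch):
        z = X[i : i + batch]
        for layer in model.layers:
            z = layer.forward(z, training=training)
        outs.append(z)
    return np.concatenate(outs)


def predict_proba(model: ModelHandle, images) -> np.ndarray:
    """Sigmoid outputs in (0, 1) for a list of preprocessed images."""
    X, _ = stack_cases(images)
    if X.shape[1:] != (model.config.input_size, model.config.input_size, 3):
        raise ValueError(
            f"image shape {X.shape[1:]} does not match the model input "
            f"({model.config.input_size}, {model.config.input_size}, 3)"
        )
    return sigmoid(_forward(model, X)).ravel()


def predict(model: ModelHandle, images, threshold: float | None = None):
    """Hard labels: 1 iff sigmoid output > threshold (a tie yields 0)."""
    thr = model.config.decision_threshold if threshold is None else threshold
    return (predict_proba(model, images) > thr).astype(int)


def _monitor(metric: str, y, p, threshold: float) -> float:
    if len(np.unique(y)) < 2:
        return float("nan")
    if metric == "AUC":
        return float(roc_auc_score(y, p))
    return float(np.mean((p > threshold).astype(int) == y))


def train(
    model: ModelHandle,
    train_cases,
    val_cases=None,
    config: TrainingConfig | None = None,
):
    """Fit for exactly ``config.epochs`` epochs; returns (model, history).

    The history has one row per epoch: class-weighted training loss
    (including the L2 penalty), the monitored metric on the training set,
    and — when a validation set is given — unweighted validation loss and
    the monitored metric on it. The final model is simply the weights
    after the last epoch.
    """
    config = (config or model.config).validate()
    X, y = stack_cases(train_cases)
    if len(np.unique(y)) < 2:
        raise ValueError(
            "training set contains a single class; weighted binary "
            "cross-entropy is degenerate"
        )
    Xv, yv = (None, None) if not val_cases else stack_cases(val_cases)
    cw = config.class_weights
    weights = np.where(y == 1, cw.get(1, 1.0), cw.get(0, 1.0))
    out_layer = model.layers[-1]
    opt = SGD(
        model.layers,
        lr=config.learning_rate,
        momentum=config.momentum,
        decay=config.decay,
    )
    shuffle_rng = np.random.default_rng([config.seed, 1])
    history = []
    n = X.shape[0]
    for epoch in range(config.epochs):
        order = (
            shuffle_rng.permutation(n)
            if config.shuffle_each_epoch
            else np.arange(n)
        )
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            z = X[idx]
            for layer in model.layers:
                z = layer.forward(z, training=True)
            loss, dz = weighted_bce_with_logits(z, y[idx], weights[idx])
            loss += out_layer.penalty()
            grad = dz
            for layer in reversed(model.layers):
                grad = layer.backward(grad)
            opt.step()
            losses.append(loss)
        p_train = sigmoid(_forward(model, X)).ravel()
        row = {
            "epoch": epoch + 1,
            "loss": float(np.mean(losses)),
            "metric": _monitor(
                config.monitored_metric, y, p_train, config.decision_threshold
            ),
        }
        if Xv is not None:
            zv = _forward(model, Xv).ravel()
            val_loss, _ = weighted_bce_with_logits(zv, yv)
            row["val_loss"] = val_loss + out_layer.penalty()
            row["val_metric"] = _monitor(
                config.monitored_metric,
                yv,
                sigmoid(zv),
                config.decision_threshold,
            )
        history.append(row)
    model.trained = True
    return model, pd.DataFrame(history)


def save_weights(model: ModelHandle, path) -> None:
    """Serialize trainable parameters to a .npz checkpoint."""
    arrays = {}
    for i, layer in enumerate(model.layers):
        for j, p in enumerate(layer.params):
            arrays[f"layer{i}_param{j}"] = p
    np.savez(path, **arrays)


def load_weights(model: ModelHandle, path) -> ModelHandle:
    with np.load(path) as data:
        for i, layer in enumerate(model.layers):
            for j, p in enumerate(layer.params):
                p[...] = data[f"layer{i}_param{j}"]
    model.trained = True
    return model
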