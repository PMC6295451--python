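"""A minimal convolutional network for 1-s EEG epochs.

Architecture (three layers, fixed):

1. valid 2-D cross-correlation of the channels x width input grid with
   6 kernels of 5 x 5, stride 1, plus a per-map bias — the kernels mix
   5 adjacent channels and 5 adjacent samples (or frequency bins);
2. non-overlapping 2 x 2 mean pooling (odd trailing row/column
   truncated);
3. a fully connected layer with sigmoid activation producing one score
   per class in (0, 1).

Training minimizes the mean squared error between the sigmoid scores
and one-hot targets with plain minibatch SGD. There is deliberately no
nonlinearity between convolution and pooling (a sigmoid there can be
enabled via ``conv_sigmoid``, default off), no weight decay, dropout or
momentum: the structure is kept as small as possible so it can be
trained on the modest per-patient epoch counts seizure data provides.

Inputs are standardized per feature (per channel x column position)
with mean and standard deviation estimated on the training data only;
the statistics are stored in the model and applied at prediction time.

All forward and backward passes are exact, analytic, and implemented
with vectorized numpy; gradients are validated against central finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ConfigurationError, DataError

__all__ = [
    "CNNConfig",
    "CNNModel",
    "TrainTrace",
    "init_model",
    "conv_forward",
    "mean_pool",
    "fc_forward",
    "forward",
    "mse_loss",
    "backward",
    "train",
    "predict",
    "predict_batch",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class CNNConfig:
    """Architecture plus training hyperparameters.

    ``input_shape`` is (channels, width) of one input grid; width is the
    number of samples (time domain) or frequency bins (frequency domain).
    """

    input_shape: tuple[int, int]
    n_classes: int
    n_maps: int = 6
    kernel_size: int = 5
    stride: int = 1
    pool_size: int = 2
    learning_rate: float = 0.01
    batch_size: int = 16
    max_epochs: int = 100
    tol: float = 1e-5
    patience: int = 10
    conv_sigmoid: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        c, w = self.input_shape
        k = self.kernel_size
        if self.stride != 1:
            raise ConfigurationError("only stride 1 is supported")
        if c < k or w < k:
            raise ConfigurationError(
                f"input {c}x{w} smaller than the {k}x{k} kernel in some dimension"
            )
        if self.n_classes not in (2, 3):
            raise ConfigurationError("n_classes must be 2 or 3")
        ph, pw = self.pooled_shape
        if ph < 1 or pw < 1:
            raise ConfigurationError(
                f"input {c}x{w} too small: pooled feature map would be {ph}x{pw}"
            )

    @property
    def conv_shape(self) -> tuple[int, int]:
        c, w = self.input_shape
        k = self.kernel_size
        return c - k + 1, w - k + 1

    @property
    def pooled_shape(self) -> tuple[int, int]:
        ch, cw = self.conv_shape
        return ch // self.pool_size, cw // self.pool_size

    @property
    def n_features(self) -> int:
        ph, pw = self.pooled_shape
        return self.n_maps * ph * pw


@dataclass
class CNNModel:
    """Trained or initialized weights plus the architecture they realize."""

    kernels: np.ndarray  # (n_maps, k, k)
    conv_bias: np.ndarray  # (n_maps,)
    fc_weights: np.ndarray  # (n_classes, n_features)
    fc_bias: np.ndarray  # (n_classes,)
    config: CNNConfig
    norm_mean: np.ndarray | None = None  # (channels, width)
    norm_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        cfg = self.config
        k = cfg.kernel_size
        if self.kernels.shape != (cfg.n_maps, k, k):
            raise ConfigurationError(f"kernel shape {self.kernels.shape} inconsistent with config")
        if self.fc_weights.shape != (cfg.n_classes, cfg.n_features):
            raise ConfigurationError(
                f"fc weight shape {self.fc_weights.shape} != "
                f"({cfg.n_classes}, {cfg.n_features})"
            )


@dataclass
class TrainTrace:
    """Per-epoch mean squared error of the training run."""

    mse: list[float] = field(default_factory=list)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_model(config: CNNConfig) -> CNNModel:
    """Seeded uniform Glorot initialization of all weights; biases zero."""
    rng = np.random.default_rng(config.seed)
    k = config.kernel_size
    kernels = _glorot(rng, (config.n_maps, k, k), k * k, config.n_maps * k * k)
    fc_w = _glorot(rng, (config.n_classes, config.n_features), config.n_features, config.n_classes)
    return CNNModel(
        kernels=kernels,
        conv_bias=np.zeros(config.n_maps),
        fc_weights=fc_w,
        fc_bias=np.zeros(config.n_classes),
        config=config,
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        return x[None, ...], True
    if x.ndim == 3:
        return x, False
    raise DataError(f"expected a (channels, width) grid or a batch of them, got ndim={x.ndim}")


def _conv_batch(x: np.ndarray, kernels: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Valid cross-correlation, stride 1: (N,C,W) -> (N,M,C-k+1,W-k+1)."""
    k = kernels.shape[-1]
    if x.shape[1] < k or x.shape[2] < k:
        raise DataError(f"input {x.shape[1:]} smaller than {k}x{k} kernel")
    win = sliding_window_view(x, (k, k), axis=(1, 2))  # (N, oh, ow, k, k)
    out = np.einsum("nijab,mab->nmij", win, kernels, optimize=True)
    return out + bias[None, :, None, None]


def conv_forward(x: np.ndarray, model: CNNModel) -> np.ndarray:
    """Convolution layer output for one input grid: (n_maps, C-4, W-4)."""
    xb, single = _as_batch(x)
    out = _conv_batch(xb, model.kernels, model.conv_bias)
    if model.config.conv_sigmoid:
        out = _sigmoid(out)
    return out[0] if single else out


def mean_pool(maps: np.ndarray, pool: int = 2) -> np.ndarray:
    """Non-overlapping ``pool x pool`` averaging of the last two axes."""
    maps = np.asarray(maps, dtype=np.float64)
    h, w = maps.shape[-2], maps.shape[-1]
    ph, pw = h // pool, w // pool
    if ph < 1 or pw < 1:
        raise DataError(f"map {h}x{w} too small for {pool}x{pool} pooling")
    trimmed = maps[..., : ph * pool, : pw * pool]
    # accumulate block elements in row-major order so the result is
    # bitwise identical to a per-block loop
    acc = np.zeros(trimmed.shape[:-2] + (ph, pw))
    for a in range(pool):
        for b in range(pool):
            acc += trimmed[..., a::pool, b::pool]
    return acc / (pool * pool)


def fc_forward(pooled: np.ndarray, model: CNNModel) -> np.ndarray:
    """Sigmoid class scores from pooled feature maps."""
    flat = np.asarray(pooled, dtype=np.float64).reshape(-1)
    if flat.shape[0] != model.config.n_features:
        raise DataError(
            f"flattened dimension {flat.shape[0]} != fc input {model.config.n_features}"
        )
    return _sigmoid(model.fc_weights @ flat + model.fc_bias)


def _forward_batch(model: CNNModel, x: np.ndarray) -> dict[str, np.ndarray]:
    """All intermediate activations for a batch (used by backward)."""
    cfg = model.config
    pre = _conv_batch(x, model.kernels, model.conv_bias)
    act = _sigmoid(pre) if cfg.conv_sigmoid else pre
    pooled = mean_pool(act, cfg.pool_size)
    flat = pooled.reshape(x.shape[0], -1)
    z = flat @ model.fc_weights.T + model.fc_bias
    scores = _sigmoid(z)
    return {"pre": pre, "act": act, "pooled": pooled, "flat": flat, "scores": scores}


def forward(model: CNNModel, x: np.ndarray) -> np.ndarray:
    """Class scores in (0,1)^n_classes for one (channels x width) grid."""
    xb, single = _as_batch(x)
    scores = _forward_batch(model, xb)["scores"]
    return scores[0] if single else scores


def mse_loss(scores: np.ndarray, target: np.ndarray) -> float:
    """Mean over classes of squared error between scores and one-hot target."""
    scores = np.asarray(scores, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if scores.shape != target.shape:
        raise DataError(f"score shape {scores.shape} != target shape {target.shape}")
    return float(np.mean((scores - target) ** 2))


def backward(model: CNNModel, x: np.ndarray, targets: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of the batch-mean MSE loss for every parameter group.

    ``x`` is (N, channels, width), ``targets`` (N, n_classes) one-hot.
    Returns a dict with keys ``kernels``, ``conv_bias``, ``fc_weights``,
    ``fc_bias`` matching the model arrays in shape.
    """
    x = np.asarray(x, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if x.ndim != 3:
        raise DataError("backward expects a batch (N, channels, width)")
    if targets.shape != (x.shape[0], model.config.n_classes):
        raise DataError(
            f"target shape {targets.shape} != ({x.shape[0]}, {model.config.n_classes})"
        )
    cfg = model.config
    n = x.shape[0]
    cache = _forward_batch(model, x)
    scores, flat, act = cache["scores"], cache["flat"], cache["act"]

    # loss = mean_batch mean_class (s - y)^2
    d_scores = 2.0 * (scores - targets) / (cfg.n_classes * n)
    d_z = d_scores * scores * (1.0 - scores)
    g_fc_w = d_z.T @ flat
    g_fc_b = d_z.sum(axis=0)

    d_flat = d_z @ model.fc_weights
    ph, pw = cfg.pooled_shape
    d_pooled = d_flat.reshape(n, cfg.n_maps, ph, pw)

    # distribute pooling gradient evenly over each 2x2 block; truncated
    # trailing rows/columns receive zero gradient
    ch, cw = cfg.conv_shape
    p = cfg.pool_size
    d_act = np.zeros((n, cfg.n_maps, ch, cw))
    up = np.repeat(np.repeat(d_pooled, p, axis=2), p, axis=3) / (p * p)
    d_act[:, :, : ph * p, : pw * p] = up

    d_pre = d_act * act * (1.0 - act) if cfg.conv_sigmoid else d_act

    k = cfg.kernel_size
    win = sliding_window_view(x, (k, k), axis=(1, 2))  # (N, ch, cw, k, k)
    g_kernels = np.einsum("nijab,nmij->mab", win, d_pre, optimize=True)
    g_conv_b = d_pre.sum(axis=(0, 2, 3))

    return {
        "kernels": g_kernels,
        "conv_bias": g_conv_b,
        "fc_weights": g_fc_w,
        "fc_bias": g_fc_b,
    }


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


def train(
    x: np.ndarray, y: np.ndarray, config: CNNConfig
) -> tuple[CNNModel, TrainTrace]:
    """Fit the network with seeded minibatch SGD.

    Parameters
    ----------
    x
        (N, channels, width) input grids (raw; standardization is fitted
        here and stored in the model).
    y
        (N,) integer class labels in ``[0, n_classes)``.
    config
        Architecture and optimization settings; ``config.seed`` drives
        both weight initialization and batch shuffling.

    Stops at ``max_epochs`` or when the per-epoch MSE has not improved
    by at least ``tol`` for ``patience`` consecutive epochs.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if x.ndim != 3:
        raise DataError("train expects (N, channels, width)")
    if len(x) < config.batch_size:
        raise ConfigurationError(
            f"need at least batch_size={config.batch_size} examples, got {len(x)}"
        )
    classes = np.unique(y)
    if len(classes) < config.n_classes:
        raise ConfigurationError(
            f"dataset covers {len(classes)} classes but config expects {config.n_classes}"
        )

    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    xn = (x - mean) / sd

    model = init_model(config)
    model.norm_mean, model.norm_sd = mean, sd
    rng = np.random.default_rng(config.seed)
    targets = _one_hot(y, config.n_classes)
    trace = TrainTrace()

    best = np.inf
    stale = 0
    for _ in range(config.max_epochs):
        order = rng.permutation(len(xn))
        sq_sum = 0.0
        for start in range(0, len(xn), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, tb = xn[idx], targets[idx]
            if config.learning_rate != 0.0:
                grads = backward(model, xb, tb)
                model.kernels -= config.learning_rate * grads["kernels"]
                model.conv_bias -= config.learning_rate * grads["conv_bias"]
                model.fc_weights -= config.learning_rate * grads["fc_weights"]
                model.fc_bias -= config.learning_rate * grads["fc_bias"]
            sq_sum += len(idx) * mse_loss(_forward_batch(model, xb)["scores"], tb)
        epoch_mse = sq_sum / len(xn)
        trace.mse.append(epoch_mse)
        if epoch_mse < best - config.tol:
            best = epoch_mse
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    return model, trace


def _normalize(model: CNNModel, x: np.ndarray) -> np.ndarray:
    if model.norm_mean is None:
        return x
    return (x - model.norm_mean) / model.norm_sd


def predict_batch(model: CNNModel, x: np.ndarray) -> np.ndarray:
    """Predicted integer labels for a batch of raw input grids."""
    xb, single = _as_batch(x)
    scores = _forward_batch(model, _normalize(model, xb))["scores"]
    labels = np.argmax(scores, axis=1)  # argmax ties break toward the lowest index
    return labels[0] if single else labels


def predict(model: CNNModel, x: np.ndarray) -> int:
    """Predicted class index for one epoch grid (ties -> lowest index)."""
    return int(predict_batch(model, np.asarray(x)))


def save_model(model: CNNModel, path: str | Path) -> None:
    """Write all weights, config, and normalization statistics to HDF5."""
    import h5py

    cfg = model.config
    with h5py.File(path, "w") as fh:
        fh["kernels"] = model.kernels
        fh["conv_bias"] = model.conv_bias
        fh["fc_weights"] = model.fc_weights
        fh["fc_bias"] = model.fc_bias
        if model.norm_mean is not None:
            fh["norm_mean"] = model.norm_mean
            fh["norm_sd"] = model.norm_sd
        for key in (
            "n_maps",
            "kernel_size",
            "stride",
            "pool_size",
            "n_classes",
            "learning_rate",
            "batch_size",
            "max_epochs",
            "tol",
            "patience",
            "seed",
        ):
            fh.attrs[key] = getattr(cfg, key)
        fh.attrs["conv_sigmoid"] = int(cfg.conv_sigmoid)
        fh.attrs["input_shape"] = cfg.input_shape


def load_model(path: str | Path) -> CNNModel:
    """Inverse of :func:`save_model`."""
    import h5py

    with h5py.File(path, "r") as fh:
        a = fh.attrs
        cfg = CNNConfig(
            input_shape=tuple(int(v) for v in a["input_shape"]),
            n_classes=int(a["n_classes"]),
            n_maps=int(a["n_maps"]),
            kernel_size=int(a["kernel_size"]),
            stride=int(a["stride"]),
            pool_size=int(a["pool_size"]),
            learning_rate=float(a["learning_rate"]),
            batch_size=int(a["batch_size"]),
            max_epochs=int(a["max_epochs"]),
            tol=float(a["tol"]),
            patience=int(a["patience"]),
            conv_sigmoid=bool(a["conv_sigmoid"]),
            seed=int(a["seed"]),
        )
        model = CNNModel(
            kernels=fh["kernels"][()],
            conv_bias=fh["conv_bias"][()],
            fc_weights=fh["fc_weights"][()],
            fc_bias=fh["fc_bias"][()],
            config=cfg,
            norm_mean=fh["norm_mean"][()] if "norm_mean" in fh else None,
            norm_sd=fh["norm_sd"][()] if "norm_sd" in fh else None,
        )
    return model

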