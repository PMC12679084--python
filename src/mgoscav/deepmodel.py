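"""The DeepMGO network: a concentration-aware 1-D convolutional regressor.

The descriptor vector of a compound is treated as a 1-D signal and passed
through three convolutional blocks (cross-correlation + per-kernel bias +
batch normalization + activation),

    conv(x)_{jm} = F( B( sum_l w^m_l * x_{j*stride + l} + b_m ) ),

then flattened into a dense layer.  The assay concentration (µM) enters a
separate small dense branch; the two representations are concatenated and
two further dense layers produce the scalar MGO scavenging activity score
(Z-scale).  Training minimizes the per-batch root-mean-square error with
Adam for a fixed number of epochs, no early stopping.

Everything is plain NumPy with explicit backpropagation, which keeps the
model deterministic bit-for-bit under a fixed seed on a single CPU.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .assaydata import DescriptorTable, ModelArrays, NormalizationState

__all__ = [
    "ConvBlockSpec",
    "DeepMGOSpec",
    "TrainConfig",
    "TrainedModel",
    "PredictionSet",
    "ConcentrationScaler",
    "conv_block_forward",
    "build_deepmgo",
    "build_network",
    "count_trainable_parameters",
    "train_model",
    "predict_scores",
    "reference_spec",
    "compact_spec",
    "deepic50_like_spec",
    "resnet18_like_spec",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS_BN = 1e-5


# ---------------------------------------------------------------------------
# specs


@dataclass
class ConvBlockSpec:
    """One convolutional block: M kernels of length L, per-kernel bias.

    The bias is shared across output positions (per kernel), the standard
    convention for convolutional layers.
    """

    n_kernels: int
    kernel_length: int
    stride: int = 1
    activation: str = "relu"
    batch_norm: bool = True
    weights: np.ndarray | None = None  # (M, L, in_channels), optional explicit
    bias: np.ndarray | None = None  # (M,)

    def __post_init__(self) -> None:
        if self.kernel_length < 1 or self.stride < 1 or self.n_kernels < 1:
            raise ValueError("kernel_length, stride and n_kernels must be >= 1")
        if self.activation not in ("relu", "tanh", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")

    def out_length(self, in_length: int) -> int:
        if in_length < self.kernel_length:
            raise ValueError(
                f"input length {in_length} shorter than kernel length {self.kernel_length}"
            )
        return (in_length - self.kernel_length) // self.stride + 1


@dataclass
class DeepMGOSpec:
    """Architecture: 3 conv blocks and 3 dense layers on the main path,
    with the concentration joining through its own dense branch."""

    input_width: int
    conv_blocks: list[ConvBlockSpec]
    feature_dense_width: int
    concentration_dense_width: int
    head_widths: tuple[int, int]
    activation: str = "relu"

    def validate(self) -> None:
        if len(self.conv_blocks) != 3:
            raise ValueError(f"DeepMGO requires exactly 3 conv blocks, got {len(self.conv_blocks)}")
        if len(self.head_widths) != 2 or self.head_widths[-1] != 1:
            raise ValueError("head must be exactly 2 dense layers ending in a scalar output")

    def to_dict(self) -> dict:
        return {
            "input_width": self.input_width,
            "conv_blocks": [
                {
                    "n_kernels": b.n_kernels,
                    "kernel_length": b.kernel_length,
                    "stride": b.stride,
                    "activation": b.activation,
                    "batch_norm": b.batch_norm,
                }
                for b in self.conv_blocks
            ],
            "feature_dense_width": self.feature_dense_width,
            "concentration_dense_width": self.concentration_dense_width,
            "head_widths": list(self.head_widths),
            "activation": self.activation,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "DeepMGOSpec":
        return cls(
            input_width=int(obj["input_width"]),
            conv_blocks=[ConvBlockSpec(**b) for b in obj["conv_blocks"]],
            feature_dense_width=int(obj["feature_dense_width"]),
            concentration_dense_width=int(obj["concentration_dense_width"]),
            head_widths=tuple(obj["head_widths"]),
            activation=obj.get("activation", "relu"),
        )


def reference_spec(input_width: int = 2756, activation: str = "relu") -> DeepMGOSpec:
    """The reference DeepMGO architecture (~0.22 M parameters at p=2,756)."""
    return DeepMGOSpec(
        input_width=input_width,
        conv_blocks=[
            ConvBlockSpec(32, 8, 2, activation, True),
            ConvBlockSpec(16, 8, 2, activation, True),
            ConvBlockSpec(8, 8, 2, activation, True),
        ],
        feature_dense_width=77,
        concentration_dense_width=16,
        head_widths=(64, 1),
        activation=activation,
    )


def compact_spec(input_width: int, activation: str = "tanh") -> DeepMGOSpec:
    """A narrower DeepMGO for moderate descriptor widths (synthetic studies).

    tanh is the default here: on smooth saturating dose-response targets it
    trains markedly better than relu at this width; relu remains available.
    """
    return DeepMGOSpec(
        input_width=input_width,
        conv_blocks=[
            ConvBlockSpec(32, 8, 2, activation, True),
            ConvBlockSpec(16, 8, 2, activation, True),
            ConvBlockSpec(8, 8, 2, activation, True),
        ],
        feature_dense_width=64,
        concentration_dense_width=16,
        head_widths=(32, 1),
        activation=activation,
    )


def deepic50_like_spec(input_width: int) -> DeepMGOSpec:
    """Wider comparator preset (a larger-capacity conv net, not a port)."""
    return DeepMGOSpec(
        input_width=input_width,
        conv_blocks=[
            ConvBlockSpec(64, 8, 1, "relu", True),
            ConvBlockSpec(64, 8, 2, "relu", True),
            ConvBlockSpec(32, 8, 2, "relu", True),
        ],
        feature_dense_width=256,
        concentration_dense_width=16,
        head_widths=(128, 1),
    )


def resnet18_like_spec(input_width: int) -> DeepMGOSpec:
    """Deep/wide comparator preset in the same generic trainer."""
    return DeepMGOSpec(
        input_width=input_width,
        conv_blocks=[
            ConvBlockSpec(64, 7, 2, "relu", True),
            ConvBlockSpec(128, 3, 2, "relu", True),
            ConvBlockSpec(256, 3, 2, "relu", True),
        ],
        feature_dense_width=512,
        concentration_dense_width=16,
        head_widths=(256, 1),
    )


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 50
    learning_rate: float = 2e-4
    optimizer: str = "adam"
    loss: str = "rmse"
    seed: int = 0
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss != "rmse":
            raise ValueError("only the rmse loss is supported")


@dataclass
class PredictionSet:
    observed: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.observed.shape != self.predicted.shape:
            raise ValueError("observed/predicted length mismatch")

    @property
    def n(self) -> int:
        return self.observed.size


# ---------------------------------------------------------------------------
# functional Eq.-1 forward pass (contract surface, used by tests and layers)


def conv_block_forward(
    x: np.ndarray,
    spec: ConvBlockSpec,
    batch_norm_fn=None,
) -> np.ndarray:
    """Forward pass of one conv block on explicit weights.

    ``x`` is ``(length, in_channels)`` or ``(batch, length, in_channels)``;
    returns the same arrangement with ``n_kernels`` output channels.  With
    ``batch_norm_fn=None`` and identity activation this is plain
    cross-correlation plus the per-kernel bias.
    """
    if spec.weights is None or spec.bias is None:
        raise ValueError("conv_block_forward needs explicit weights and bias in the spec")
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    n, in_len, in_ch = x.shape
    W = np.asarray(spec.weights, dtype=float)
    b = np.asarray(spec.bias, dtype=float)
    if W.shape != (spec.n_kernels, spec.kernel_length, in_ch):
        raise ValueError(f"weights shape {W.shape} does not match spec/in_channels {in_ch}")
    out_len = spec.out_length(in_len)
    idx = np.arange(out_len)[:, None] * spec.stride + np.arange(spec.kernel_length)[None, :]
    cols = x[:, idx, :]  # (n, out_len, L, in_ch)
    out = np.einsum("nolc,mlc->nom", cols, W) + b
    if batch_norm_fn is not None:
        out = batch_norm_fn(out)
    out = _activate(out, spec.activation)
    return out[0] if squeeze else out


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "tanh":
        return np.tanh(z)
    return z


# ---------------------------------------------------------------------------
# layers with backprop


class _Layer:
    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, grad) triples; grad arrays are reused in place."""
        return []


class _Conv1D(_Layer):
    def __init__(self, in_ch: int, spec: ConvBlockSpec, rng: np.random.Generator):
        self.spec = spec
        fan_in = spec.kernel_length * in_ch
        self.W = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(spec.n_kernels, spec.kernel_length, in_ch))
        self.b = np.zeros(spec.n_kernels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        s = self.spec
        out_len = s.out_length(x.shape[1])
        idx = np.arange(out_len)[:, None] * s.stride + np.arange(s.kernel_length)[None, :]
        self._x_shape = x.shape
        self._idx = idx
        self._cols = x[:, idx, :]
        return np.einsum("nolc,mlc->nom", self._cols, self.W) + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[...] = np.einsum("nolc,nom->mlc", self._cols, dout)
        self.db[...] = dout.sum(axis=(0, 1))
        dcols = np.einsum("nom,mlc->nolc", dout, self.W)
        dx = np.zeros(self._x_shape)
        s = self.spec
        starts = np.arange(dout.shape[1]) * s.stride
        for l in range(s.kernel_length):
            dx[:, starts + l, :] += dcols[:, :, l, :]
        return dx

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class _BatchNorm1D(_Layer):
    """Per-channel normalization over batch and position axes."""

    def __init__(self, n_ch: int, momentum: float = 0.9):
        self.gamma = np.ones(n_ch)
        self.beta = np.zeros(n_ch)
        self.dgamma = np.zeros(n_ch)
        self.dbeta = np.zeros(n_ch)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum = momentum

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._inv = 1.0 / np.sqrt(var + _EPS_BN)
        self._xhat = (x - mu) * self._inv
        self._train = train
        return self.gamma * self._xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = tuple(range(dout.ndim - 1))
        self.dgamma[...] = (dout * self._xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        if not self._train:
            return dxhat * self._inv
        nt = np.prod([dout.shape[a] for a in axes])
        return (
            self._inv
            / nt
            * (nt * dxhat - dxhat.sum(axis=axes) - self._xhat * (dxhat * self._xhat).sum(axis=axes))
        )

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]


class _Activation(_Layer):
    def __init__(self, kind: str):
        self.kind = kind

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        self._y = _activate(x, self.kind)
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.kind == "relu":
            return dout * (self._x > 0)
        if self.kind == "tanh":
            return dout * (1.0 - self._y**2)
        return dout


class _Flatten(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


# ---------------------------------------------------------------------------
# the network


class Network:
    """Generic conv-net with a concentration branch (DeepMGO's shape family)."""

    def __init__(self, spec: DeepMGOSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.feature_layers: list[_Layer] = []
        in_ch, length = 1, spec.input_width
        for block in spec.conv_blocks:
            self.feature_layers.append(_Conv1D(in_ch, block, rng))
            if block.batch_norm:
                self.feature_layers.append(_BatchNorm1D(block.n_kernels))
            self.feature_layers.append(_Activation(block.activation))
            length = block.out_length(length)
            in_ch = block.n_kernels
        self.feature_layers.append(_Flatten())
        self.feature_layers.append(_Dense(length * in_ch, spec.feature_dense_width, rng))
        self.feature_layers.append(_Activation(spec.activation))

        self.conc_layers: list[_Layer] = [
            _Dense(1, spec.concentration_dense_width, rng),
            _Activation(spec.activation),
        ]
        concat = spec.feature_dense_width + spec.concentration_dense_width
        self.head_layers: list[_Layer] = [
            _Dense(concat, spec.head_widths[0], rng),
            _Activation(spec.activation),
            _Dense(spec.head_widths[0], spec.head_widths[1], rng),
        ]

    def _layers(self) -> list[_Layer]:
        return self.feature_layers + self.conc_layers + self.head_layers

    def forward(self, X: np.ndarray, conc_scaled: np.ndarray, train: bool = False) -> np.ndarray:
        h = np.asarray(X, dtype=float)[:, :, None]  # (n, p, 1 channel)
        for layer in self.feature_layers:
            h = layer.forward(h, train)
        c = np.asarray(conc_scaled, dtype=float).reshape(-1, 1)
        for layer in self.conc_layers:
            c = layer.forward(c, train)
        self._split = h.shape[1]
        z = np.concatenate([h, c], axis=1)
        for layer in self.head_layers:
            z = layer.forward(z, train)
        return z[:, 0]

    def backward(self, dout: np.ndarray) -> None:
        g = np.asarray(dout, dtype=float)[:, None]
        for layer in reversed(self.head_layers):
            g = layer.backward(g)
        gh, gc = g[:, : self._split], g[:, self._split :]
        for layer in reversed(self.conc_layers):
            gc = layer.backward(gc)
        for layer in reversed(self.feature_layers):
            gh = layer.backward(gh)

    def parameters(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        out = []
        for i, layer in enumerate(self._layers()):
            for name, val, grad in layer.params():
                out.append((f"layer{i:02d}.{name}", val, grad))
        return out

    # serialization ---------------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: val.tolist() for name, val, _ in self.parameters()}
        for i, layer in enumerate(self._layers()):
            if isinstance(layer, _BatchNorm1D):
                state[f"layer{i:02d}.running_mean"] = layer.running_mean.tolist()
                state[f"layer{i:02d}.running_var"] = layer.running_var.tolist()
        return state

    def load_state_dict(self, state: dict) -> None:
        named = {name: val for name, val, _ in self.parameters()}
        for key, lst in state.items():
            arr = np.array(lst, dtype=float)
            if key in named:
                named[key][...] = arr
            elif key.endswith("running_mean") or key.endswith("running_var"):
                i = int(key.split(".")[0][5:])
                layer = self._layers()[i]
                setattr(layer, key.split(".")[1], arr)
            else:
                raise KeyError(f"unknown parameter {key!r} in checkpoint")


def build_deepmgo(spec: DeepMGOSpec, seed: int = 0) -> Network:
    """Build the DeepMGO network, enforcing the 3-conv / 3-dense shape."""
    spec.validate()
    return Network(spec, seed=seed)


def build_network(spec: DeepMGOSpec, seed: int = 0) -> Network:
    """Build without the DeepMGO shape constraint (comparator presets)."""
    return Network(spec, seed=seed)


def count_trainable_parameters(model: Network) -> int:
    """Weights + biases + batch-norm scale/shift (running stats excluded)."""
    return int(sum(val.size for _, val, _ in model.parameters()))


# ---------------------------------------------------------------------------
# concentration scaling


@dataclass
class ConcentrationScaler:
    """Min-max scaling of the dose input, on log10 µM by default.

    Assay doses span six orders of magnitude and potencies vary on a log
    scale, so the dose enters the network as scaled log10 concentration;
    ``log10=False`` switches to plain min-max on the linear scale.
    """

    lo: float
    hi: float
    log10: bool = True

    @classmethod
    def fit(cls, concentrations: np.ndarray, log10: bool = True) -> "ConcentrationScaler":
        c = np.asarray(concentrations, dtype=float)
        if np.any(c <= 0):
            raise ValueError("concentrations must be > 0 µM")
        t = np.log10(c) if log10 else c
        lo, hi = float(t.min()), float(t.max())
        if hi == lo:
            hi = lo + 1.0  # single training dose: map it to 0
        return cls(lo=lo, hi=hi, log10=log10)

    def transform(self, concentrations: np.ndarray) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        t = np.log10(c) if self.log10 else c
        return (t - self.lo) / (self.hi - self.lo)

    def to_dict(self) -> dict:
        return {"lo": self.lo, "hi": self.hi, "log10": self.log10}

    @classmethod
    def from_dict(cls, obj: dict) -> "ConcentrationScaler":
        return cls(lo=float(obj["lo"]), hi=float(obj["hi"]), log10=bool(obj["log10"]))


# ---------------------------------------------------------------------------
# training


class TrainingDiverged(RuntimeError):
    pass


class _Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(v) for _, v, _ in params]
        self.v = [np.zeros_like(v) for _, v, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (name, val, grad), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * grad
            v *= self.b2
            v += (1 - self.b2) * grad**2
            val -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainedModel:
    """A fitted network paired with the only statistics it may see at
    prediction time: its NormalizationState and concentration scaler."""

    network: Network
    normalization: NormalizationState
    conc_scaler: ConcentrationScaler
    train_config: TrainConfig
    history: dict = field(default_factory=dict)

    def predict_normalized(self, X_scaled: np.ndarray, concentrations: np.ndarray) -> np.ndarray:
        c = self.conc_scaler.transform(concentrations)
        return self.network.forward(X_scaled, c, train=False)


def _rmse_loss_and_grad(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    resid = pred - y
    mse = float(np.mean(resid**2))
    loss = math.sqrt(mse)
    if loss == 0.0:
        return 0.0, np.zeros_like(resid)
    return loss, resid / (resid.size * loss)


def train_model(
    model: Network,
    train: ModelArrays,
    config: TrainConfig,
    normalization: NormalizationState,
    val: ModelArrays | None = None,
    conc_scaler: ConcentrationScaler | None = None,
) -> TrainedModel:
    """Minimize per-batch sqrt(MSE) with Adam for exactly ``config.epochs``.

    ``train``/``val`` carry min-max scaled features and Z-scaled scores from
    :func:`mgoscav.assaydata.apply_normalization`.  The concentration
    scaler is fit on the training doses unless supplied.  History records
    the mean train batch loss and the full validation loss per epoch.
    """
    if conc_scaler is None:
        conc_scaler = ConcentrationScaler.fit(train.concentration)
    c_train = conc_scaler.transform(train.concentration)
    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.parameters(), lr=config.learning_rate)
    n = train.n
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            pred = model.forward(train.X[sel], c_train[sel], train=True)
            loss, dpred = _rmse_loss_and_grad(pred, train.y[sel])
            if not math.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}: learning_rate={config.learning_rate}, "
                    f"|y| scale={np.abs(train.y).max():.3g}, batch={sel.size}"
                )
            model.backward(dpred)
            opt.step()
            batch_losses.append(loss)
        history["train_loss"].append(float(np.mean(batch_losses)))
        if val is not None:
            vp = model.forward(val.X, conc_scaler.transform(val.concentration), train=False)
            history["val_loss"].append(float(np.sqrt(np.mean((vp - val.y) ** 2))))
    return TrainedModel(
        network=model,
        normalization=normalization,
        conc_scaler=conc_scaler,
        train_config=config,
        history=history,
    )


def predict_scores(
    trained: TrainedModel,
    features: DescriptorTable | np.ndarray,
    concentrations: Sequence[float] | np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Predict activity scores (Z-scale) for feature rows at given doses.

    Raw descriptor values are normalized internally with the model's paired
    NormalizationState; a feature-name mismatch is an error.  One
    concentration per row.
    """
    state = trained.normalization
    if isinstance(features, DescriptorTable):
        if list(features.feature_names) != list(state.feature_names):
            raise ValueError("descriptor columns do not match the model's NormalizationState")
        raw = features.values
    else:
        raw = np.asarray(features, dtype=float)
        if feature_names is not None and list(feature_names) != list(state.feature_names):
            raise ValueError("feature names do not match the model's NormalizationState")
        if raw.shape[1] != len(state.feature_names):
            raise ValueError(
                f"feature width {raw.shape[1]} != normalization width {len(state.feature_names)}"
            )
    conc = np.asarray(concentrations, dtype=float)
    if conc.ndim == 0:
        conc = np.full(raw.shape[0], float(conc))
    if conc.shape[0] != raw.shape[0]:
        raise ValueError("need one concentration per feature row")
    X = state.transform_features(raw)
    return trained.predict_normalized(X, conc)


# ---------------------------------------------------------------------------
# checkpoints (JSON: text-only, floats round-trip exactly via repr)


def save_checkpoint(trained: TrainedModel, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "spec": trained.network.spec.to_dict(),
        "train_config": asdict(trained.train_config),
        "normalization": trained.normalization.to_dict(),
        "conc_scaler": trained.conc_scaler.to_dict(),
        "history": trained.history,
    }
    (d / "manifest.json").write_text(json.dumps(manifest))
    (d / "weights.json").write_text(json.dumps(trained.network.state_dict()))


def load_checkpoint(directory: str | Path) -> TrainedModel:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    spec = DeepMGOSpec.from_dict(manifest["spec"])
    net = Network(spec, seed=0)
    net.load_state_dict(json.loads((d / "weights.json").read_text()))
    return TrainedModel(
        network=net,
        normalization=NormalizationState.from_dict(manifest["normalization"]),
        conc_scaler=ConcentrationScaler.from_dict(manifest["conc_scaler"]),
        train_config=TrainConfig(**manifest["train_config"]),
        history=manifest["history"],
    )
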