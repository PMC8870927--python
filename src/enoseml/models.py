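"""The five estimators: SVR, RFR, BPNN, 1-D CNN, and the CNN-RFR hybrid.

The CNN backbone is a compact stack of four ConvBNReLU blocks and three
pooling layers that maps a (10 channels, 100 s) curve matrix to a
128-dimensional feature vector:

    Conv 16@3 p1 s2 -> 16x50
    Conv 32@3 p0 s1 -> 32x48
    MaxPool 2/2     -> 32x24
    Conv 64@3 p1 s2 -> 64x12
    MaxPool 2/2     -> 64x6
    Conv 128@3 p1 s2 -> 128x3
    AvgPool 3/1     -> 128x1
    Flatten         -> 128

The full CNN regressor adds a fully-connected head (128-64 ReLU,
64-32 Sigmoid, 32-1 linear output; the explicit scalar output layer is
our reading of the architecture — a Sigmoid 32-vector cannot itself be
a regression output). Labels are fractions in [0, 1].

The hybrid trains the CNN end-to-end, freezes the backbone at a chosen
checkpoint, and fits a random-forest regressor on the extracted 128-dim
features; at inference the frozen backbone (batch-norm in inference
mode) feeds the forest.

Classical baselines (RBF-kernel SVR, random-forest regressor, a 10-21-1
backpropagation network) operate on stable-value rows and are backed by
scikit-learn estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR as _SkSVR

from . import nn
from .features import MultichannelInput

# ---------------------------------------------------------------------------
# declarative layer specs


@dataclass(frozen=True)
class ConvBlock:
    out_channels: int
    kernel: int = 3
    stride: int = 1
    padding: int = 0


@dataclass(frozen=True)
class PoolBlock:
    kind: str  # "max" or "avg"
    kernel: int
    stride: int


@dataclass(frozen=True)
class BackboneSpec:
    """Ordered conv/pool layer stack of the feature-extraction backbone."""

    layers: tuple = (
        ("Conv1", ConvBlock(16, 3, stride=2, padding=1)),
        ("Conv2", ConvBlock(32, 3, stride=1, padding=0)),
        ("Pool1", PoolBlock("max", 2, 2)),
        ("Conv3", ConvBlock(64, 3, stride=2, padding=1)),
        ("Pool2", PoolBlock("max", 2, 2)),
        ("Conv4", ConvBlock(128, 3, stride=2, padding=1)),
        ("Pool3", PoolBlock("avg", 3, 1)),
    )
    in_channels: int = 10
    in_length: int = 100


@dataclass(frozen=True)
class HeadSpec:
    """Fully-connected regression head on top of the flattened features."""

    widths: tuple[int, ...] = (64, 32)
    activations: tuple[str, ...] = ("relu", "sigmoid")


@dataclass
class RFRParams:
    """Random-forest regressor hyperparameters.

    ``max_features_frac`` is the per-node predictor-subsampling rule
    m-of-M: by default one third of the predictors, rounded up.
    """

    n_trees: int = 100
    max_depth: int | None = None
    min_samples_split: int = 2
    max_features_frac: float = 1 / 3
    bootstrap: bool = True
    seed: int = 0


@dataclass
class SVRParams:
    C: float = 1.0
    gamma: float = 1.0
    epsilon: float = 0.1


@dataclass
class BPNNSpec:
    """10-21-1 backpropagation network: ReLU hidden layer, MSE loss, SGD."""

    n_inputs: int = 10
    n_hidden: int = 21
    learning_rate: float = 0.01
    n_epochs: int = 2000
    batch_size: int = 32
    seed: int = 0


# ---------------------------------------------------------------------------
# shape arithmetic


def _conv_len(length: int, kernel: int, stride: int, padding: int,
              name: str) -> int:
    padded = length + 2 * padding
    if padded < kernel:
        raise ValueError(
            f"{name}: input length {length} (+2*{padding} padding) shorter "
            f"than kernel {kernel}"
        )
    return (padded - kernel) // stride + 1


def backbone_output_shape(
    spec: BackboneSpec | None = None,
    input_shape: tuple[int, int] | None = None,
) -> list[tuple[str, int, int]]:
    """Per-layer (name, channels, length) through the backbone, plus the
    flatten row, by pure convolution/pooling arithmetic."""
    spec = spec or BackboneSpec()
    ch, length = input_shape or (spec.in_channels, spec.in_length)
    out: list[tuple[str, int, int]] = []
    for name, block in spec.layers:
        if isinstance(block, ConvBlock):
            length = _conv_len(length, block.kernel, block.stride,
                               block.padding, name)
            ch = block.out_channels
        else:
            length = _conv_len(length, block.kernel, block.stride, 0, name)
        out.append((name, ch, length))
    out.append(("Flatten", ch * length, 1))
    return out


def feature_width(spec: BackboneSpec | None = None) -> int:
    return backbone_output_shape(spec)[-1][1]


# ---------------------------------------------------------------------------
# backbone / CNN construction


class Backbone:
    """Trainable conv/pool feature extractor."""

    def __init__(self, spec: BackboneSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        ch = spec.in_channels
        for _, block in spec.layers:
            if isinstance(block, ConvBlock):
                layers.append(nn.Conv1d(ch, block.out_channels, block.kernel,
                                        block.stride, block.padding,
                                        bias=False, rng=rng))
                layers.append(nn.BatchNorm1d(block.out_channels))
                layers.append(nn.ReLU())
                ch = block.out_channels
            elif block.kind == "max":
                layers.append(nn.MaxPool1d(block.kernel, block.stride))
            else:
                layers.append(nn.AvgPool1d(block.kernel, block.stride))
        layers.append(nn.Flatten())
        self.net = nn.Sequential(layers)
        self.n_features = feature_width(spec)

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        if x.ndim != 3 or x.shape[1:] != (self.spec.in_channels,
                                          self.spec.in_length):
            raise ValueError(
                f"expected input (batch, {self.spec.in_channels}, "
                f"{self.spec.in_length}), got {x.shape}"
            )
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(self._check(x), training)

    def extract_features(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode features (batch-norm uses running statistics)."""
        return self.forward(x, training=False)

    def state_dict(self) -> list[np.ndarray]:
        return self.net.state_dict()

    def load_state_dict(self, arrays: list[np.ndarray]) -> None:
        self.net.load_state_dict(arrays)


def build_backbone(spec: BackboneSpec | None = None, seed: int = 0) -> Backbone:
    return Backbone(spec or BackboneSpec(), seed)


class CNNRegressor:
    """Backbone + fully-connected head predicting the adulterant fraction.

    ``self.backbone`` is the live backbone object; the hybrid extracts
    it by reference, so weight updates are visible both ways.
    """

    def __init__(self, spec: BackboneSpec, head: HeadSpec, seed: int = 0):
        self.spec, self.head_spec = spec, head
        self.backbone = Backbone(spec, seed)
        rng = np.random.default_rng(seed + 1)
        acts = {"relu": nn.ReLU, "sigmoid": nn.Sigmoid}
        layers: list[nn.Layer] = []
        w_in = self.backbone.n_features
        for width, act in zip(head.widths, head.activations, strict=True):
            layers.append(nn.Linear(w_in, width, rng=rng))
            layers.append(acts[act]())
            w_in = width
        layers.append(nn.Linear(w_in, 1, rng=rng))  # linear scalar output
        self.head = nn.Sequential(layers)

    def params(self) -> list[nn.Param]:
        return self.backbone.net.params() + self.head.params()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        feats = self.backbone.forward(x, training)
        return self.head.forward(feats, training)[:, 0]

    def backward(self, grad_out: np.ndarray) -> None:
        g = self.head.backward(grad_out[:, None])
        self.backbone.net.backward(g)

    def predict(self, x: np.ndarray | MultichannelInput) -> np.ndarray:
        if isinstance(x, MultichannelInput):
            x = x.tensor
        return self.forward(np.asarray(x, float), training=False)

    def state_dict(self) -> list[np.ndarray]:
        return self.backbone.state_dict() + self.head.state_dict()

    def load_state_dict(self, arrays: list[np.ndarray]) -> None:
        n = len(self.backbone.state_dict())
        self.backbone.load_state_dict(arrays[:n])
        self.head.load_state_dict(arrays[n:])


def build_1dcnn(spec: BackboneSpec | None = None,
                head: HeadSpec | None = None, seed: int = 0) -> CNNRegressor:
    return CNNRegressor(spec or BackboneSpec(), head or HeadSpec(), seed)


# ---------------------------------------------------------------------------
# classical estimators (scikit-learn backed)


def _check_sv_width(X: np.ndarray, expected: int = 10) -> np.ndarray:
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] != expected:
        raise ValueError(
            f"expected a (n, {expected}) stable-value matrix, got {X.shape}"
        )
    return X


def make_rfr(params: RFRParams, n_features: int) -> RandomForestRegressor:
    m = max(1, int(np.ceil(params.max_features_frac * n_features)))
    return RandomForestRegressor(
        n_estimators=params.n_trees,
        max_depth=params.max_depth,
        min_samples_split=params.min_samples_split,
        max_features=m,
        bootstrap=params.bootstrap,
        random_state=params.seed,
    )


def fit_rfr(X: np.ndarray, y: np.ndarray,
            params: RFRParams | None = None) -> RandomForestRegressor:
    """Fit a random-forest regressor (bootstrap + m-of-M node subsampling)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.size == 0:
        raise ValueError("empty input")
    params = params or RFRParams()
    forest = make_rfr(params, X.shape[1])
    forest.fit(X, y)
    return forest


def fit_svr(X: np.ndarray, y: np.ndarray,
            params: SVRParams | None = None) -> _SkSVR:
    """Fit an epsilon-insensitive RBF-kernel SVR on stable-value rows."""
    X = _check_sv_width(X)
    params = params or SVRParams()
    model = _SkSVR(kernel="rbf", C=params.C, gamma=params.gamma,
                   epsilon=params.epsilon)
    model.fit(X, np.asarray(y, float))
    return model


def fit_bpnn(X: np.ndarray, y: np.ndarray,
             spec: BPNNSpec | None = None) -> MLPRegressor:
    """Fit the 10-21-1 backpropagation network (ReLU, MSE, SGD)."""
    spec = spec or BPNNSpec()
    X = _check_sv_width(X, spec.n_inputs)
    model = MLPRegressor(
        hidden_layer_sizes=(spec.n_hidden,),
        activation="relu",
        solver="sgd",
        learning_rate="constant",
        learning_rate_init=spec.learning_rate,
        batch_size=min(spec.batch_size, X.shape[0]),
        max_iter=spec.n_epochs,
        momentum=0.9,
        tol=0.0,
        n_iter_no_change=spec.n_epochs,
        random_state=spec.seed,
    )
    # tol=0 deliberately trains the full epoch budget; the resulting
    # "did not converge" warning is expected and uninformative here
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, np.asarray(y, float))
    return model


# ---------------------------------------------------------------------------
# hybrid


@dataclass
class HybridModel:
    """Frozen CNN backbone feeding a fitted random-forest regressor."""

    backbone: Backbone
    forest: RandomForestRegressor
    rfr_params: RFRParams | None = None

    def predict(self, inputs: MultichannelInput | np.ndarray) -> np.ndarray:
        return hybrid_predict(self.backbone, self.forest, inputs)


def hybrid_predict(backbone: Backbone, forest: RandomForestRegressor,
                   inputs: MultichannelInput | np.ndarray) -> np.ndarray:
    """Predict fractions: forest applied to inference-mode CNN features."""
    x = inputs.tensor if isinstance(inputs, MultichannelInput) else inputs
    feats = backbone.extract_features(np.asarray(x, float))
    if feats.shape[1] != forest.n_features_in_:
        raise ValueError(
            f"backbone emits {feats.shape[1]} features but the forest was "
            f"fitted on {forest.n_features_in_}"
        )
    return forest.predict(feats)
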