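"""The attention-residual convolutional classifier.

Topology (channels-last, input 20 x 14 — 20 electrodes as the spatial
axis, 14 features as input channels):

    Conv1D 64/k7 (no bias) -> BN -> ReLU -> ChannelAttention(r=8)
    -> MaxPool/2
    -> ResidualBlock 128/k5 (1x1 projection skip)
    -> MaxPool/2
    -> ResidualBlock 256/k3 (1x1 projection skip)
    -> global average- and max-pool, concatenated (512)
    -> Dense 512 -> BN -> ReLU -> Dropout 0.5 -> Dense 5 -> softmax

Total parameters: 758,725, counting batch-norm moving statistics (4
values per normalized channel) alongside trainable weights.  The first
convolution carries no bias; the residual-block and projection
convolutions do — both choices are pinned by the published per-layer
parameter counts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .nn.layers import (
    BatchNorm,
    ChannelAttention,
    Conv1D,
    Dense,
    Dropout,
    GlobalPoolConcat,
    MaxPool1D,
    ReLU,
)
from .nn.losses import softmax

INPUT_SHAPE = (20, 14)


@dataclass(frozen=True)
class AttentionConfig:
    """Channel-attention hyperparameters."""

    channels: int
    reduction_ratio: int = 8

    def __post_init__(self) -> None:
        if self.reduction_ratio < 1 or self.channels % self.reduction_ratio != 0:
            raise ConfigurationError(
                f"channels ({self.channels}) must be divisible by "
                f"reduction ratio ({self.reduction_ratio})"
            )


@dataclass(frozen=True)
class ArchitectureSpec:
    """Widths, kernels and head configuration of the network."""

    input_shape: tuple[int, int] = INPUT_SHAPE
    stage_widths: tuple[int, int, int] = (64, 128, 256)
    kernel_sizes: tuple[int, int, int] = (7, 5, 3)
    reduction_ratio: int = 8
    pool_size: int = 2
    head_width: int = 512
    dropout: float = 0.5
    n_classes: int = 5
    double_sigmoid: bool = True


CANONICAL_SPEC = ArchitectureSpec()


@dataclass
class LayerRow:
    """One row of the layer table (mirrors the published architecture table)."""

    name: str
    maps: int
    size: str
    kernel: str
    params: int
    meta: dict = field(default_factory=dict)


class ResidualBlock:
    """conv(k) -> BN -> ReLU -> channel attention -> conv(k) -> BN, plus skip.

    The skip path is the identity when input and output widths match,
    otherwise a 1x1 projection convolution; the sum passes through a
    final ReLU.  'Same' padding keeps the spatial length unchanged.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, reduction_ratio: int,
                 *, double_sigmoid: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv1D(c_in, c_out, kernel, bias=True, rng=rng)
        self.bn1 = BatchNorm(c_out)
        self.relu1 = ReLU()
        self.attention = ChannelAttention(
            c_out, reduction_ratio, double_sigmoid=double_sigmoid, rng=rng
        )
        self.conv2 = Conv1D(c_out, c_out, kernel, bias=True, rng=rng)
        self.bn2 = BatchNorm(c_out)
        self.projection = (
            Conv1D(c_in, c_out, 1, bias=True, rng=rng) if c_in != c_out else None
        )
        self.relu_out = ReLU()

    def layers(self):
        out = [self.conv1, self.bn1, self.relu1, self.attention, self.conv2, self.bn2]
        if self.projection is not None:
            out.append(self.projection)
        out.append(self.relu_out)
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training))
        h = self.attention.forward(h, training)
        h = self.bn2.forward(self.conv2.forward(h, training), training)
        s = self.projection.forward(x, training) if self.projection is not None else x
        return self.relu_out.forward(h + s, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dy)
        # main path
        dh = self.bn2.backward(d)
        dh = self.conv2.backward(dh)
        dh = self.attention.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        # skip path
        dx += self.projection.backward(d) if self.projection is not None else d
        return dx


class Network:
    """The assembled network with an inspectable layer table and attention taps."""

    def __init__(self, spec: ArchitectureSpec = CANONICAL_SPEC, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        w0, w1, w2 = spec.stage_widths
        k0, k1, k2 = spec.kernel_sizes
        t_in, c_in = spec.input_shape
        r = spec.reduction_ratio

        self.conv0 = Conv1D(c_in, w0, k0, bias=False, rng=rng)
        self.bn0 = BatchNorm(w0)
        self.relu0 = ReLU()
        self.attention0 = ChannelAttention(w0, r, double_sigmoid=spec.double_sigmoid, rng=rng)
        self.pool0 = MaxPool1D(spec.pool_size)
        self.block1 = ResidualBlock(w0, w1, k1, r, double_sigmoid=spec.double_sigmoid, rng=rng)
        self.pool1 = MaxPool1D(spec.pool_size)
        self.block2 = ResidualBlock(w1, w2, k2, r, double_sigmoid=spec.double_sigmoid, rng=rng)
        self.gpool = GlobalPoolConcat()
        self.fc1 = Dense(2 * w2, spec.head_width, rng=rng)
        self.bn_head = BatchNorm(spec.head_width)
        self.relu_head = ReLU()
        self.dropout = Dropout(spec.dropout)
        self.dropout.rng = np.random.default_rng(rng.integers(2**31))
        self.fc2 = Dense(spec.head_width, spec.n_classes, rng=rng)

    # -- plumbing ----------------------------------------------------------
    def layers(self):
        return (
            [self.conv0, self.bn0, self.relu0, self.attention0, self.pool0]
            + self.block1.layers()
            + [self.pool1]
            + self.block2.layers()
            + [self.gpool, self.fc1, self.bn_head, self.relu_head, self.dropout, self.fc2]
        )

    def trainable_layers(self):
        return [l for l in self.layers() if l.params]

    def num_params(self) -> int:
        return sum(l.param_count() for l in self.layers())

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for l in self.layers():
            out.extend(v.copy() for v in l.params.values())
            out.extend(v.copy() for v in l.stats.values())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for l in self.layers():
            for k in l.params:
                l.params[k] = next(it).copy()
            for k in l.stats:
                l.stats[k] = next(it).copy()

    def save(self, path: "str | Path") -> None:
        """Save weights as an .npz array bundle."""
        arrays = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        np.savez(path, **arrays)

    def load(self, path: "str | Path") -> None:
        with np.load(path) as z:
            self.set_weights([z[f"w{i}"] for i in range(len(z.files))])

    # -- computation -------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a batch of (20, 14) feature matrices."""
        x = np.asarray(x, dtype=float)
        flat = int(np.prod(self.spec.input_shape))
        if x.ndim == 1 and x.size == flat:
            x = x.reshape(1, *self.spec.input_shape)
        elif x.ndim == 2 and x.shape == self.spec.input_shape:
            x = x[None]
        elif x.ndim == 2 and x.shape[1] == flat:
            x = x.reshape(x.shape[0], *self.spec.input_shape)
        if x.ndim != 3 or x.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"expected input of shape (n, {self.spec.input_shape[0]}, "
                f"{self.spec.input_shape[1]}) or (n, {flat}), got {x.shape}"
            )
        h = self.attention0.forward(
            self.relu0.forward(self.bn0.forward(self.conv0.forward(x, training), training)),
            training,
        )
        h = self.pool0.forward(h)
        h = self.block1.forward(h, training)
        h = self.pool1.forward(h)
        h = self.block2.forward(h, training)
        h = self.gpool.forward(h)
        h = self.relu_head.forward(self.bn_head.forward(self.fc1.forward(h), training))
        h = self.dropout.forward(h, training)
        return self.fc2.forward(h)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.fc2.backward(dlogits)
        d = self.dropout.backward(d)
        d = self.bn_head.backward(self.relu_head.backward(d))
        d = self.fc1.backward(d)
        d = self.gpool.backward(d)
        d = self.block2.backward(d)
        d = self.pool1.backward(d)
        d = self.block1.backward(d)
        d = self.pool0.backward(d)
        d = self.attention0.backward(d)
        d = self.conv0.backward(self.bn0.backward(self.relu0.backward(d)))
        return d

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False))

    def attention_maps(self, x: np.ndarray) -> list[np.ndarray]:
        """Per-module attention weight vectors for the given input."""
        self.forward(x, training=False)
        return [
            self.attention0.last_weights.copy(),
            self.block1.attention.last_weights.copy(),
            self.block2.attention.last_weights.copy(),
        ]

    # -- audit -------------------------------------------------------------
    def layer_table(self) -> list[LayerRow]:
        """Per-layer table mirroring the published architecture description."""
        spec = self.spec
        t0, c_in = spec.input_shape
        t1 = t0 // spec.pool_size
        t2 = t1 // spec.pool_size
        w0, w1, w2 = spec.stage_widths
        k0, k1, k2 = spec.kernel_sizes
        head = spec.head_width

        def conv_row(name, layer, t_out, c_prev):
            return LayerRow(
                name, layer.c_out, f"{t_out} x {layer.c_out}",
                f"{layer.kernel}/1/same", layer.param_count(),
                meta=dict(kind="conv", n=t_out, k=layer.kernel,
                          c_in=c_prev, c_out=layer.c_out),
            )

        def bn_row(name, layer, t_out, maps):
            size = f"{t_out} x {maps}" if t_out else str(maps)
            return LayerRow(name, maps, size, "-/-/-", layer.param_count(),
                            meta=dict(kind="batchnorm"))

        def att_row(layer, t_out):
            return LayerRow(
                "Channel Attention", layer.c, f"{t_out} x {layer.c}", "-/-/-",
                layer.param_count(),
                meta=dict(kind="attention", c=layer.c, r=layer.r),
            )

        b1, b2 = self.block1, self.block2
        rows = [
            LayerRow("Input", 1, f"{t0} x {c_in}", "-/-/-", 0, meta=dict(kind="input")),
            conv_row("Conv1D", self.conv0, t0, c_in),
            bn_row("BatchNorm + ReLU", self.bn0, t0, w0),
            att_row(self.attention0, t0),
            LayerRow("MaxPool1D", w0, f"{t1} x {w0}", "2/2/valid", 0, meta=dict(kind="pool")),
            conv_row("Conv1D", b1.conv1, t1, w0),
            bn_row("BatchNorm + ReLU", b1.bn1, t1, w1),
            att_row(b1.attention, t1),
            conv_row("Conv1D", b1.conv2, t1, w1),
            bn_row("BatchNorm", b1.bn2, t1, w1),
            conv_row("Skip Conv1D", b1.projection, t1, w0),
            LayerRow("Add + ReLU", w1, f"{t1} x {w1}", "-/-/-", 0, meta=dict(kind="add")),
            LayerRow("MaxPool1D", w1, f"{t2} x {w1}", "2/2/valid", 0, meta=dict(kind="pool")),
            conv_row("Conv1D", b2.conv1, t2, w1),
            bn_row("BatchNorm + ReLU", b2.bn1, t2, w2),
            att_row(b2.attention, t2),
            conv_row("Conv1D", b2.conv2, t2, w2),
            bn_row("BatchNorm", b2.bn2, t2, w2),
            conv_row("Skip Conv1D", b2.projection, t2, w1),
            LayerRow("Add + ReLU", w2, f"{t2} x {w2}", "-/-/-", 0, meta=dict(kind="add")),
            LayerRow("GlobalPool + Concat", 2 * w2, str(2 * w2), "-/-/-", 0,
                     meta=dict(kind="pool")),
            LayerRow("Dense", head, str(head), "-/-/-", self.fc1.param_count(),
                     meta=dict(kind="dense", n_in=2 * w2, n_out=head)),
            bn_row("BatchNorm + ReLU", self.bn_head, None, head),
            LayerRow(f"Dropout({spec.dropout})", head, str(head), "-/-/-", 0,
                     meta=dict(kind="dropout")),
            LayerRow("Dense (Softmax)", spec.n_classes, str(spec.n_classes), "-/-/-",
                     self.fc2.param_count(),
                     meta=dict(kind="dense", n_in=head, n_out=spec.n_classes)),
        ]
        return rows

    def layer_table_csv(self) -> str:
        buf = io.StringIO()
        buf.write("layer,maps,size,kernel_stride_pad,parameters\n")
        for row in self.layer_table():
            buf.write(f"{row.name},{row.maps},{row.size},{row.kernel},{row.params}\n")
        buf.write(f"Total,,,,{self.num_params()}\n")
        return buf.getvalue()


def build_network(spec: ArchitectureSpec = CANONICAL_SPEC, seed: int = 0,
                  *, strict: bool = False) -> Network:
    """Instantiate the network; ``strict`` rejects any deviation from the
    canonical widths/kernels/head configuration."""
    if strict:
        canonical = (
            CANONICAL_SPEC.stage_widths, CANONICAL_SPEC.kernel_sizes,
            CANONICAL_SPEC.reduction_ratio, CANONICAL_SPEC.head_width,
            CANONICAL_SPEC.n_classes, CANONICAL_SPEC.input_shape,
        )
        got = (spec.stage_widths, spec.kernel_sizes, spec.reduction_ratio,
               spec.head_width, spec.n_classes, spec.input_shape)
        if got != canonical:
            raise ConfigurationError(
                f"strict mode: spec {got} deviates from the canonical architecture"
            )
    return Network(spec, seed)


# -- functional wrappers over the layer primitives --------------------------

def channel_attention(x: np.ndarray, config: AttentionConfig, *, seed: int = 0,
                      double_sigmoid: bool = True) -> np.ndarray:
    """Apply a freshly initialized channel-attention module to a T x C map."""
    layer = ChannelAttention(config.channels, config.reduction_ratio,
                             double_sigmoid=double_sigmoid,
                             rng=np.random.default_rng(seed))
    x = np.asarray(x, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    y = layer.forward(x)
    return y[0] if single else y


def residual_block(x: np.ndarray, out_channels: int, kernel: int, *,
                   reduction_ratio: int = 8, seed: int = 0,
                   training: bool = False) -> np.ndarray:
    """Apply a freshly initialized residual block to a T x C map."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    block = ResidualBlock(x.shape[2], out_channels, kernel, reduction_ratio,
                          rng=np.random.default_rng(seed))
    y = block.forward(x, training)
    return y[0] if single else y


def forward(network: Network, feature_matrix: np.ndarray) -> np.ndarray:
    """Class probabilities for one 20 x 14 feature matrix (or a batch)."""
    p = network.predict_proba(feature_matrix)
    return p[0] if np.asarray(feature_matrix).ndim == 2 else p


@dataclass
class AttentionMaps:
    """The per-module attention weight vectors for one input."""

    maps: list[np.ndarray]

    def __iter__(self):
        return iter(self.maps)

    def __getitem__(self, i):
        return self.maps[i]


def extract_attention(network: Network, feature_matrix: np.ndarray) -> AttentionMaps:
    maps = network.attention_maps(feature_matrix)
    if np.asarray(feature_matrix).ndim == 2:
        maps = [m[0] for m in maps]
    return AttentionMaps(maps)


# -- scikit-learn style estimator -------------------------------------------

class AttentionResidualClassifier:
    """Seizure-type classifier with the attention-residual architecture.

    A scikit-learn compatible estimator over flattened 280-feature
    vectors (or (n, 20, 14) feature matrices).  Training uses Adam with
    class-weighted cross-entropy, reduce-on-plateau learning-rate decay
    and early stopping on validation accuracy with best-weight restore.

    Parameters mirror the published training configuration; see
    :class:`ictalnet.training.TrainConfig`.
    """

    def __init__(self, *, reduction_ratio: int = 8, double_sigmoid: bool = True,
                 dropout: float = 0.5, learning_rate: float = 1e-4,
                 max_epochs: int = 15, batch_size: int = 32,
                 lr_factor: float = 0.5, lr_patience: int = 3,
                 lr_floor: float = 1e-6, early_stopping_patience: int = 5,
                 class_weight: "str | dict | None" = "balanced",
                 standardize: bool = True, random_state: int = 0):
        self.reduction_ratio = reduction_ratio
        self.double_sigmoid = double_sigmoid
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.lr_factor = lr_factor
        self.lr_patience = lr_patience
        self.lr_floor = lr_floor
        self.early_stopping_patience = early_stopping_patience
        self.class_weight = class_weight
        self.standardize = standardize
        self.random_state = random_state

    # sklearn protocol ----------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "reduction_ratio", "double_sigmoid", "dropout", "learning_rate",
                "max_epochs", "batch_size", "lr_factor", "lr_patience",
                "lr_floor", "early_stopping_patience", "class_weight",
                "standardize", "random_state",
            )
        }

    def set_params(self, **params) -> "AttentionResidualClassifier":
        valid = self.get_params()
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _validate_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3 and X.shape[1:] == INPUT_SHAPE:
            X = X.reshape(X.shape[0], -1)
        if X.ndim != 2 or X.shape[1] != int(np.prod(INPUT_SHAPE)):
            raise ValueError(
                f"X must be (n, 280) or (n, 20, 14); got shape {X.shape}"
            )
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        return X

    def fit(self, X, y, X_val=None, y_val=None) -> "AttentionResidualClassifier":
        from .training import TrainConfig, class_weights, fit_network

        X = self._validate_X(X)
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise ValueError("X and y have inconsistent lengths")
        # z-score per feature on the training split; scale lives with the model
        if self.standardize:
            self.feature_mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
            self.feature_scale_ = scale
            X = (X - self.feature_mean_) / self.feature_scale_
        else:
            self.feature_mean_ = None
            self.feature_scale_ = None
        self.classes_ = np.unique(y)
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValueError("need at least two classes")
        self._class_index = {c: i for i, c in enumerate(self.classes_)}
        y_enc = np.array([self._class_index[c] for c in y])

        spec = ArchitectureSpec(
            reduction_ratio=self.reduction_ratio,
            double_sigmoid=self.double_sigmoid,
            dropout=self.dropout,
            n_classes=n_classes,
        )
        self.network_ = Network(spec, seed=self.random_state)

        if self.class_weight == "balanced":
            cw = class_weights(y_enc, n_classes=n_classes).weights
        elif isinstance(self.class_weight, dict):
            cw = np.array(
                [self.class_weight.get(c, 1.0) for c in self.classes_], dtype=float
            )
        else:
            cw = None

        cfg = TrainConfig(
            learning_rate=self.learning_rate, max_epochs=self.max_epochs,
            batch_size=self.batch_size, lr_factor=self.lr_factor,
            lr_patience=self.lr_patience, lr_floor=self.lr_floor,
            early_stop_patience=self.early_stopping_patience,
            seed=self.random_state,
        )
        val = None
        if X_val is not None:
            Xv = self._validate_X(X_val)
            if self.feature_mean_ is not None:
                Xv = (Xv - self.feature_mean_) / self.feature_scale_
            yv = np.array([self._class_index[c] for c in np.asarray(y_val)])
            val = (Xv, yv)
        self.history_ = fit_network(self.network_, X, y_enc, cfg,
                                    validation=val, class_weight=cw)
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise AttributeError("this classifier has not been fitted yet")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._validate_X(X)
        if self.feature_mean_ is not None:
            X = (X - self.feature_mean_) / self.feature_scale_
        return self.network_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def __sklearn_tags__(self):  # pragma: no cover - sklearn >=1.6 protocol
        from sklearn.utils import Tags, TargetTags, ClassifierTags

        return Tags(
            estimator_type="classifier",
            target_tags=TargetTags(required=True),
            classifier_tags=ClassifierTags(),
        )
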