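"""Dual-channel feature images and the transfer-learning CNN classifier.

The classifier consumes a two-channel square "feature image" per subject:
channel 1 holds the subject's effect-size-selected Fisher-z Pearson
connectivity features, channel 2 the selected partial-correlation features,
each arranged by its own :class:`~fcdiff.features.ChannelLayout`.  Channels
are z-score normalised with statistics from the training split only.

Three convolutional backbones are provided, all implemented here in NumPy
(forward and backward passes, softmax cross-entropy, Adam, inverted dropout):

``tiny``
    Two 3x3 conv layers + global average pooling, operating natively on the
    side x side x 2 tensor.  The default for desk-scale experiments and tests.
``vgg16``
    A VGG-style stack (paired 3x3 convs between 2x2 max-pools) on a 32x32x3
    input; dual-channel tensors are adapted by bilinear upsampling with a
    synthesized third channel.
``resnet50``
    A ResNet-style network (initial conv + two identity-skip residual blocks)
    on the same 32x32x3 input.

Two transfer strategies are supported: ``freeze`` trains only the
fully-connected head (backbone parameters are provably untouched), while
``fine_tune`` trains every parameter.  Pretrained backbone weights can be
loaded from a local ``.npz`` checkpoint via ``TrainConfig.pretrained_weights``;
by default backbones are randomly initialised so everything runs offline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .features import ChannelLayout

__all__ = [
    "DualChannelFeature",
    "TrainConfig",
    "EvalMetrics",
    "build_dual_channel",
    "channel_norm_stats",
    "normalize_channels",
    "adapt_input",
    "build_model",
    "train_classifier",
    "evaluate",
    "stratified_split",
    "repeated_evaluate",
]

ADAPTED_SIZE = 32  # spatial size expected by the vgg16/resnet50 backbones


# ---------------------------------------------------------------------------
# Dual-channel feature construction
# ---------------------------------------------------------------------------

@dataclass
class DualChannelFeature:
    """side x side x 2 feature image for one subject (Pearson, partial)."""

    subject_id: str
    tensor: np.ndarray
    label: str


def build_dual_channel(
    pearson_features: dict[str, np.ndarray],
    partial_features: dict[str, np.ndarray],
    layouts: tuple[ChannelLayout, ChannelLayout],
    labels: dict[str, str],
) -> list[DualChannelFeature]:
    """Assemble per-subject dual-channel tensors from the two feature maps.

    ``pearson_features`` / ``partial_features`` map subject_id to the full
    upper-triangle feature vector of the respective connectivity matrix; each
    channel is filled by its own layout.  Every subject must appear in both
    maps.
    """
    lay_p, lay_q = layouts
    if lay_p.side != lay_q.side:
        raise ValueError("both channel layouts must share the same side")
    out = []
    for sid in pearson_features:
        if sid not in partial_features:
            raise KeyError(f"subject {sid} missing from partial features")
        tensor = np.stack(
            [lay_p.fill(pearson_features[sid]), lay_q.fill(partial_features[sid])], axis=-1
        )
        out.append(DualChannelFeature(sid, tensor, labels[sid]))
    return out


def channel_norm_stats(features: list[DualChannelFeature]) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and sd over a (training) set of dual-channel tensors."""
    stack = np.stack([f.tensor for f in features])  # (N, side, side, 2)
    mean = stack.mean(axis=(0, 1, 2))
    sd = stack.std(axis=(0, 1, 2))
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def normalize_channels(
    features: list[DualChannelFeature], stats: tuple[np.ndarray, np.ndarray]
) -> list[DualChannelFeature]:
    mean, sd = stats
    return [
        DualChannelFeature(f.subject_id, (f.tensor - mean) / sd, f.label) for f in features
    ]


# ---------------------------------------------------------------------------
# Input adapters
# ---------------------------------------------------------------------------

def _lin_interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic linear-interpolation matrix (align-corners sampling)."""
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    i0 = np.minimum(pos.astype(int), n_in - 2)
    frac = pos - i0
    rows = np.arange(n_out)
    m[rows, i0] = 1.0 - frac
    m[rows, i0 + 1] += frac
    return m


def resize_bilinear(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable bilinear resize of a 2-D array; exact on constants and ramps."""
    a = _lin_interp_matrix(img.shape[0], out_h)
    b = _lin_interp_matrix(img.shape[1], out_w)
    return a @ img @ b.T


def adapt_input(
    tensor: np.ndarray, backbone: str, third_channel: str = "mean"
) -> np.ndarray:
    """Map a side x side x 2 tensor to the backbone's input (channel-first).

    The tiny backbone takes the tensor natively (identity adapter, only the
    axes are reordered).  The vgg16/resnet50 backbones expect 3 x 32 x 32:
    both channels are bilinearly upsampled and a third channel is synthesized
    as their mean (``third_channel="zeros"`` uses a zero plane instead).
    """
    tensor = np.asarray(tensor, dtype=float)
    if backbone == "tiny":
        return np.moveaxis(tensor, -1, 0)
    if backbone in ("vgg16", "resnet50"):
        c0 = resize_bilinear(tensor[..., 0], ADAPTED_SIZE, ADAPTED_SIZE)
        c1 = resize_bilinear(tensor[..., 1], ADAPTED_SIZE, ADAPTED_SIZE)
        if third_channel == "mean":
            c2 = (c0 + c1) / 2.0
        elif third_channel == "zeros":
            c2 = np.zeros_like(c0)
        else:
            raise ValueError(f"unknown third_channel {third_channel!r}")
        return np.stack([c0, c1, c2])
    raise ValueError(f"unknown backbone {backbone!r}")


# ---------------------------------------------------------------------------
# NumPy neural-network layers
# ---------------------------------------------------------------------------

class Layer:
    """Minimal layer protocol: forward caches what backward needs."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 same-padding convolution, NCHW, He-initialised."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, k: int = 3):
        super().__init__()
        self.k = k
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = rng.standard_normal((cout, cin, k, k)) * scale
        self.b = np.zeros(cout)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        k = self.k
        pad = k // 2
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        self._xp_shape = xp.shape
        self._xp = xp
        y = np.zeros((n, self.w.shape[0], h, w))
        for di in range(k):
            for dj in range(k):
                xs = xp[:, :, di : di + h, dj : dj + w]
                y += np.einsum("nchw,oc->nohw", xs, self.w[:, :, di, dj], optimize=True)
        return y + self.b[None, :, None, None]

    def backward(self, gy):
        k = self.k
        pad = k // 2
        n, _, h, w = gy.shape
        xp = self._xp
        gxp = np.zeros(self._xp_shape)
        gw = self.grads[0]
        gw[...] = 0.0
        for di in range(k):
            for dj in range(k):
                xs = xp[:, :, di : di + h, dj : dj + w]
                gw[:, :, di, dj] = np.einsum("nohw,nchw->oc", gy, xs, optimize=True)
                gxp[:, :, di : di + h, dj : dj + w] += np.einsum(
                    "nohw,oc->nchw", gy, self.w[:, :, di, dj], optimize=True
                )
        self.grads[1][...] = gy.sum(axis=(0, 2, 3))
        return gxp[:, :, pad : pad + h, pad : pad + w] if pad else gxp


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class MaxPool2(Layer):
    """2x2 max-pooling with stride 2; odd trailing rows/columns are cropped."""

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, :, : h2 * 2, : w2 * 2]
        xr = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._argmax = xr.argmax(axis=-1)
        return xr.max(axis=-1)

    def backward(self, gy):
        n, c, h2, w2 = gy.shape
        g4 = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(g4, self._argmax[..., None], gy[..., None], axis=-1)
        g = g4.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2 * 2, w2 * 2)
        out = np.zeros(self._in_shape)
        out[:, :, : h2 * 2, : w2 * 2] = g
        return out


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy):
        n, c, h, w = self._in_shape
        return np.broadcast_to(gy[:, :, None, None], self._in_shape) / (h * w)


class Dense(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        super().__init__()
        self.w = rng.standard_normal((din, dout)) * np.sqrt(2.0 / din)
        self.b = np.zeros(dout)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.w + self.b

    def backward(self, gy):
        self.grads[0][...] = self._x.T @ gy
        self.grads[1][...] = gy.sum(axis=0)
        return gy @ self.w.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    @property
    def all_params(self):
        return [p for layer in self.layers for p in getattr(layer, "params", [])]

    @property
    def all_grads(self):
        return [g for layer in self.layers for g in getattr(layer, "grads", [])]

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class ResidualBlock(Layer):
    """Two 3x3 convs with an identity skip: y = relu(conv2(relu(conv1(x))) + x)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2D(channels, channels, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(channels, channels, rng)
        self.out_relu = ReLU()
        self.params = self.conv1.params + self.conv2.params
        self.grads = self.conv1.grads + self.conv2.grads

    def forward(self, x, train=False, rng=None):
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.out_relu.forward(h + x)

    def backward(self, gy):
        g = self.out_relu.backward(gy)
        gb = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        return gb + g


def _make_backbone(tag: str, in_channels: int, rng: np.random.Generator) -> Sequential:
    if tag == "tiny":
        return Sequential(
            [
                Conv2D(in_channels, 8, rng),
                ReLU(),
                MaxPool2(),
                Conv2D(8, 16, rng),
                ReLU(),
                GlobalAvgPool(),
            ]
        )
    if tag == "vgg16":
        layers: list[Layer] = []
        cin = in_channels
        for cout in (16, 32, 64):
            layers += [Conv2D(cin, cout, rng), ReLU(), Conv2D(cout, cout, rng), ReLU(), MaxPool2()]
            cin = cout
        layers.append(GlobalAvgPool())
        return Sequential(layers)
    if tag == "resnet50":
        return Sequential(
            [
                Conv2D(in_channels, 16, rng),
                ReLU(),
                MaxPool2(),
                ResidualBlock(16, rng),
                ResidualBlock(16, rng),
                GlobalAvgPool(),
            ]
        )
    raise ValueError(f"unknown backbone {tag!r}")


_BACKBONE_FEATURES = {"tiny": 16, "vgg16": 64, "resnet50": 16}


# ---------------------------------------------------------------------------
# Model, training, evaluation
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Classifier hyperparameters; numeric defaults follow the study design
    (Adam, lr 1e-3, batch 32, 60 epochs, conv dropout 0.1, fc dropout 0.2)."""

    backbone: str = "tiny"
    strategy: str = "fine_tune"  # or "freeze"
    fcl_neurons: int = 1024  # 0 means softmax classifier only
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 60
    conv_dropout: float = 0.1
    fc_dropout: float = 0.2
    pretrained_weights: str | None = None
    third_channel: str = "mean"
    augment_sd: float = 0.0  # optional Gaussian jitter on feature tensors, off by default
    seed: int = 0

    def validate(self) -> None:
        if self.backbone not in _BACKBONE_FEATURES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.strategy not in ("freeze", "fine_tune"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.fcl_neurons < 0:
            raise ValueError("fcl_neurons must be >= 0")
        for d in (self.conv_dropout, self.fc_dropout):
            if not 0.0 <= d < 1.0:
                raise ValueError("dropout rates must be in [0, 1)")


class Classifier:
    """Backbone + fully-connected head with a 2-way softmax output."""

    def __init__(self, config: TrainConfig, in_channels: int, rng: np.random.Generator):
        self.config = config
        self.backbone = _make_backbone(config.backbone, in_channels, rng)
        self.conv_dropout = Dropout(config.conv_dropout)
        feat = _BACKBONE_FEATURES[config.backbone]
        head: list[Layer] = []
        if config.fcl_neurons > 0:
            head += [Dense(feat, config.fcl_neurons, rng), ReLU(), Dropout(config.fc_dropout)]
            feat = config.fcl_neurons
        head.append(Dense(feat, 2, rng))
        self.head = Sequential(head)
        if config.pretrained_weights is not None:
            self.load_backbone(config.pretrained_weights)

    # -- persistence ------------------------------------------------------
    def backbone_params(self) -> list[np.ndarray]:
        return self.backbone.all_params

    def load_backbone(self, path: str | Path) -> None:
        data = np.load(path)
        params = self.backbone.all_params
        for k, p in enumerate(params):
            src = data[f"param_{k}"]
            if src.shape != p.shape:
                raise ValueError(f"pretrained parameter {k} has shape {src.shape}, expected {p.shape}")
            p[...] = src

    def save_backbone(self, path: str | Path) -> None:
        np.savez(path, **{f"param_{k}": p for k, p in enumerate(self.backbone.all_params)})

    # -- forward ----------------------------------------------------------
    def logits(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        h = self.backbone.forward(x, train=train, rng=rng)
        h = self.conv_dropout.forward(h, train=train, rng=rng)
        return self.head.forward(h, train=train, rng=rng)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax(self.logits(x))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    def __init__(self, params, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _encode_labels(labels, positive_label=None):
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"training set must contain exactly two classes, found {uniq}")
    if positive_label is None:
        positive_label = uniq[0]
    y = (labels == positive_label).astype(int)
    return y, positive_label


def _adapt_set(features: list[DualChannelFeature], config: TrainConfig) -> np.ndarray:
    return np.stack(
        [adapt_input(f.tensor, config.backbone, config.third_channel) for f in features]
    )


def train_classifier(
    train_set: list[DualChannelFeature],
    config: TrainConfig,
    positive_label: str | None = None,
) -> tuple[Classifier, pd.DataFrame]:
    """Train the dual-channel classifier; returns (model, per-epoch history).

    ``freeze`` updates only the head (gradients are not even propagated into
    the backbone); ``fine_tune`` updates every parameter.  Optimisation is
    Adam with softmax cross-entropy.  Fully deterministic given
    ``config.seed``.  History columns: epoch, loss, accuracy (training set).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    x = _adapt_set(train_set, config)
    y, positive_label = _encode_labels([f.label for f in train_set], positive_label)
    model = Classifier(config, in_channels=x.shape[1], rng=rng)
    model.positive_label = positive_label
    if config.strategy == "freeze":
        params, grads = model.head.all_params, model.head.all_grads
    else:
        params = model.backbone.all_params + model.head.all_params
        grads = model.backbone.all_grads + model.head.all_grads
    opt = Adam(params, grads, config.learning_rate)
    n = x.shape[0]
    onehot = np.eye(2)[y]
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, hits = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x[idx]
            if config.augment_sd > 0:
                xb = xb + rng.normal(0.0, config.augment_sd, size=xb.shape)
            if config.strategy == "freeze":
                h = model.backbone.forward(xb, train=False)
                h = model.conv_dropout.forward(h, train=True, rng=rng)
                logits = model.head.forward(h, train=True, rng=rng)
            else:
                logits = model.logits(xb, train=True, rng=rng)
            p = _softmax(logits)
            yb = onehot[idx]
            losses.append(-np.mean(np.log(np.clip(p[np.arange(len(idx)), y[idx]], 1e-12, None))))
            hits += int((p.argmax(axis=1) == y[idx]).sum())
            dz = (p - yb) / len(idx)
            g = model.head.backward(dz)
            if config.strategy == "fine_tune":
                model.backbone.backward(model.conv_dropout.backward(g))
            opt.step()
        history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": hits / n}
        )
    return model, pd.DataFrame(history)


@dataclass
class EvalMetrics:
    """Confusion-matrix metrics (percent) plus the ROC curve and its AUC."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc_points: list[tuple[float, float]]
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roc_points"] = [[float(a), float(b)] for a, b in self.roc_points]
        d["confusion"] = dict(zip(("TP", "FP", "TN", "FN"), self.confusion))
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent from confusion counts."""
    total = tp + fp + tn + fn
    acc = 100.0 * (tp + tn) / total if total else float("nan")
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return acc, sens, spec


def evaluate(
    model: Classifier,
    test_set: list[DualChannelFeature],
    positive_label: str | None = None,
) -> EvalMetrics:
    """Held-out metrics: accuracy/sensitivity/specificity (percent), ROC, AUC.

    The positive class is the patient group (``model.positive_label`` unless
    overridden).  ROC sweeps the positive-class softmax score; AUC is the
    trapezoidal integral.  Raises on a single-class test set (AUC undefined).
    """
    if positive_label is None:
        positive_label = getattr(model, "positive_label", None)
    y, positive_label = _encode_labels([f.label for f in test_set], positive_label)
    if y.min() == y.max():
        raise ValueError("test set must contain both classes for AUC")
    x = _adapt_set(test_set, model.config)
    proba = model.predict_proba(x)
    # softmax column 1 corresponds to class 1 of the 0/1 encoding, i.e. the
    # positive (patient) class by construction of _encode_labels
    scores = proba[:, 1]
    pred = (scores >= 0.5).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    acc, sens, spec = metrics_from_confusion(tp, fp, tn, fn)
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return EvalMetrics(acc, sens, spec, auc, list(zip(fpr.tolist(), tpr.tolist())), (tp, fp, tn, fn))


def stratified_split(
    labels, test_size: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (train, test) of a stratified random holdout of ``test_size`` subjects."""
    labels = np.asarray(labels)
    n = len(labels)
    if not 0 < test_size < n:
        raise ValueError("test_size must be between 1 and n_subjects - 1")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for lab in dict.fromkeys(labels.tolist()):
        idx = np.flatnonzero(labels == lab)
        k = int(round(test_size * idx.size / n))
        k = max(1, min(k, idx.size - 1))
        test_idx.extend(rng.choice(idx, size=k, replace=False).tolist())
    test = np.array(sorted(test_idx))
    train = np.array([i for i in range(n) if i not in set(test_idx)])
    return train, test


def repeated_evaluate(
    features: list[DualChannelFeature],
    config: TrainConfig,
    test_size: int,
    n_splits: int = 5,
    positive_label: str | None = None,
) -> tuple[list[EvalMetrics], dict]:
    """Average held-out metrics over repeated stratified splits.

    Returns the per-split metrics plus a dict of their means (accuracy,
    sensitivity, specificity, auc).  Each split derives its own seed from
    ``config.seed`` so the whole procedure is reproducible.
    """
    labels = [f.label for f in features]
    results = []
    for s in range(n_splits):
        split_seed = int(np.random.SeedSequence(config.seed, spawn_key=(s,)).generate_state(1)[0] % (2**31))
        train_idx, test_idx = stratified_split(labels, test_size, split_seed)
        train = [features[i] for i in train_idx]
        test = [features[i] for i in test_idx]
        stats = channel_norm_stats(train)
        cfg = TrainConfig(**{**asdict(config), "seed": split_seed})
        model, _ = train_classifier(normalize_channels(train, stats), cfg, positive_label)
        results.append(evaluate(model, normalize_channels(test, stats)))
    mean = {
        "accuracy": float(np.mean([r.accuracy for r in results])),
        "sensitivity": float(np.mean([r.sensitivity for r in results])),
        "specificity": float(np.mean([r.specificity for r in results])),
        "auc": float(np.mean([r.auc for r in results])),
    }
    return results, mean
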