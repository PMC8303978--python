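"""AlexNet-geometry convolutional network as a 4096-d feature extractor.

The network is the classical 8-layer AlexNet feature path: five
convolution stages (two of them grouped, groups = 2), interleaved ReLU /
cross-channel (local response) normalization / max-pooling layers, then
two 4096-unit fully connected layers.  Activations of the *second* fully
connected layer (fc-19 in the layer table below) are the feature vector
handed to the downstream SVM; the softmax head is used only when training
the fully connected stack on labeled images.

Everything runs on numpy (im2col + matmul convolutions) in float32.
Weight modes:

- ``random``: seeded He-normal initialization.  Random convolutional
  projections preserve class-separating image structure and make the
  extractor fully reproducible with no external assets.
- ``pretrained_file``: load a local ``.npz`` of named tensors (never
  downloaded); shapes are validated against the layer table.
- ``scratch_trained``: after random init, :func:`scratch_train` fits the
  fully connected stack (fc16 -> relu -> dropout -> fc19 -> softmax head)
  by cross-entropy on labeled images while the convolutional stack stays
  frozen at its seeded initialization.

Dropout (50%, layer 18) is active only during training, never during
feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

INPUT_SIDE = 227
FEATURE_DIM = 4096

# Local response normalization constants (classical AlexNet values).
LRN_DEPTH, LRN_ALPHA, LRN_BETA, LRN_K = 5, 1e-4, 0.75, 2.0

#: The 19 feature-path layers: (index, kind, expected output shape HxWxC,
#: weight shape, bias shape, hyperparameters).
LAYER_TABLE = [
    (1, "conv", (55, 55, 96), (11, 11, 3, 96), (96,), {"stride": 4, "pad": 0, "groups": 1}),
    (2, "relu", (55, 55, 96), None, None, {}),
    (3, "lrn", (55, 55, 96), None, None, {}),
    (4, "maxpool", (27, 27, 96), None, None, {"size": 3, "stride": 2}),
    (5, "conv", (27, 27, 256), (5, 5, 48, 128, 2), (128, 2), {"stride": 1, "pad": 2, "groups": 2}),
    (6, "relu", (27, 27, 256), None, None, {}),
    (7, "lrn", (27, 27, 256), None, None, {}),
    (8, "maxpool", (13, 13, 256), None, None, {"size": 3, "stride": 2}),
    (9, "conv", (13, 13, 384), (3, 3, 256, 384), (384,), {"stride": 1, "pad": 1, "groups": 1}),
    (10, "relu", (13, 13, 384), None, None, {}),
    (11, "conv", (13, 13, 384), (3, 3, 192, 192, 2), (192, 2), {"stride": 1, "pad": 1, "groups": 2}),
    (12, "relu", (13, 13, 384), None, None, {}),
    (13, "conv", (13, 13, 256), (3, 3, 192, 128, 2), (128, 2), {"stride": 1, "pad": 1, "groups": 2}),
    (14, "relu", (13, 13, 256), None, None, {}),
    (15, "maxpool", (6, 6, 256), None, None, {"size": 3, "stride": 2}),
    (16, "fc", (1, 1, 4096), (4096, 9216), (4096,), {}),
    (17, "relu", (1, 1, 4096), None, None, {}),
    (18, "dropout", (1, 1, 4096), None, None, {"rate": 0.5}),
    (19, "fc", (1, 1, 4096), (4096, 4096), (4096,), {}),
]

#: fc-16 input dimension: 6 * 6 * 256 flattened.
FC16_INPUT_DIM = 6 * 6 * 256


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int, pad: int,
            groups: int) -> np.ndarray:
    """Grouped 2-D convolution of one (H, W, C) image, HWC layout."""
    if pad:
        x = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    k = w.shape[0]
    view = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(0, 1))
    view = view[::stride, ::stride]  # (Ho, Wo, C, k, k)
    ho, wo = view.shape[:2]
    cin = x.shape[2] // groups
    outs = []
    for g in range(groups):
        wg = w[..., g] if groups > 1 else w  # (k, k, cin, cout)
        bg = b[..., g] if groups > 1 else b
        patch = view[:, :, g * cin : (g + 1) * cin]  # (Ho, Wo, cin, k, k)
        # flatten patches as (k, k, cin) to match the weight layout
        cols = patch.transpose(0, 1, 3, 4, 2).reshape(ho * wo, k * k * cin)
        wm = wg.reshape(k * k * cin, wg.shape[3])
        outs.append((cols @ wm + bg).reshape(ho, wo, wg.shape[3]))
    return np.concatenate(outs, axis=2) if groups > 1 else outs[0]


def _maxpool(x: np.ndarray, size: int, stride: int) -> np.ndarray:
    view = np.lib.stride_tricks.sliding_window_view(x, (size, size), axis=(0, 1))
    return view[::stride, ::stride].max(axis=(3, 4))


def _lrn(x: np.ndarray) -> np.ndarray:
    sq = x * x
    c = x.shape[2]
    half = LRN_DEPTH // 2
    csum = np.concatenate(
        [np.zeros_like(sq[:, :, :1]), np.cumsum(sq, axis=2)], axis=2
    )
    lo = np.maximum(np.arange(c) - half, 0)
    hi = np.minimum(np.arange(c) + half + 1, c)
    window = csum[:, :, hi] - csum[:, :, lo]
    return x / (LRN_K + LRN_ALPHA * window) ** LRN_BETA


@dataclass
class ShapeReport:
    """Per-layer expected-vs-actual geometry comparison."""

    rows: list = field(default_factory=list)  # (index, kind, expected, actual, ok)

    @property
    def passed(self) -> bool:
        return all(r[4] for r in self.rows)

    def failures(self) -> list:
        return [r for r in self.rows if not r[4]]


class AlexNetFeatures:
    """The layer-table network with explicit numpy weights."""

    def __init__(self, weights: dict[str, np.ndarray], seed: int | None = None):
        self.weights = weights
        self.seed = seed
        self.layers = [
            {"index": i, "kind": kind, "expected": shape, **hyper}
            for i, kind, shape, _w, _b, hyper in LAYER_TABLE
        ]
        self.train_history_: list[float] = []

    # -- forward ---------------------------------------------------------
    def forward_conv(self, image: np.ndarray) -> np.ndarray:
        """Run layers 1-15 on one (227, 227, 3) image; returns flat 9216."""
        x = np.asarray(image, dtype=np.float32)
        if x.shape != (INPUT_SIDE, INPUT_SIDE, 3):
            raise ValueError(f"expected ({INPUT_SIDE}, {INPUT_SIDE}, 3) image, got {x.shape}")
        for layer in self.layers:
            if layer["index"] > 15:
                break
            x = self._apply(layer, x)
        return x.reshape(-1)

    def _apply(self, layer: dict, x: np.ndarray) -> np.ndarray:
        kind = layer["kind"]
        if kind == "conv":
            name = f"layer{layer['index']}"
            return _conv2d(
                x, self.weights[name + "_w"], self.weights[name + "_b"],
                layer["stride"], layer["pad"], layer["groups"],
            )
        if kind == "relu":
            return np.maximum(x, 0)
        if kind == "lrn":
            return _lrn(x)
        if kind == "maxpool":
            return _maxpool(x, layer["size"], layer["stride"])
        raise ValueError(kind)  # pragma: no cover

    def fc_features(self, conv_flat: np.ndarray) -> np.ndarray:
        """Layers 16-19 on (n, 9216) conv features; dropout inactive."""
        w16, b16 = self.weights["layer16_w"], self.weights["layer16_b"]
        w19, b19 = self.weights["layer19_w"], self.weights["layer19_b"]
        h = np.maximum(conv_flat @ w16.T + b16, 0)
        return h @ w19.T + b19

    def features(self, images: np.ndarray) -> np.ndarray:
        """Extract fc-19 activations for (n, 227, 227, 3) images."""
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[None]
        conv = np.stack([self.forward_conv(im) for im in images])
        return self.fc_features(conv)

    # -- shape tracing ---------------------------------------------------
    def trace_shapes(self) -> list[tuple[int, str, tuple]]:
        """Output shape of every layer for a zero 227 x 227 x 3 input."""
        x = np.zeros((INPUT_SIDE, INPUT_SIDE, 3), dtype=np.float32)
        shapes = []
        for layer in self.layers:
            if layer["kind"] == "fc":
                name = f"layer{layer['index']}"
                x = x.reshape(-1)
                w = self.weights[name + "_w"]
                if x.size != w.shape[1]:
                    # incompatible flatten (e.g. altered upstream geometry):
                    # report the offending input size instead of crashing
                    shapes.append((layer["index"], "fc", ("incompatible-input", x.size)))
                    x = np.zeros(w.shape[0], dtype=np.float32)
                    continue
                x = w @ x + self.weights[name + "_b"]
                shapes.append((layer["index"], "fc", (1, 1, x.size)))
            elif layer["kind"] == "dropout":
                shapes.append((layer["index"], "dropout", (1, 1, x.size)))
            elif x.ndim == 1:  # post-fc activation layers keep the 1x1xN shape
                x = np.maximum(x, 0) if layer["kind"] == "relu" else x
                shapes.append((layer["index"], layer["kind"], (1, 1, x.size)))
            else:
                x = self._apply(layer, x)
                shapes.append((layer["index"], layer["kind"], x.shape))
        return shapes


def _init_random_weights(seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    weights: dict[str, np.ndarray] = {}
    for i, kind, _shape, wshape, bshape, hyper in LAYER_TABLE:
        if wshape is None:
            continue
        name = f"layer{i}"
        if kind == "conv":
            fan_in = int(np.prod(wshape[:3]))
        else:  # fc: (out, in)
            fan_in = wshape[1]
        std = np.sqrt(2.0 / fan_in)
        weights[name + "_w"] = rng.normal(0, std, size=wshape).astype(np.float32)
        weights[name + "_b"] = np.zeros(bshape, dtype=np.float32)
    return weights


def build_cnn(
    weights_mode: str = "random", seed: int = 0, weights_file: str | None = None
) -> AlexNetFeatures:
    """Construct the layer-table network.

    ``weights_mode`` is ``random`` (seeded He init), or ``pretrained_file``
    (load a local npz whose tensor names are ``layer<i>_w`` / ``layer<i>_b``;
    shapes validated, never downloaded).
    """
    if weights_mode == "random":
        return AlexNetFeatures(_init_random_weights(seed), seed=seed)
    if weights_mode == "pretrained_file":
        if weights_file is None:
            raise ValueError("pretrained_file mode requires weights_file")
        archive = np.load(weights_file)
        weights = {}
        for i, _kind, _shape, wshape, bshape, _hyper in LAYER_TABLE:
            if wshape is None:
                continue
            for suffix, expected in (("_w", wshape), ("_b", bshape)):
                name = f"layer{i}{suffix}"
                if name not in archive:
                    raise ValueError(f"weights file missing tensor {name!r}")
                tensor = archive[name]
                if tuple(tensor.shape) != tuple(expected):
                    raise ValueError(
                        f"tensor {name!r} has shape {tuple(tensor.shape)}, "
                        f"expected {tuple(expected)}"
                    )
                weights[name] = tensor.astype(np.float32)
        return AlexNetFeatures(weights, seed=None)
    raise ValueError(f"unknown weights_mode {weights_mode!r}")


def verify_shapes(model: AlexNetFeatures) -> ShapeReport:
    """Compare the model's forward-pass geometry with the layer table."""
    actual = {idx: shape for idx, _kind, shape in model.trace_shapes()}
    report = ShapeReport()
    for i, kind, expected, wshape, _bshape, _hyper in LAYER_TABLE:
        got = tuple(actual[i])
        ok = got == tuple(expected)
        if wshape is not None:
            name = f"layer{i}_w"
            ok = ok and tuple(model.weights[name].shape) == tuple(wshape)
        report.rows.append((i, kind, tuple(expected), got, ok))
    return report


def extract_features(model: AlexNetFeatures, images: np.ndarray) -> np.ndarray:
    """fc-19 activations, shape (n, 4096); deterministic given weights."""
    feats = model.features(images)
    if not np.isfinite(feats).all():  # pragma: no cover - contract guard
        raise FloatingPointError("non-finite feature values")
    return feats


def scratch_train(
    model: AlexNetFeatures,
    images: np.ndarray,
    labels: np.ndarray,
    epochs: int = 8,
    seed: int = 0,
    lr: float = 3e-3,
    batch_size: int = 32,
    momentum: float = 0.5,
    conv_features: np.ndarray | None = None,
) -> AlexNetFeatures:
    """Cross-entropy training of the fully connected stack.

    The convolutional stack stays frozen at its seeded initialization;
    fc16, fc19 and a temporary softmax head are trained by mini-batch
    SGD with momentum and 50% dropout after the fc16 ReLU (layer 18).
    Seeded and deterministic; the per-epoch mean loss history is stored
    on ``model.train_history_``.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train")
    y = np.searchsorted(classes, labels)
    if conv_features is None:
        images = np.asarray(images, dtype=np.float32)
        conv_features = np.stack([model.forward_conv(im) for im in images])
    F = conv_features.astype(np.float32)
    n = F.shape[0]
    rng = np.random.default_rng(seed)
    w16 = model.weights["layer16_w"].copy()
    b16 = model.weights["layer16_b"].copy()
    w19 = model.weights["layer19_w"].copy()
    b19 = model.weights["layer19_b"].copy()
    wh = rng.normal(0, np.sqrt(2.0 / FEATURE_DIM), (classes.size, FEATURE_DIM)).astype(np.float32)
    bh = np.zeros(classes.size, dtype=np.float32)
    params = [w16, b16, w19, b19, wh, bh]
    velocity = [np.zeros_like(p) for p in params]

    def full_loss() -> float:
        # evaluation pass: dropout inactive
        h1 = np.maximum(F @ w16.T + b16, 0)
        h2 = h1 @ w19.T + b19
        logits = h2 @ wh.T + bh
        logits = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        return float(-np.mean(np.log(probs[np.arange(n), y] + 1e-12)))

    history = []
    for _epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = F[idx], y[idx]
            # forward
            h1 = np.maximum(xb @ w16.T + b16, 0)
            mask = (rng.random(h1.shape) > 0.5).astype(np.float32) / 0.5
            h1d = h1 * mask
            h2 = h1d @ w19.T + b19
            logits = h2 @ wh.T + bh
            logits -= logits.max(axis=1, keepdims=True)
            expl = np.exp(logits)
            probs = expl / expl.sum(axis=1, keepdims=True)
            # backward
            dlogits = probs
            dlogits[np.arange(len(yb)), yb] -= 1
            dlogits /= len(yb)
            grads = [None] * 6
            grads[4] = dlogits.T @ h2
            grads[5] = dlogits.sum(axis=0)
            dh2 = dlogits @ wh
            grads[2] = dh2.T @ h1d
            grads[3] = dh2.sum(axis=0)
            dh1 = (dh2 @ w19) * mask * (h1 > 0)
            grads[0] = dh1.T @ xb
            grads[1] = dh1.sum(axis=0)
            # global-norm gradient clipping stabilizes the first steps
            gnorm = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads))
            scale = min(1.0, 1.0 / (gnorm + 1e-12))
            for p, g, buf in zip(params, grads, velocity):
                buf *= momentum
                buf += scale * g.astype(np.float32)
                p -= lr * buf
        history.append(full_loss())
    model.weights["layer16_w"], model.weights["layer16_b"] = w16, b16
    model.weights["layer19_w"], model.weights["layer19_b"] = w19, b19
    model.train_history_ = history
    model.head_ = (wh, bh, classes)
    return model


class CNNFeatureExtractor(BaseEstimator, TransformerMixin):
    """Sklearn transformer: spectrogram images -> 4096-d fc-19 activations.

    Parameters
    ----------
    weights_mode : {"random", "pretrained_file"}
    seed : int
        Seed of the random weight initialization (and of FC training).
    train : {"none", "fc"}
        With ``"fc"`` and labels available, :func:`scratch_train` fits the
        fully connected stack on the training images during ``fit``.
    epochs, lr, batch_size : FC-training hyperparameters.
    """

    def __init__(
        self,
        weights_mode: str = "random",
        seed: int = 0,
        train: str = "none",
        epochs: int = 8,
        lr: float = 3e-3,
        batch_size: int = 32,
        weights_file: str | None = None,
    ):
        self.weights_mode = weights_mode
        self.seed = seed
        self.train = train
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.weights_file = weights_file

    def fit(self, X: np.ndarray, y: np.ndarray | None = None) -> "CNNFeatureExtractor":
        self._fit(X, y)
        return self

    def _fit(self, X: np.ndarray, y: np.ndarray | None) -> np.ndarray:
        self.model_ = build_cnn(self.weights_mode, seed=self.seed,
                                weights_file=self.weights_file)
        X = np.asarray(X, dtype=np.float32)
        conv = np.stack([self.model_.forward_conv(im) for im in X])
        if self.train == "fc":
            if y is None:
                raise ValueError('train="fc" requires labels in fit')
            scratch_train(
                self.model_, X, np.asarray(y), epochs=self.epochs, seed=self.seed,
                lr=self.lr, batch_size=self.batch_size, conv_features=conv,
            )
        elif self.train != "none":
            raise ValueError(f"unknown train mode {self.train!r}")
        return conv

    def fit_transform(self, X: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
        conv = self._fit(X, y)
        return self.model_.fc_features(conv)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return extract_features(self.model_, np.asarray(X, dtype=np.float32))
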