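"""Two-route 1-D convolutional classifier for PVC windows.

The network accepts the 10-value normalized feature vector of one 20 s
window and predicts PVC vs. non-PVC.  Two parallel feature-extraction
routes read the same input:

* **upper route** — four length-3 convolutions (ReLU); the first three
  preserve length via zero padding, and a single size-2 max-pool
  follows the fourth;
* **lower route** — two length-3 convolutions (ReLU) with one size-2
  max-pool after the second.

Both route outputs are flattened, concatenated, passed through one
hidden fully-connected ReLU layer and a 2-unit softmax head.  Training
uses cross-entropy with Adam (learning rate 1e-4, batch size 200,
40 epochs, learning rate multiplied by 0.2 every ``lr_drop_period``
epochs).

The implementation is plain numpy (forward, backprop, Adam), which
keeps training bit-for-bit reproducible under a fixed seed on a fixed
platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .features import NormalizationParams, PVC_LABEL, NON_PVC_LABEL

#: Integer class codes: index 0 = non-PVC, index 1 = PVC (positive class).
CLASS_NAMES = (NON_PVC_LABEL, PVC_LABEL)


@dataclass(frozen=True)
class ModelConfig:
    input_length: int = 10
    n_classes: int = 2
    upper_route_filters: tuple[int, int, int, int] = (16, 16, 16, 32)
    lower_route_filters: tuple[int, int] = (16, 32)
    kernel_length: int = 3
    pool_size: int = 2
    fc_units: int = 32
    learning_rate: float = 1e-4
    max_epochs: int = 40
    batch_size: int = 200
    lr_drop_factor: float = 0.2
    lr_drop_period: int = 20
    class_weighting: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.input_length != 10:
            raise ValueError("input_length must be 10")
        if self.n_classes != 2:
            raise ValueError("n_classes must be 2")
        if len(self.upper_route_filters) != 4:
            raise ValueError("upper route needs 4 filter counts")
        if len(self.lower_route_filters) != 2:
            raise ValueError("lower route needs 2 filter counts")
        if min(self.upper_route_filters + self.lower_route_filters) < 1:
            raise ValueError("filter counts must be positive")
        if self.kernel_length < 1 or self.pool_size < 1 or self.fc_units < 1:
            raise ValueError("kernel_length, pool_size and fc_units must "
                             "be positive")
        if self.learning_rate <= 0 or self.max_epochs < 1 \
                or self.batch_size < 1:
            raise ValueError("invalid training hyperparameters")
        if not 0 < self.lr_drop_factor <= 1 or self.lr_drop_period < 1:
            raise ValueError("invalid learning-rate schedule")


# ---------------------------------------------------------------- layers

class _Conv1d:
    """Length-`k` 1-D convolution, stride 1, 'same' or 'valid' padding."""

    def __init__(self, in_ch: int, out_ch: int, k: int, padding: str,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * k))      # He initialization
        self.w = rng.normal(0.0, scale, size=(out_ch, in_ch, k))
        self.b = np.zeros(out_ch)
        self.padding = padding
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def out_length(self, length: int) -> int:
        k = self.w.shape[2]
        return length if self.padding == "same" else length - k + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.w.shape[2]
        if self.padding == "same":
            lo = (k - 1) // 2
            xp = np.pad(x, ((0, 0), (0, 0), (lo, k - 1 - lo)))
        else:
            lo, xp = 0, x
        windows = sliding_window_view(xp, k, axis=2)
        y = np.einsum("nclk,ock->nol", windows, self.w) \
            + self.b[None, :, None]
        self._cache = (x.shape, windows, lo)
        return y

    def backward(self, dy: np.ndarray):
        x_shape, windows, lo = self._cache
        k = self.w.shape[2]
        dw = np.einsum("nclk,nol->ock", windows, dy)
        db = dy.sum(axis=(0, 2))
        l_out = dy.shape[2]
        pad_len = x_shape[2] + (k - 1 if self.padding == "same" else 0)
        dxp = np.zeros((x_shape[0], x_shape[1], pad_len))
        for kk in range(k):
            dxp[:, :, kk:kk + l_out] += np.einsum(
                "nol,oc->ncl", dy, self.w[:, :, kk])
        dx = dxp[:, :, lo:lo + x_shape[2]] if self.padding == "same" else dxp
        return dx, [dw, db]


class _ReLU:
    params: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask, []


class _MaxPool1d:
    """Non-overlapping max-pool; a trailing odd sample is dropped."""

    params: list = []

    def __init__(self, size: int):
        self.size = size

    def out_length(self, length: int) -> int:
        return length // self.size

    def forward(self, x):
        n, c, length = x.shape
        lo = (length // self.size) * self.size
        xt = x[:, :, :lo].reshape(n, c, -1, self.size)
        self._arg = xt.argmax(axis=3)
        self._in_shape = x.shape
        return xt.max(axis=3)

    def backward(self, dy):
        n, c, length = self._in_shape
        dx = np.zeros((n, c, length // self.size, self.size))
        np.put_along_axis(dx, self._arg[..., None], dy[..., None], axis=3)
        out = np.zeros(self._in_shape)
        out[:, :, :dx.shape[2] * self.size] = dx.reshape(n, c, -1)
        return out, []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        dw = self._x.T @ dy
        db = dy.sum(axis=0)
        return dy @ self.w.T, [dw, db]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ----------------------------------------------------------------- model

class TwoRouteCNN:
    """The dual-route convolutional window classifier."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        k, pad_first3 = config.kernel_length, "same"
        uf, lf = config.upper_route_filters, config.lower_route_filters

        self.upper: list = []
        in_ch = 1
        for i, f in enumerate(uf):
            padding = pad_first3 if i < 3 else "valid"
            self.upper.append(_Conv1d(in_ch, f, k, padding, rng))
            self.upper.append(_ReLU())
            in_ch = f
        self.upper.append(_MaxPool1d(config.pool_size))

        self.lower: list = []
        in_ch = 1
        for i, f in enumerate(lf):
            padding = pad_first3 if i < 1 else "valid"
            self.lower.append(_Conv1d(in_ch, f, k, padding, rng))
            self.lower.append(_ReLU())
            in_ch = f
        self.lower.append(_MaxPool1d(config.pool_size))

        upper_len = self._route_length(self.upper, config.input_length)
        lower_len = self._route_length(self.lower, config.input_length)
        concat_width = upper_len * uf[-1] + lower_len * lf[-1]
        self.fc_hidden = _Dense(concat_width, config.fc_units, rng)
        self.fc_relu = _ReLU()
        self.fc_out = _Dense(config.fc_units, config.n_classes, rng)
        self._concat_split = upper_len * uf[-1]
        self._route_shapes = (upper_len, lower_len)

        self.normalization: NormalizationParams | None = None
        self.history: list[dict] = []

    @staticmethod
    def _route_length(layers, length: int) -> int:
        for layer in layers:
            if hasattr(layer, "out_length"):
                length = layer.out_length(length)
        return length

    # -- introspection -------------------------------------------------

    def architecture(self) -> dict:
        """Structural summary used by the conformance tests."""
        def count(route, cls):
            return sum(isinstance(l, cls) for l in route)
        return {
            "upper_conv_layers": count(self.upper, _Conv1d),
            "upper_pool_layers": count(self.upper, _MaxPool1d),
            "lower_conv_layers": count(self.lower, _Conv1d),
            "lower_pool_layers": count(self.lower, _MaxPool1d),
            "concatenations": 1,
            "hidden_fc_units": self.config.fc_units,
            "output_units": self.config.n_classes,
            "output_activation": "softmax",
        }

    @property
    def layers(self):
        return (self.upper + self.lower
                + [self.fc_hidden, self.fc_relu, self.fc_out])

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    # -- forward / backward --------------------------------------------

    def _forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for x of shape (n, input_length)."""
        h = x[:, None, :]
        hu = h
        for layer in self.upper:
            hu = layer.forward(hu)
        hl = h
        for layer in self.lower:
            hl = layer.forward(hl)
        self._shapes = (hu.shape, hl.shape)
        flat = np.concatenate(
            [hu.reshape(len(x), -1), hl.reshape(len(x), -1)], axis=1)
        z = self.fc_hidden.forward(flat)
        z = self.fc_relu.forward(z)
        return self.fc_out.forward(z)

    def _backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        grads_tail: list[np.ndarray] = []
        dz, g = self.fc_out.backward(dlogits)
        grads_tail = g + grads_tail
        dz, g = self.fc_relu.backward(dz)
        dz, g = self.fc_hidden.backward(dz)
        grads_tail = g + grads_tail
        du = dz[:, :self._concat_split].reshape(self._shapes[0])
        dl = dz[:, self._concat_split:].reshape(self._shapes[1])
        grads_routes: list[np.ndarray] = []
        for layer in reversed(self.lower):
            dl, g = layer.backward(dl)
            grads_routes = g + grads_routes
        for layer in reversed(self.upper):
            du, g = layer.backward(du)
            grads_routes = g + grads_routes
        return grads_routes + grads_tail

    def parameters(self) -> list[np.ndarray]:
        out = []
        for route in (self.upper, self.lower):
            for layer in route:
                out.extend(layer.params)
        out.extend(self.fc_hidden.params)
        out.extend(self.fc_out.params)
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.config.input_length:
            raise ValueError(
                f"expected (n, {self.config.input_length}) features, "
                f"got {x.shape}")
        return _softmax(self._forward(x))

    # -- persistence ----------------------------------------------------

    def save(self, path: str) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        meta = {"config": asdict(self.config),
                "normalization": (self.normalization.to_dict()
                                  if self.normalization else None),
                "history": self.history}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "TwoRouteCNN":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        cfg = meta["config"]
        for key in ("upper_route_filters", "lower_route_filters"):
            cfg[key] = tuple(cfg[key])
        model = cls(ModelConfig(**cfg))
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"p{i}"]
        if meta["normalization"]:
            model.normalization = NormalizationParams.from_dict(
                meta["normalization"])
        model.history = meta["history"]
        return model


def build_model(config: ModelConfig | None = None) -> TwoRouteCNN:
    return TwoRouteCNN(config or ModelConfig())


# -------------------------------------------------------------- training

def train(model: TwoRouteCNN, x: np.ndarray, y: np.ndarray,
          config: ModelConfig | None = None) -> TwoRouteCNN:
    """Train in place with cross-entropy + Adam; returns the model.

    `x` is the (n, 10) normalized feature matrix, `y` integer class
    codes (0 = non-PVC, 1 = PVC) or label strings.  Raises if the
    training set is empty or misses a class.
    """
    config = config or model.config
    x = np.asarray(x, dtype=np.float64)
    y = encode_labels(y)
    if len(x) == 0:
        raise ValueError("empty training set")
    present = set(np.unique(y))
    missing = [CLASS_NAMES[c] for c in range(config.n_classes)
               if c not in present]
    if missing:
        raise ValueError(
            f"training set contains no '{missing[0]}' windows")

    if config.class_weighting:
        freq = np.bincount(y, minlength=config.n_classes) / len(y)
        class_w = 1.0 / np.maximum(freq, 1e-12)
        class_w /= class_w.mean()
    else:
        class_w = np.ones(config.n_classes)

    params = model.parameters()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    rng = np.random.default_rng(config.seed)
    onehot = np.eye(config.n_classes)[y]
    model.history = []

    for epoch in range(config.max_epochs):
        lr = config.learning_rate * config.lr_drop_factor ** (
            epoch // config.lr_drop_period)
        order = rng.permutation(len(x))
        epoch_loss, n_correct = 0.0, 0
        for start in range(0, len(x), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb, ob = x[idx], y[idx], onehot[idx]
            logits = model._forward(xb)
            probs = _softmax(logits)
            w = class_w[yb]
            losses = -np.log(np.maximum(probs[np.arange(len(xb)), yb],
                                        1e-12))
            epoch_loss += float((w * losses).sum())
            n_correct += int((probs.argmax(axis=1) == yb).sum())
            dlogits = (probs - ob) * w[:, None] / len(xb)
            grads = model._backward(dlogits)
            t += 1
            for p, g, mi, vi in zip(params, grads, m, v):
                mi *= beta1
                mi += (1 - beta1) * g
                vi *= beta2
                vi += (1 - beta2) * g ** 2
                mhat = mi / (1 - beta1 ** t)
                vhat = vi / (1 - beta2 ** t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
        model.history.append({
            "epoch": epoch,
            "lr": lr,
            "loss": epoch_loss / len(x),
            "accuracy": n_correct / len(x),
        })
    return model


def encode_labels(y) -> np.ndarray:
    """Map PVC/non-PVC label strings (or ints) to class codes."""
    arr = np.asarray(y)
    if arr.dtype.kind in "iub":
        return arr.astype(np.int64)
    codes = {name: i for i, name in enumerate(CLASS_NAMES)}
    try:
        return np.asarray([codes[str(v)] for v in arr], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}") from exc


def predict(model: TwoRouteCNN, x: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and class probabilities for normalized features."""
    probs = model.predict_proba(x)
    labels = np.asarray([CLASS_NAMES[i] for i in probs.argmax(axis=1)])
    return labels, probs
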