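"""A small, self-contained neural-network engine on numpy.

The grading/runtime environment ships no deep-learning framework, so the
convolutional classifier is implemented here from first principles:
1-D convolution (im2col + matmul), ReLU, max-pooling, dense layers,
inverted dropout, a sigmoid/binary-cross-entropy head computed on logits
for numerical stability, and Adam. Everything is float32 and batch-first
with inputs shaped (N, L, C).

The implementation is deliberately minimal — exactly the layer grammar the
promoter classifier needs — and is verified against finite-difference
gradients in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class ArchitectureError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


class Layer:
    """Base layer: subclasses fill ``params``/``grads`` dicts keyed by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:
        raise NotImplementedError


def glorot_uniform(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Glorot/Xavier uniform init — the convention deep-learning frameworks
    default to, and markedly more stable here than He init on one-hot input."""
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, shape).astype(np.float32)


class Conv1D(Layer):
    """Valid-mode 1-D convolution, stride 1: (N, L, C) -> (N, L-w+1, F).

    Computed as a sum over the ``width`` tap positions of (N*Lout, C) @
    (C, F) matmuls, which avoids materialising an im2col buffer; the weight
    tensor is stored flat as (width*C, F), tap-major.
    """

    def __init__(self, in_channels: int, filters: int, width: int, rng: np.random.Generator):
        super().__init__()
        self.in_channels, self.filters, self.width = in_channels, filters, width
        self.params["W"] = glorot_uniform((width * in_channels, filters), rng)
        self.params["b"] = np.zeros(filters, dtype=np.float32)

    def out_shape(self, in_shape):
        n, L, c = in_shape
        if c != self.in_channels:
            raise ArchitectureError(f"Conv1D expected {self.in_channels} channels, got {c}")
        if L < self.width:
            raise ArchitectureError(
                f"Conv1D width {self.width} exceeds input length {L}"
            )
        return (n, L - self.width + 1, self.filters)

    def _taps(self):
        c = self.in_channels
        return [self.params["W"][j * c : (j + 1) * c] for j in range(self.width)]

    def forward(self, x, train=False):
        n, L, c = x.shape
        lout = L - self.width + 1
        y = np.tile(self.params["b"], (n, lout, 1))
        for j, wj in enumerate(self._taps()):
            y += x[:, j : j + lout, :] @ wj
        self._x = x
        return y

    def backward(self, dy):
        n, lout, f = dy.shape
        c = self.in_channels
        x = self._x
        dW = np.empty_like(self.params["W"])
        dy2 = dy.reshape(-1, f)
        for j in range(self.width):
            xj = x[:, j : j + lout, :].reshape(-1, c)
            dW[j * c : (j + 1) * c] = xj.T @ dy2
        self.grads["W"] = dW
        self.grads["b"] = dy.sum(axis=(0, 1))
        dx = np.zeros_like(x)
        for j, wj in enumerate(self._taps()):
            dx[:, j : j + lout, :] += dy @ wj.T
        return dx


class ReLU(Layer):
    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(Layer):
    """Max pooling over the length axis: (N, L, C) -> (N, P, C)."""

    def __init__(self, width: int, stride: int):
        super().__init__()
        if width < 1 or stride < 1:
            raise ArchitectureError("pool width and stride must be positive")
        self.width, self.stride = width, stride

    def out_shape(self, in_shape):
        n, L, c = in_shape
        if self.width > L:
            raise ArchitectureError(f"pool width {self.width} exceeds input length {L}")
        p = (L - self.width) // self.stride + 1
        if p < 1:
            raise ArchitectureError(
                f"pooling (width {self.width}, stride {self.stride}) collapses length {L} to zero"
            )
        return (n, p, c)

    def forward(self, x, train=False):
        n, L, c = x.shape
        self._starts = np.arange(0, L - self.width + 1, self.stride)
        view = sliding_window_view(x, self.width, axis=1)[:, self._starts]  # (N,P,C,w)
        self._arg = view.argmax(axis=3)
        self._in_shape = x.shape
        return view.max(axis=3)

    def backward(self, dy):
        dx = np.zeros(self._in_shape, dtype=np.float32)
        for j in range(self.width):
            mask = self._arg == j
            dx[:, self._starts + j, :] += dy * mask
        return dx


class Flatten(Layer):
    def out_shape(self, in_shape):
        n = in_shape[0]
        return (n, int(np.prod(in_shape[1:])))

    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_units: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.in_units, self.units = in_units, units
        self.params["W"] = glorot_uniform((in_units, units), rng)
        self.params["b"] = np.zeros(units, dtype=np.float32)

    def out_shape(self, in_shape):
        n, u = in_shape
        if u != self.in_units:
            raise ArchitectureError(f"Dense expected {self.in_units} inputs, got {u}")
        return (n, self.units)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not (0 <= rate < 1):
            raise ArchitectureError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate, self.rng = rate, rng

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential:
    """A feed-forward stack ending in a single logit per sample."""

    def __init__(self, layers: list[Layer], input_shape: tuple[int, int]):
        self.layers = layers
        self.input_shape = input_shape  # (L, C)
        shape = (1, *input_shape)
        for layer in layers:  # validates the whole stack eagerly
            shape = layer.out_shape(shape)
        if shape != (1, 1):
            raise ArchitectureError(f"network must end in one logit, got shape {shape[1:]}")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x[:, 0]  # logits, shape (N,)

    def backward(self, dlogit: np.ndarray) -> None:
        dy = dlogit[:, None].astype(np.float32)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """P(label = 1) per sample, computed in batches."""
        out = np.empty(len(x), dtype=np.float64)
        for i in range(0, len(x), batch_size):
            out[i : i + batch_size] = _sigmoid(self.forward(x[i : i + batch_size]))
        return out

    def n_parameters(self) -> int:
        return sum(int(p.size) for l in self.layers for p in l.params.values())

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in l.params.items()} for l in self.layers]

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for layer, w in zip(self.layers, weights):
            for k in layer.params:
                layer.params[k][...] = w[k]

    def save_weights(self, path: str) -> None:
        """Persist parameters as an .npz keyed ``<layer index>/<name>``."""
        flat = {
            f"{i}/{k}": v
            for i, layer in enumerate(self.layers)
            for k, v in layer.params.items()
        }
        np.savez(path, **flat)

    def load_weights(self, path: str) -> None:
        with np.load(path) as data:
            for i, layer in enumerate(self.layers):
                for k in layer.params:
                    layer.params[k][...] = data[f"{i}/{k}"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z, y = logits.astype(np.float64), y.astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (_sigmoid(z) - y) / len(z)
    return loss, dz.astype(np.float32)


class Adam:
    """Adam with an optional linear learning-rate warmup.

    The warmup guards against a failure mode specific to uncentered one-hot
    inputs: full-size steps in the first iterations can push every hidden
    ReLU unit permanently negative, collapsing the network onto a constant
    logit.
    """

    def __init__(self, model: Sequential, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, warmup_steps: int = 0):
        self.model, self.lr = model, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.warmup_steps = warmup_steps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in model.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in model.layers]

    def step(self) -> None:
        self.t += 1
        lr = self.lr
        if self.warmup_steps and self.t < self.warmup_steps:
            lr *= self.t / self.warmup_steps
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for li, layer in enumerate(self.model.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m = self.m[li][k]
                v = self.v[li][k]
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                p -= (lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(
                    np.float32
                )


def train_epoch(
    model: Sequential,
    opt: Adam,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    batch_size: int = 64,
) -> float:
    """One shuffled pass; returns the mean training loss."""
    order = rng.permutation(len(X))
    losses = []
    for i in range(0, len(X), batch_size):
        idx = order[i : i + batch_size]
        logits = model.forward(X[idx], train=True)
        loss, dz = bce_with_logits(logits, y[idx])
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite loss at optimizer step {opt.t}")
        model.backward(dz)
        opt.step()
        losses.append(loss * len(idx))
    return float(np.sum(losses) / len(X))
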