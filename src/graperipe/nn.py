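"""Minimal seeded neural-network core (numpy, explicit backprop).

Provides exactly the pieces the two deep classifiers in this package need:
dense and 1-D convolutional layers, max pooling, batch normalisation,
ReLU, inverted dropout, softmax cross-entropy and mean-squared-error
losses, and an AdamW optimiser (adaptive moments with decoupled weight
decay).  Everything runs on float64 numpy with a single
``numpy.random.Generator`` supplying initialisation, shuffling and
dropout masks, so training is bit-reproducible given a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv1d",
    "MaxPool1d",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "Flatten",
    "Sequential",
    "AdamW",
    "softmax",
    "cross_entropy_grad",
    "train_classifier",
    "train_autoencoder",
]


class Layer:
    """Base layer: stateless unless it declares ``params``/``grads``."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)  # He init, matches the ReLU stacks here
        self.params = {
            "w": rng.normal(0.0, scale, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, gout):
        self.grads["w"][...] = self._x.T @ gout
        self.grads["b"][...] = gout.sum(axis=0)
        return gout @ self.params["w"].T


class Conv1d(Layer):
    """Valid (no-padding) 1-D convolution over (N, C, L) tensors."""

    def __init__(
        self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator
    ) -> None:
        super().__init__()
        self.kernel, self.stride = kernel, stride
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.params = {
            "w": rng.normal(0.0, scale, size=(c_out, c_in, kernel)),
            "b": np.zeros(c_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def out_length(self, length: int) -> int:
        if length < self.kernel:
            raise ValueError(f"input length {length} shorter than kernel {self.kernel}")
        return (length - self.kernel) // self.stride + 1

    def _windows(self, x):
        l_out = self.out_length(x.shape[2])
        starts = np.arange(l_out) * self.stride
        # (N, C, L_out, k)
        return x[:, :, starts[:, None] + np.arange(self.kernel)], starts

    def forward(self, x, train):
        win, starts = self._windows(x)
        self._win, self._starts, self._in_shape = win, starts, x.shape
        return np.einsum("nclk,ock->nol", win, self.params["w"]) + self.params["b"][
            None, :, None
        ]

    def backward(self, gout):
        self.grads["w"][...] = np.einsum("nol,nclk->ock", gout, self._win)
        self.grads["b"][...] = gout.sum(axis=(0, 2))
        gwin = np.einsum("nol,ock->nclk", gout, self.params["w"])
        gx = np.zeros(self._in_shape)
        for j in range(self.kernel):
            np.add.at(gx, (slice(None), slice(None), self._starts + j), gwin[..., j])
        return gx


class MaxPool1d(Layer):
    def __init__(self, size: int, stride: int) -> None:
        super().__init__()
        self.size, self.stride = size, stride

    def forward(self, x, train):
        l_out = (x.shape[2] - self.size) // self.stride + 1
        if l_out < 1:
            raise ValueError("input too short for pooling window")
        starts = np.arange(l_out) * self.stride
        win = x[:, :, starts[:, None] + np.arange(self.size)]  # (N,C,L_out,size)
        self._arg = win.argmax(axis=3)
        self._starts, self._in_shape = starts, x.shape
        return win.max(axis=3)

    def backward(self, gout):
        gx = np.zeros(self._in_shape)
        n, c, l_out = gout.shape
        pos = self._starts[None, None, :] + self._arg  # absolute L index
        ni = np.arange(n)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(gx, (ni, ci, pos), gout)
        return gx


class BatchNorm(Layer):
    """Batch normalisation over (N, F) or per-channel over (N, C, L)."""

    def __init__(self, width: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.params = {"gamma": np.ones(width), "beta": np.zeros(width)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(width)
        self.running_var = np.ones(width)

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2)

    def _shape(self, x, v):
        return v if x.ndim == 2 else v[None, :, None]

    def forward(self, x, train):
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(x, mean)) * self._shape(x, inv)
        self._xhat, self._inv, self._axes_cached = xhat, inv, axes
        self._m = x.size // x.shape[1]  # elements per feature
        return self._shape(x, self.params["gamma"]) * xhat + self._shape(
            x, self.params["beta"]
        )

    def backward(self, gout):
        axes = self._axes_cached
        xhat, inv, m = self._xhat, self._inv, self._m
        self.grads["gamma"][...] = (gout * xhat).sum(axis=axes)
        self.grads["beta"][...] = gout.sum(axis=axes)
        g = gout * self._shape(gout, self.params["gamma"])
        gsum = g.sum(axis=axes)
        gxsum = (g * xhat).sum(axis=axes)
        return (
            self._shape(gout, inv)
            / m
            * (m * g - self._shape(gout, gsum) - xhat * self._shape(gout, gxsum))
        )


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gout):
        return gout if self._mask is None else gout * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def trainable(self) -> list[Layer]:
        return [l for l in self.layers if l.params]


class AdamW:
    """Adaptive-moment optimiser with decoupled weight decay.

    Decay is applied to weight matrices only (not biases, not batch-norm
    affine parameters), the usual convention.
    """

    def __init__(
        self,
        layers: list[Layer],
        lr: float = 1e-4,
        weight_decay: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m = self.m[li][k]
                v = self.v[li][k]
                m += (1 - self.b1) * (g - m)
                v += (1 - self.b2) * (g * g - v)
                update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                if self.wd and k == "w":
                    update = update + self.wd * p
                p -= self.lr * update


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(p[np.arange(n), labels] + 1e-300).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for s in range(0, n, batch_size):
        yield perm[s : s + batch_size]


def train_classifier(
    net: Sequential,
    x: np.ndarray,
    labels: np.ndarray,
    epochs: int,
    batch_size: int,
    lr: float,
    weight_decay: float,
    rng: np.random.Generator,
) -> list[float]:
    """Cross-entropy training loop; returns the per-epoch mean loss."""
    opt = AdamW(net.layers, lr=lr, weight_decay=weight_decay)
    history = []
    n = x.shape[0]
    for epoch in range(epochs):
        losses = []
        for idx in _batches(n, batch_size, rng):
            logits = net.forward(x[idx], train=True)
            loss, grad = cross_entropy_grad(logits, labels[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (NaN loss) at epoch {epoch}")
            net.backward(grad)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def train_autoencoder(
    net: Sequential,
    x: np.ndarray,
    target: np.ndarray,
    epochs: int,
    batch_size: int,
    lr: float,
    weight_decay: float,
    rng: np.random.Generator,
) -> list[float]:
    """MSE reconstruction training loop; returns per-epoch mean loss."""
    opt = AdamW(net.layers, lr=lr, weight_decay=weight_decay)
    history = []
    n = x.shape[0]
    for epoch in range(epochs):
        losses = []
        for idx in _batches(n, batch_size, rng):
            out = net.forward(x[idx], train=True)
            diff = out - target[idx]
            loss = float((diff**2).mean())
            if not np.isfinite(loss):
                raise RuntimeError(f"pretraining diverged (NaN loss) at epoch {epoch}")
            net.backward(2.0 * diff / diff.size)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history
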