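"""Minimal CPU neural-network core used by the autoencoder and classifier.

Implements exactly the layer vocabulary the two architectures need —
zero-padded ("same") convolution, 2x2 max-pooling, 2x2 nearest-neighbour
upsampling, batch normalization, dense, dropout — together with
Glorot/Xavier initialization and the Adam optimizer.  Data layout is
NHWC, float32 throughout; convolutions are evaluated as a single im2col
matrix product so the heavy lifting stays inside BLAS.

Everything is deterministic given the seed passed to ``Sequential``:
weight draws, dropout masks and (externally) batch shuffling all come
from ``numpy.random.Generator`` streams.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "MaxPool2x2",
    "Upsample2x",
    "BatchNorm",
    "ReLU",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "Adam",
    "mse_loss",
    "bce_with_logits_loss",
    "fit",
]


class Layer:
    """Base layer: forward/backward plus flat parameter access."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def init(self, rng: np.random.Generator) -> None:  # noqa: ARG002
        pass

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _pad_same(x: np.ndarray, p: int) -> np.ndarray:
    return np.pad(x.astype(np.float32, copy=False),
                  ((0, 0), (p, p), (p, p), (0, 0)))


def _conv_same(xp: np.ndarray, wk: np.ndarray) -> np.ndarray:
    """'same' convolution of pre-padded ``xp`` with kernel ``wk`` (k,k,Cin,Cout).

    For few input channels an im2col matrix product is cheapest; for many,
    materializing the k*k-fold patch matrix is memory-bound, so the sum of
    k*k shifted matrix products on strided views wins.
    """
    k, _, c, o = wk.shape
    n = xp.shape[0]
    h, w = xp.shape[1] - (k - 1), xp.shape[2] - (k - 1)
    if k * k * c <= 128:
        cols = np.empty((n, h, w, k, k, c), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                cols[:, :, :, di, dj, :] = xp[:, di:di + h, dj:dj + w, :]
        return (cols.reshape(n * h * w, k * k * c)
                @ wk.reshape(k * k * c, o)).reshape(n, h, w, o)
    out = np.zeros((n, h, w, o), dtype=np.float32)
    for di in range(k):
        for dj in range(k):
            out += xp[:, di:di + h, dj:dj + w, :] @ wk[di, dj]
    return out


class Conv2D(Layer):
    """Zero-padded ("same") square convolution with optional fused ReLU."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 activation: str = "linear"):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        if activation not in ("linear", "relu", "none"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.activation = "linear" if activation == "none" else activation
        self.W = np.zeros((kernel, kernel, in_ch, out_ch), dtype=np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        # set False by Sequential for the first layer: its input gradient
        # is never consumed, and it is the costliest one to compute
        self.needs_input_grad = True
        self._xp = None
        self._mask = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def init(self, rng):
        k = self.k
        self.W[:] = _glorot_uniform(
            rng, self.W.shape, fan_in=k * k * self.in_ch, fan_out=k * k * self.out_ch
        )
        self.b[:] = 0.0

    def forward(self, x, training):
        xp = _pad_same(x, self.k // 2)
        out = _conv_same(xp, self.W)
        out += self.b
        self._xp = xp if training else None
        if self.activation == "relu":
            mask = out > 0
            out *= mask
            self._mask = mask if training else None
        return out

    def backward(self, grad):
        k = self.k
        xp = self._xp
        self._xp = None
        n = xp.shape[0]
        h, w = xp.shape[1] - (k - 1), xp.shape[2] - (k - 1)
        if self.activation == "relu":
            grad = grad * self._mask
        gflat = grad.reshape(n * h * w, self.out_ch).astype(np.float32, copy=False)
        self.gb[:] = gflat.sum(axis=0)
        tmp = np.empty((n, h, w, self.in_ch), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                np.copyto(tmp, xp[:, di:di + h, dj:dj + w, :])
                self.gW[di, dj] = tmp.reshape(n * h * w, self.in_ch).T @ gflat
        if not self.needs_input_grad:
            return None
        # input gradient of a "same" convolution = convolution of the output
        # gradient with the spatially flipped, in/out-transposed kernel
        w_flip = np.ascontiguousarray(self.W[::-1, ::-1].transpose(0, 1, 3, 2))
        return _conv_same(_pad_same(grad, k // 2), w_flip)


class MaxPool2x2(Layer):
    """2x2 max pooling; gradient goes to the first maximal entry per window."""

    _OFFSETS = ((0, 0), (0, 1), (1, 0), (1, 1))

    def forward(self, x, training):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("max-pool input dims must be even")
        out = np.maximum(
            np.maximum(x[:, 0::2, 0::2, :], x[:, 0::2, 1::2, :]),
            np.maximum(x[:, 1::2, 0::2, :], x[:, 1::2, 1::2, :]),
        )
        if training:
            self._x, self._out = x, out
        return out

    def backward(self, grad):
        x, out = self._x, self._out
        self._x = self._out = None
        gx = np.zeros_like(x)
        remaining = np.ones(out.shape, dtype=bool)
        for oi, oj in self._OFFSETS:
            hit = (x[:, oi::2, oj::2, :] == out) & remaining
            gx[:, oi::2, oj::2, :] = grad * hit
            remaining &= ~hit
        return gx


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling (no learned parameters)."""

    def forward(self, x, training):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, grad):
        n, h, w, c = grad.shape
        return grad.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class BatchNorm(Layer):
    """Channel-wise batch normalization over (N, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        self.c = channels
        self.momentum, self.eps = momentum, eps
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        # zero-initialized EMAs debiased by 1 - momentum^t, so inference
        # statistics are usable even after very few training steps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.zeros(channels, dtype=np.float32)
        self._steps = 0

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[:] = m * self.running_mean + (1 - m) * mu
            self.running_var[:] = m * self.running_var + (1 - m) * var
            self._steps += 1
        elif self._steps == 0:
            mu, var = np.zeros(self.c, np.float32), np.ones(self.c, np.float32)
        else:
            debias = 1.0 - self.momentum**self._steps
            mu = self.running_mean / debias
            var = self.running_var / debias
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if training:
            self._xhat, self._inv, self._axes = xhat, inv, axes
            self._m = x.size // self.c
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        xhat, inv, axes, m = self._xhat, self._inv, self._axes, self._m
        self.ggamma[:] = (grad * xhat).sum(axis=axes)
        self.gbeta[:] = grad.sum(axis=axes)
        gx = (self.gamma * inv / m) * (
            m * grad - self.gbeta - xhat * self.ggamma
        )
        return gx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, training):
        mask = x > 0
        if training:
            self._mask = mask
        return x * mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, activation: str = "linear"):
        if activation not in ("linear", "relu", "none"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.n_in, self.n_out = n_in, n_out
        self.activation = "linear" if activation == "none" else activation
        self.W = np.zeros((n_in, n_out), dtype=np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def init(self, rng):
        self.W[:] = _glorot_uniform(rng, self.W.shape, self.n_in, self.n_out)
        self.b[:] = 0.0

    def forward(self, x, training):
        if training:
            self._x = x
        out = x @ self.W + self.b
        if self.activation == "relu":
            mask = out > 0
            out *= mask
            if training:
                self._mask = mask
        return out

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * self._mask
        self.gW[:] = self._x.T @ grad
        self.gb[:] = grad.sum(axis=0)
        return grad @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference. Mask stream seeded once."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._rng = np.random.default_rng(0)

    def reseed(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sequential:
    """Ordered layer stack with seeded initialization."""

    def __init__(self, layers: list[Layer], seed: int = 0):
        self.layers = layers
        self.seed = seed
        rng = np.random.default_rng(seed)
        for layer in layers:
            layer.init(rng)
            if isinstance(layer, Dropout):
                layer.reseed(int(rng.integers(2**31)))
        if layers and isinstance(layers[0], Conv2D):
            layers[0].needs_input_grad = False

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def params_and_grads(self):
        out = []
        for layer in self.layers:
            out.extend(zip(layer.params(), layer.grads()))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params()]
        if len(flat) != len(weights):
            raise ValueError("weight list does not match model")
        for p, w in zip(flat, weights):
            p[:] = w.astype(np.float32).reshape(p.shape)


class Adam:
    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, epsilon: float = 1e-7):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, epsilon
        self.t = 0
        pg = model.params_and_grads()
        self.m = [np.zeros_like(p) for p, _ in pg]
        self.v = [np.zeros_like(p) for p, _ in pg]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for (p, g), m, v in zip(self.model.params_and_grads(), self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    loss = float(np.mean(np.square(diff)))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(np.float32)


def bce_with_logits_loss(logits: np.ndarray, target: np.ndarray):
    """Numerically stable binary cross-entropy on raw logits."""
    z, t = logits, target
    loss = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    sig = 1.0 / (1.0 + np.exp(-z))
    grad = (sig - t) / z.size
    return loss, grad.astype(np.float32)


def fit(model: Sequential, x: np.ndarray, y: np.ndarray, *, epochs: int,
        batch_size: int, optimizer: Adam, loss: str = "mse",
        shuffle_seed: int = 0, log: list | None = None) -> list[float]:
    """Minibatch training loop; returns per-epoch mean loss history."""
    loss_fn = {"mse": mse_loss, "bce": bce_with_logits_loss}[loss]
    n = x.shape[0]
    rng = np.random.default_rng(shuffle_seed)
    history: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            pred = model.forward(x[idx], training=True)
            value, grad = loss_fn(pred, y[idx])
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {value}"
                )
            model.backward(grad)
            optimizer.step()
            total += value * len(idx)
            seen += len(idx)
        history.append(total / seen)
        if log is not None:
            log.append({"epoch": epoch, "loss": history[-1]})
    return history
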