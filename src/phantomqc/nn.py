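"""A small CPU neural-network engine (numpy).

Implements exactly the layer set the phantom-scoring networks need:
stride-1 'same' convolutions, per-channel batch normalization, ReLU,
3x3/stride-2 max pooling, inverted dropout, a fully connected head and
softmax cross-entropy, trained with SGD + momentum.  Forward/backward
passes use im2col matrix multiplication; everything is deterministic
under a fixed seed.

Arrays are NCHW ``float64``.  The engine favours clarity and exact
parameter accounting over raw speed; at the reduced problem sizes used
throughout this package that is ample.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: forward caches what backward needs."""

    trainable: tuple = ()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[str, np.ndarray]]:
        return [(name, getattr(self, name)) for name in self.trainable]

    def grads(self) -> list[np.ndarray]:
        return [getattr(self, "d_" + name) for name in self.trainable]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) with 'same' zero padding, stride 1."""
    p = k // 2
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


class Conv2d(Layer):
    """Stride-1 convolution with size-preserving (same) padding."""

    trainable = ("weight", "bias")

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("same padding requires an odd kernel")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                 (out_channels, in_channels, kernel_size,
                                  kernel_size))
        self.bias = np.zeros(out_channels)

    def forward(self, x, train):
        n, c, h, w = x.shape
        k = self.kernel_size
        self._shape = x.shape
        self._cols = _im2col(x, k)
        wmat = self.weight.reshape(self.out_channels, -1)
        out = self._cols @ wmat.T + self.bias
        return out.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, c, h, w = self._shape
        k = self.kernel_size
        dout2 = dout.transpose(0, 2, 3, 1).reshape(-1, self.out_channels)
        self.d_weight = (dout2.T @ self._cols).reshape(self.weight.shape)
        self.d_bias = dout2.sum(axis=0)
        # dx: 'same' correlation of dout with the flipped, transposed kernel
        wflip = self.weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        cols2 = _im2col(dout, k)
        dx = cols2 @ wflip.reshape(self.in_channels, -1).T
        self._cols = None
        return dx.reshape(n, h, w, self.in_channels).transpose(0, 3, 1, 2)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with a learned affine transform."""

    trainable = ("weight", "bias")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.weight = np.ones(channels)
        self.bias = np.zeros(channels)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._ivar = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._ivar[None, :, None, None]
        return self.weight[None, :, None, None] * self._xhat \
            + self.bias[None, :, None, None]

    def backward(self, dout):
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.d_weight = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.d_bias = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.weight[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * self._xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (self._ivar[None, :, None, None] / m
              * (m * dxhat - s1 - self._xhat * s2))
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool3s2(Layer):
    """3x3 max pooling with stride 2, no padding (63 = pool(128))."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        if h < 3 or w < 3:
            raise ValueError("input too small for 3x3 pooling")
        win = sliding_window_view(x, (3, 3), axis=(2, 3))[:, :, ::2, ::2]
        ho, wo = win.shape[2], win.shape[3]
        flat = win.reshape(n, c, ho, wo, 9)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout):
        n, c, h, w = self._shape
        ho, wo = dout.shape[2], dout.shape[3]
        dx = np.zeros(self._shape)
        ai, aj = np.divmod(self._arg, 3)
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        ri = 2 * np.arange(ho)[None, None, :, None] + ai
        cj = 2 * np.arange(wo)[None, None, None, :] + aj
        np.add.at(dx, (ni, ci, ri, cj), dout)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    trainable = ("weight", "bias")

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        self.weight = rng.normal(0.0, np.sqrt(2.0 / in_features),
                                 (in_features, out_features))
        self.bias = np.zeros(out_features)

    def forward(self, x, train):
        self._x = x
        return x @ self.weight + self.bias

    def backward(self, dout):
        self.d_weight = self._x.T @ dout
        self.d_bias = dout.sum(axis=0)
        dx = dout @ self.weight.T
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray,
                  ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient with respect to the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(p[np.arange(n), labels] + 1e-12).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Sequential:
    """An ordered layer stack with softmax-probability output."""

    def __init__(self, layers: list[Layer], seed: int = 0):
        self.layers = layers
        self.seed = seed

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def parameters(self) -> list[np.ndarray]:
        return [arr for layer in self.layers for _, arr in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers if layer.trainable
                for g in layer.grads()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state(self) -> list[np.ndarray]:
        """Copies of all trainable parameters and batch-norm statistics."""
        out = [p.copy() for p in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                out.append(layer.running_mean.copy())
                out.append(layer.running_var.copy())
        return out

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, s in zip(params, state):
            p[...] = s
        extra = iter(state[len(params):])
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = next(extra)
                layer.running_var[...] = next(extra)


class SGDMomentum:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[np.ndarray], lr: float, momentum: float):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, v, g in zip(self.params, self.velocity, grads):
            v *= self.momentum
            v -= self.lr * g
            p += v
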