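"""Minimal 1-D neural-network engine (NumPy, CPU, deterministic).

Implements exactly the layers the curve-regression backbone needs —
1-D convolution, batch normalization, ReLU/Sigmoid, max/average pooling,
flatten, fully-connected — with hand-written backward passes and a
momentum-SGD optimizer. Everything is float64 and seeded, so two runs
with the same seed produce bitwise-identical training trajectories.

Shapes follow the (batch, channels, length) convention. Convolutions
carry no bias when followed by batch normalization (the BN shift absorbs
it); output lengths obey

    L_out = floor((L_in + 2 * padding - kernel) / stride) + 1.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=float)
        self.g = np.zeros_like(self.v)


def _window_index(length: int, kernel: int, stride: int) -> np.ndarray:
    """(L_out, kernel) gather index for sliding windows."""
    l_out = (length - kernel) // stride + 1
    return stride * np.arange(l_out)[:, None] + np.arange(kernel)[None, :]


class Layer:
    def params(self) -> list[Param]:
        return []

    def state(self) -> list[np.ndarray]:
        """Arrays needed to restore the layer (params + buffers)."""
        return [p.v for p in self.params()]

    def set_state(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.params(), arrays, strict=True):
            p.v = np.array(a, dtype=float)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution (cross-correlation), optional bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(out_ch, in_ch, kernel)))
        self.b = Param(np.zeros(out_ch)) if bias else None

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if self.padding:
            x = np.pad(x, ((0, 0), (0, 0), (self.padding, self.padding)))
        if x.shape[2] < self.kernel:
            raise ValueError(
                f"Conv1d: padded length {x.shape[2]} < kernel {self.kernel}"
            )
        idx = _window_index(x.shape[2], self.kernel, self.stride)
        cols = x[:, :, idx]                      # (B, C_in, L_out, K)
        out = np.einsum("bclk,ock->bol", cols, self.w.v, optimize=True)
        if self.b is not None:
            out = out + self.b.v[None, :, None]
        self._cache = (cols, idx, x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, idx, padded_shape = self._cache
        self.w.g += np.einsum("bclk,bol->ock", cols, grad, optimize=True)
        if self.b is not None:
            self.b.g += grad.sum(axis=(0, 2))
        dcols = np.einsum("bol,ock->bclk", grad, self.w.v, optimize=True)
        dx = np.zeros(padded_shape)
        l_out = idx.shape[0]
        # scatter window gradients: for fixed kernel offset k the target
        # positions stride*l + k are distinct, so strided adds suffice
        for k in range(self.kernel):
            dx[:, :, k:k + self.stride * (l_out - 1) + 1:self.stride] += \
                dcols[:, :, :, k]
        if self.padding:
            dx = dx[:, :, self.padding:-self.padding]
        return dx


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(n_ch))
        self.beta = Param(np.zeros(n_ch))
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def state(self) -> list[np.ndarray]:
        return [self.gamma.v, self.beta.v,
                self.running_mean, self.running_var]

    def set_state(self, arrays: list[np.ndarray]) -> None:
        g, b, rm, rv = arrays
        self.gamma.v = np.array(g, float)
        self.beta.v = np.array(b, float)
        self.running_mean = np.array(rm, float)
        self.running_var = np.array(rv, float)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            n = x.shape[0] * x.shape[2]
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            # unbiased variance in the running estimate, as is conventional
            unbiased = var * n / max(n - 1, 1)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std, x.shape, training)
        return self.gamma.v[None, :, None] * xhat + self.beta.v[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape, training = self._cache
        self.gamma.g += (grad * xhat).sum(axis=(0, 2))
        self.beta.g += grad.sum(axis=(0, 2))
        g = grad * self.gamma.v[None, :, None]
        if not training:
            return g * inv_std[None, :, None]
        n = shape[0] * shape[2]
        sum_g = g.sum(axis=(0, 2))[None, :, None]
        sum_gx = (g * xhat).sum(axis=(0, 2))[None, :, None]
        return (inv_std[None, :, None] / n) * (n * g - sum_g - xhat * sum_gx)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class MaxPool1d(Layer):
    def __init__(self, kernel: int, stride: int):
        self.kernel, self.stride = kernel, stride

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[2] < self.kernel:
            raise ValueError(
                f"MaxPool1d: length {x.shape[2]} < kernel {self.kernel}"
            )
        idx = _window_index(x.shape[2], self.kernel, self.stride)
        wins = x[:, :, idx]                       # (B, C, L_out, K)
        arg = wins.argmax(axis=3)
        self._cache = (idx, arg, x.shape)
        return wins.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, arg, shape = self._cache
        dx = np.zeros(shape)
        l_out = arg.shape[2]
        # route each window's gradient to its argmax position; for a fixed
        # kernel offset k the positions stride*l + k never collide
        for k in range(self.kernel):
            dx[:, :, k:k + self.stride * (l_out - 1) + 1:self.stride] += \
                np.where(arg == k, grad, 0.0)
        return dx


class AvgPool1d(Layer):
    def __init__(self, kernel: int, stride: int):
        self.kernel, self.stride = kernel, stride

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[2] < self.kernel:
            raise ValueError(
                f"AvgPool1d: length {x.shape[2]} < kernel {self.kernel}"
            )
        idx = _window_index(x.shape[2], self.kernel, self.stride)
        self._cache = (idx, x.shape)
        return x[:, :, idx].mean(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        dx = np.zeros(shape)
        l_out = idx.shape[0]
        g = grad / self.kernel
        for k in range(self.kernel):
            dx[:, :, k:k + self.stride * (l_out - 1) + 1:self.stride] += g
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / in_f),
                                  size=(out_f, in_f)))
        self.b = Param(np.zeros(out_f))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.w.v.T + self.b.v

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.g += grad.T @ self._x
        self.b.g += grad.sum(axis=0)
        return grad @ self.w.v


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def state_dict(self) -> list[np.ndarray]:
        return [np.array(a) for l in self.layers for a in l.state()]

    def load_state_dict(self, arrays: list[np.ndarray]) -> None:
        i = 0
        for l in self.layers:
            n = len(l.state())
            l.set_state(arrays[i:i + n])
            i += n
        if i != len(arrays):
            raise ValueError("state size mismatch")


class SGD:
    """Momentum SGD; the learning rate is mutable for step decay."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p.v) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.g[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            v *= self.momentum
            v -= self.lr * p.g
            p.v += v


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size
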