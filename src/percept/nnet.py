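"""Small neural-network layer stack over :mod:`percept._autodiff`.

Provides the operation set used by the model backbones — 2-D convolution,
pointwise rectification, max pooling, batch normalization, linear layers,
dropout — plus an Adam optimizer and flat (de)serialization of parameters.
Sized for minutes-scale CPU training of desk-scale models.
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor


class Layer:
    def parameters(self) -> list[Tensor]:
        return []

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Non-trainable state (e.g. batch-norm running moments)."""
        return {}

    def __call__(self, x, train: bool = False):
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def parameters(self):
        return [self.weight, self.bias]

    def __call__(self, x, train: bool = False):
        return x @ self.weight + self.bias


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 rng: np.random.Generator, stride: tuple[int, int] = (1, 1),
                 padding: tuple[int, int] = (0, 0)):
        kh, kw = kernel
        scale = np.sqrt(2.0 / (c_in * kh * kw))
        self.weight = Tensor(rng.normal(0.0, scale, size=(c_out, c_in, kh, kw)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.padding = stride, padding

    def parameters(self):
        return [self.weight, self.bias]

    def __call__(self, x, train: bool = False):
        return ad.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class ReLU(Layer):
    def __call__(self, x, train: bool = False):
        return ad.relu(x)


class MaxPool2d(Layer):
    def __init__(self, kernel: tuple[int, int]):
        self.kernel = kernel

    def __call__(self, x, train: bool = False):
        return ad.maxpool2d(x, self.kernel)


class Flatten(Layer):
    def __call__(self, x, train: bool = False):
        n = x.shape[0]
        return x.reshape(n, int(np.prod(x.shape[1:])))


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (axis 1)."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels), requires_grad=True)
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum, self.eps = momentum, eps

    def parameters(self):
        return [self.gamma, self.beta]

    def state_arrays(self):
        return {"running_mean": self.running_mean,
                "running_var": self.running_var}

    def __call__(self, x, train: bool = False):
        axes = (0,) + tuple(range(2, x.ndim))
        shape = [1] * x.ndim
        shape[1] = -1
        if train:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * ad.value(mu).ravel()
            self.running_var = (1 - m) * self.running_var + m * ad.value(var).ravel()
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xn = (x - mu) / ad.sqrt(var + self.eps)
        return xn * self.gamma.reshape(tuple(shape)) + self.beta.reshape(tuple(shape))


class Dropout(Layer):
    """Inverted dropout; a fresh mask per call, drawn from the layer's rng."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p, self.rng = p, rng

    def __call__(self, x, train: bool = False):
        if not train or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def state_arrays(self):
        out = {}
        for i, l in enumerate(self.layers):
            for k, v in l.state_arrays().items():
                out[f"layer{i}.{k}"] = v
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]):
        for i, l in enumerate(self.layers):
            for k in l.state_arrays():
                key = f"layer{i}.{k}"
                if key in state:
                    getattr(l, k)[...] = state[key]

    def __call__(self, x, train: bool = False):
        for l in self.layers:
            x = l(x, train=train)
        return x


class Adam:
    """Adam optimizer with externally supplied learning rate per step."""

    def __init__(self, params: list[Tensor], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def flatten_params(params: list[Tensor]) -> dict[str, np.ndarray]:
    return {f"param{i}": p.data for i, p in enumerate(params)}


def load_params(params: list[Tensor], arrays: dict[str, np.ndarray]):
    for i, p in enumerate(params):
        p.data[...] = arrays[f"param{i}"]
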