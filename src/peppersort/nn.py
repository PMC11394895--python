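"""Minimal neural-network layer/optimizer toolkit over the autodiff core.

Provides the building blocks the multi-domain networks are assembled
from: grouped 2-D convolution, batch normalization, the activations
the architecture calls for (SiLU inside YOLO-style blocks, GELU and
hard-sigmoid inside the attention modules), SGD with momentum, and a
cross-entropy loss.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Module", "Parameter", "Sequential", "Conv2d", "BatchNorm2d", "Linear",
    "SiLU", "GELU", "ReLU", "HardSigmoid", "Identity",
    "global_avg_pool", "cross_entropy", "SGD",
]


class Parameter(Tensor):
    """A tensor registered as learnable."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: tracks parameters/submodules by attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- flat state dict of raw arrays ---------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v.data.copy() for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        for k, v in getattr(self, "_buffers", {}).items():
            out[prefix + k] = v.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for k, p in self._params.items():
            p.data = np.array(state[prefix + k], dtype=np.float64)
        for k in getattr(self, "_buffers", {}):
            self._buffers[k] = np.array(state[prefix + k], dtype=np.float64)
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"_{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel, stride: int = 1,
                 padding=None, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        if padding is None:                      # "same" for stride 1
            padding = (kh // 2, kw // 2)
        rng = rng or np.random.default_rng()
        fan_in = (cin // groups) * kh * kw
        self.weight = Parameter(_kaiming(rng, (cout, cin // groups, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding,
                         groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps, self.momentum = eps, momentum
        object.__setattr__(self, "_buffers", {
            "running_mean": np.zeros(channels),
            "running_var": np.ones(channels),
        })

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self._buffers["running_mean"] = (
                (1 - self.momentum) * self._buffers["running_mean"]
                + self.momentum * mu.data.reshape(c))
            self._buffers["running_var"] = (
                (1 - self.momentum) * self._buffers["running_var"]
                + self.momentum * var.data.reshape(c))
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(1, c, 1, 1))
            var = Tensor(self._buffers["running_var"].reshape(1, c, 1, 1))
        xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class Linear(Module):
    def __init__(self, nin: int, nout: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_kaiming(rng, (nin, nout), nin))
        self.bias = Parameter(np.zeros(nout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y if self.bias is None else y + self.bias


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x * x.sigmoid()


class GELU(Module):
    """Exact (erf-based) Gaussian error linear unit."""

    def forward(self, x: Tensor) -> Tensor:
        return x * 0.5 * ((x * (1.0 / np.sqrt(2.0))).erf() + 1.0)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class HardSigmoid(Module):
    """clamp((t + 3) / 6, 0, 1)."""

    def forward(self, x: Tensor) -> Tensor:
        return ((x + 3.0) * (1.0 / 6.0)).clip(0.0, 1.0)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C)."""
    return x.mean(axis=(2, 3))


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood; ``labels`` are integer class ids."""
    logp = ad.log_softmax(logits, axis=-1)
    picked = logp[np.arange(len(labels)), np.asarray(labels)]
    return -picked.mean()


class SGD:
    """SGD with momentum and decoupled-style L2 weight decay."""

    def __init__(self, params: list[Parameter], lr: float = 0.01,
                 momentum: float = 0.937, weight_decay: float = 5e-4):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._vel = [np.zeros_like(p.data) for p in params]

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
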