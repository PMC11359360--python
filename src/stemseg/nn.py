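"""Neural-network layers and the Adam optimizer, built on :mod:`stemseg.autograd`.

Feature maps flow through the network as ``(batch, channels, points)`` tensors.
A "pointwise convolution" here is the shared per-point linear map (a 1x1 conv);
batch normalization normalizes each channel over the batch and point axes, with
running statistics for evaluation mode.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "PointwiseConv",
    "BatchNorm",
    "PReLU",
    "Linear",
    "Sequential",
    "Adam",
]


class Module:
    """Base class: parameter registration, train/eval mode, state dicts."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_module(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        object.__setattr__(self, name, module)
        return module

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + k, v) for k, v in self._params.items()]
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = [(prefix + k, v) for k, v in self._buffers.items()]
        for name, m in self._modules.items():
            out.extend(m.named_buffers(prefix + name + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {("param:" + k): v.data.copy() for k, v in self.named_parameters()}
        state.update({("buffer:" + k): v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                params[name].data = np.asarray(value, dtype=params[name].data.dtype)
            else:
                self._set_buffer(name, np.asarray(value))
        return self

    def _set_buffer(self, dotted: str, value: np.ndarray):
        mod: Module = self
        parts = dotted.split(".")
        for p in parts[:-1]:
            mod = mod._modules[p]
        mod._buffers[parts[-1]] = value
        object.__setattr__(mod, parts[-1], value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class PointwiseConv(Module):
    """Shared linear map over the channel axis of a (B, C, ...) tensor."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Tensor(_kaiming(rng, in_channels, (out_channels, in_channels)),
                             requires_grad=True)
        self.bias = (Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)
                     if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        b = x.shape[0]
        flat = x.reshape(b, self.in_channels, -1)
        out = self.weight @ flat  # (Cout,Cin) @ (B,Cin,S) -> (B,Cout,S)
        if self.bias is not None:
            out = out + self.bias.reshape(1, self.out_channels, 1)
        return out.reshape((b, self.out_channels) + x.shape[2:])


class Linear(Module):
    """Dense layer on (..., in_features) tensors."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Tensor(_kaiming(rng, in_features, (in_features, out_features)),
                             requires_grad=True)
        self.bias = (Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)
                     if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm(Module):
    """Per-channel normalization of (B, C, ...) over batch and spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self._buffers["running_mean"] = np.zeros(channels, dtype=np.float32)
        self._buffers["running_var"] = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0,) + tuple(range(2, x.ndim))
        shape = (1, self.channels) + (1,) * (x.ndim - 2)
        if self.training:
            mu = x.data.mean(axis=axes, keepdims=True)
            xm = x.data - mu
            var = (xm * xm).mean(axis=axes, keepdims=True)
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            m = self.momentum
            self._buffers["running_mean"] = (1 - m) * rm + m * mu.reshape(-1)
            self._buffers["running_var"] = (1 - m) * rv + m * var.reshape(-1)
        else:
            mu = self._buffers["running_mean"].reshape(shape)
            var = self._buffers["running_var"].reshape(shape)
            xm = x.data - mu
        inv_std = 1.0 / np.sqrt(var + self.eps)
        gamma, beta = self.gamma, self.beta
        scale = (gamma.data.reshape(shape) * inv_std).astype(x.data.dtype)
        out_data = xm * scale + beta.data.reshape(shape)
        n_red = x.data.size // self.channels
        training = self.training

        def backward(g):
            dgamma = (g * xm).sum(axis=axes) * inv_std.reshape(-1)
            dbeta = g.sum(axis=axes)
            if training:
                # standard batch-norm backward through the batch statistics
                dx = scale * (g - dbeta.reshape(shape) / n_red) \
                    - xm * (scale * inv_std * dgamma.reshape(shape) / n_red)
            else:
                dx = g * scale
            return dx, dgamma.astype(gamma.data.dtype), dbeta.astype(beta.data.dtype)

        return Tensor._make(out_data.astype(x.data.dtype, copy=False),
                            (x, gamma, beta), backward)


class PReLU(Module):
    """Parametric ReLU, one learnable negative slope per channel.

    f(x) = x for x >= 0, alpha * x for x < 0.
    """

    def __init__(self, channels: int, init: float = 0.25):
        super().__init__()
        self.channels = channels
        self.alpha = Tensor(np.full(channels, init, dtype=np.float32),
                            requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, self.channels) + (1,) * (x.ndim - 2)
        alpha = self.alpha
        a = alpha.data.reshape(shape)
        neg_mask = x.data < 0
        out_data = np.where(neg_mask, x.data * a, x.data)
        axes = (0,) + tuple(range(2, x.ndim))

        def backward(g):
            dx = np.where(neg_mask, g * a, g)
            dalpha = (g * x.data * neg_mask).sum(axis=axes)
            return dx, dalpha.astype(alpha.data.dtype)

        return Tensor._make(out_data, (x, alpha), backward)


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(np.float32)
        return x * Tensor(keep / (1.0 - self.p))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self.register_module(f"layer{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam with decoupled learning rate (set per step via ``lr``)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data = p.data - self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
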