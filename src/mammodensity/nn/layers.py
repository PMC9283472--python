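"""Neural-network layers on top of :mod:`mammodensity.nn.tensor`.

Modules register parameters (trainable tensors) and buffers (running
statistics) by name so a model can be flattened into a checkpoint dict.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, conv_transpose2d

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "GroupNorm",
    "InstanceNorm2d",
    "ReLU",
    "make_norm",
]


class Module:
    """Base class: tracks child modules, parameters and buffers."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(value, dtype=np.float32), requires_grad=True)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=np.float32)
        self._buffers[name] = arr
        return arr

    def children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)) and not isinstance(val, str):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, t in self._params.items():
            yield prefix + name, t
        for cname, child in self.children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [t for _, t in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for cname, child in self.children():
            yield from child.named_buffers(prefix + cname + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for key, arr in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                params[name].data = np.asarray(arr, dtype=params[name].data.dtype)
            elif kind == "buffer":
                self._set_buffer(name, np.asarray(arr))

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        owners = {name: (mod, local) for mod, name, local in _buffer_owners(self)}
        mod, local = owners[dotted]
        mod._buffers[local][...] = value

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self.children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _buffer_owners(root: Module, prefix: str = ""):
    for name in root._buffers:
        yield root, prefix + name, name
    for cname, child in root.children():
        yield from _buffer_owners(child, prefix + cname + ".")


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.items = list(modules)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x


class ReLU(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x):
        return x.relu()


class Conv2d(Module):
    """Stride-1 'same' 2-D convolution; He-normal init; optional weight
    standardization (weights normalized per output channel before use)."""

    def __init__(self, in_ch, out_ch, kernel, dilation=1, bias=True,
                 rng=None, weight_standardize=False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = self.register_parameter(
            "weight", rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel))
        )
        self.bias = self.register_parameter("bias", np.zeros(out_ch)) if bias else None
        self.dilation = int(dilation)
        self.weight_standardize = weight_standardize

    def forward(self, x):
        w = self.weight
        if self.weight_standardize:
            m = w.mean(axis=(1, 2, 3), keepdims=True)
            v = ((w - m) ** 2).mean(axis=(1, 2, 3), keepdims=True)
            w = (w - m) / ((v + 1e-5) ** 0.5)
        return conv2d(x, w, self.bias, dilation=self.dilation)


class ConvTranspose2d(Module):
    """Kernel-2 stride-2 transpose convolution (2x upsampling)."""

    def __init__(self, in_ch, out_ch, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (in_ch * 4))
        self.weight = self.register_parameter(
            "weight", rng.normal(0.0, std, size=(in_ch, out_ch, 2, 2))
        )
        self.bias = self.register_parameter("bias", np.zeros(out_ch))

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.gamma = self.register_parameter("gamma", np.ones((1, channels, 1, 1)))
        self.beta = self.register_parameter("beta", np.zeros((1, channels, 1, 1)))
        self.register_buffer("running_mean", np.zeros((1, channels, 1, 1)))
        self.register_buffer("running_var", np.ones((1, channels, 1, 1)))
        self.eps = eps
        self.momentum = momentum

    def forward(self, x):
        if self.training:
            m = x.mean(axis=(0, 2, 3), keepdims=True)
            v = ((x - m) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            rm *= 1.0 - self.momentum
            rm += self.momentum * m.data
            rv *= 1.0 - self.momentum
            rv += self.momentum * v.data
        else:
            m = Tensor(self._buffers["running_mean"])
            v = Tensor(self._buffers["running_var"])
        xhat = (x - m) / ((v + self.eps) ** 0.5)
        return xhat * self.gamma + self.beta


class GroupNorm(Module):
    """Per-sample normalization over channel groups (batch-size independent)."""

    def __init__(self, groups, channels, eps=1e-5):
        super().__init__()
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.groups = groups
        self.channels = channels
        self.eps = eps
        self.gamma = self.register_parameter("gamma", np.ones((1, channels, 1, 1)))
        self.beta = self.register_parameter("beta", np.zeros((1, channels, 1, 1)))

    def forward(self, x):
        b, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(b, g, c // g * h * w)
        m = xg.mean(axis=2, keepdims=True)
        v = ((xg - m) ** 2).mean(axis=2, keepdims=True)
        xhat = ((xg - m) / ((v + self.eps) ** 0.5)).reshape(b, c, h, w)
        return xhat * self.gamma + self.beta


class InstanceNorm2d(GroupNorm):
    def __init__(self, channels, eps=1e-5):
        super().__init__(channels, channels, eps=eps)


def make_norm(kind: str, channels: int, groups: int = 4) -> Module:
    """Factory for the normalization-layer variants exposed in the config."""
    kind = kind.lower()
    if kind == "batch":
        return BatchNorm2d(channels)
    if kind == "instance":
        return InstanceNorm2d(channels)
    if kind in ("group", "wsgroup", "weight-standardized+group"):
        g = min(groups, channels)
        while channels % g:
            g -= 1
        return GroupNorm(g, channels)
    raise ValueError(f"unknown norm layer kind: {kind!r}")
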