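"""Layer modules with trainable parameters and a torch-like Module tree.

Weight initialisation draws from a process-global generator; call
:func:`manual_seed` before building a model to make construction (and hence
training) reproducible.
"""

from __future__ import annotations

import pickle
from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor

_rng = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    global _rng
    _rng = np.random.default_rng(seed)


class Module:
    def __init__(self):
        self.training = True

    # parameter / submodule discovery by attribute walk
    def children(self) -> Iterator["Module"]:
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def modules(self) -> Iterator["Module"]:
        # a submodule may be referenced from several attributes; visit once
        seen: set[int] = set()
        stack: list[Module] = [self]
        while stack:
            module = stack.pop()
            if id(module) in seen:
                continue
            seen.add(id(module))
            yield module
            stack.extend(module.children())

    def parameters(self) -> list[Parameter]:
        params, seen = [], set()
        for module in self.modules():
            for value in module.__dict__.values():
                if isinstance(value, Parameter) and id(value) not in seen:
                    seen.add(id(value))
                    params.append(value)
        return params

    def train(self, mode: bool = True) -> "Module":
        for module in self.modules():
            module.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # whole-tree (de)serialisation; config travels with the weights
    def state_arrays(self) -> list[np.ndarray]:
        arrays = []
        for module in self.modules():
            for name in sorted(module.__dict__):
                value = module.__dict__[name]
                if isinstance(value, Parameter):
                    arrays.append(value.data)
                elif isinstance(value, np.ndarray):
                    arrays.append(value)
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for module in self.modules():
            for name in sorted(module.__dict__):
                value = module.__dict__[name]
                if isinstance(value, Parameter):
                    value.data = next(it).astype(np.float32)
                elif isinstance(value, np.ndarray):
                    module.__dict__[name] = next(it)

    def save(self, path, config: dict | None = None) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"config": config or {}, "arrays": self.state_arrays()}, fh)

    @staticmethod
    def load_checkpoint(path) -> tuple[dict, list[np.ndarray]]:
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        return blob["config"], blob["arrays"]


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]


class _MacCounter:
    """Accumulates multiply–accumulate counts during a forward pass."""

    active: "_MacCounter | None" = None

    def __init__(self):
        self.total = 0

    def __enter__(self):
        _MacCounter.active = self
        return self

    def __exit__(self, *exc):
        _MacCounter.active = None


def _record_macs(n: int) -> None:
    if _MacCounter.active is not None:
        _MacCounter.active.total += n


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0,
                 groups=1, bias=True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        fan_in = in_channels // groups * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Parameter(
            _rng.normal(0.0, scale,
                        (out_channels, in_channels // groups, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = F.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)
        _record_macs((self.in_channels // self.groups) * self.out_channels
                     * self.kernel_size ** 2 * out.shape[2] * out.shape[3])
        return out


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        scale = np.sqrt(1.0 / in_features)
        self.weight = Parameter(_rng.uniform(-scale, scale, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        _record_macs(self.in_features * self.out_features * int(np.prod(x.shape[:-1])))
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        c = self.num_features
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c)
            inv = (var + self.eps) ** -0.5
            xhat = centred * inv
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            inv = 1.0 / np.sqrt(self.running_var.reshape(1, c, 1, 1) + self.eps)
            xhat = (x - Tensor(mu)) * Tensor(inv)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class MaxPool2d(Module):
    def __init__(self, kernel_size, stride=None, padding=0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class AvgPool2d(Module):
    def __init__(self, kernel_size, stride=None, padding=0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.avg_pool2d(x, self.kernel_size, self.stride, self.padding)


class GlobalAvgPool(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.global_avg_pool(x)


class UpsampleNearest2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.upsample_nearest2x(x)


# ---------------------------------------------------------------------------
# accounting

_COUNTABLE = (Conv2d, Linear)
_MAC_FREE = (BatchNorm2d, ReLU, Identity, MaxPool2d, AvgPool2d, GlobalAvgPool,
             UpsampleNearest2x, Sequential)


def count_parameters(model: Module) -> int:
    """Exact number of trainable scalars in the module tree."""
    return int(sum(p.data.size for p in model.parameters()))


def count_macs(model: Module, input_hw: int, in_channels: int = 3) -> int:
    """Multiply–accumulate count for one forward pass at ``input_hw`` square input.

    Convolutions and affine layers contribute one MAC per scalar product;
    pooling, normalisation and activations are excluded.  Raises for module
    types whose cost convention is undeclared.
    """
    for module in model.modules():
        owns_params = any(isinstance(v, Parameter) for v in module.__dict__.values())
        if owns_params and not isinstance(module, _COUNTABLE + (BatchNorm2d,)):
            raise TypeError(f"unsupported layer type for MAC counting: {type(module).__name__}")
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((1, in_channels, input_hw, input_hw), dtype=np.float32))
    with _MacCounter() as counter:
        model(x)
    model.train(was_training)
    return counter.total
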