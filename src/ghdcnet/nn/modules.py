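"""Layer modules over the autograd primitives: parameter registry, state dicts.

Mirrors the familiar Module idiom: submodules and parameters register through
attribute assignment, ``state_dict``/``load_state_dict`` serialize flat
name -> array mappings (including batch-norm running statistics), and
``train()``/``eval()`` toggle normalization behaviour.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Identity",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "AvgPool2d",
    "UpsampleBilinear",
]

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs) -> Tensor:
        return self.forward(*args, **kwargs)

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def parameters(self) -> Iterator[Parameter]:
        for m in self.modules():
            yield from m._parameters.values()

    def named_state(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray, bool]]:
        for name, p in self._parameters.items():
            yield prefix + name, p.data, True
        for name, b in self._buffers.items():
            yield prefix + name, b, False
        for name, m in self._modules.items():
            yield from m.named_state(prefix + name + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: arr.copy() for name, arr, _ in self.named_state()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {name: (arr, is_param) for name, arr, is_param in self.named_state()}
        missing = set(own) - set(state)
        unexpected = set(state) - set(own)
        if missing or unexpected:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(unexpected)}")
        for name, (arr, _) in own.items():
            src = np.asarray(state[name])
            if src.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}: {src.shape} vs {arr.shape}")
            arr[...] = src

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, *, rng,
                 stride=1, padding=0, dilation=1, bias=True):
        super().__init__()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(_he_init(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.dilation)


class ConvTranspose2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, *, rng,
                 stride=1, padding=0, output_padding=0, bias=True):
        super().__init__()
        self.stride, self.padding, self.output_padding = stride, padding, output_padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(_he_init(rng, (in_channels, out_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride,
                                  self.padding, self.output_padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=DTYPE))
        self.register_buffer("running_var", np.ones(num_features, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class AvgPool2d(Module):
    """Fixed 2x2 stride-2 average pooling."""

    def forward(self, x: Tensor) -> Tensor:
        return F.avg_pool2d(x)


class UpsampleBilinear(Module):
    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x: Tensor) -> Tensor:
        return F.upsample_bilinear(x, scale=self.scale)
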