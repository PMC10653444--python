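"""Trainable layers on top of the autograd engine."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import functional as F
from .autograd import Tensor, prelu

__all__ = ["Module", "Conv3d", "ConvTranspose3d", "PReLU"]


def _walk(name: str, value) -> Iterator[tuple[str, "Tensor"]]:
    if isinstance(value, Tensor):
        if value.requires_grad:
            yield name, value
    elif isinstance(value, Module):
        yield from value.named_parameters(name)
    elif isinstance(value, (list, tuple)):
        for i, item in enumerate(value):
            yield from _walk(f"{name}.{i}", item)


class Module:
    """Minimal container: children and parameters discovered via __dict__
    (arbitrarily nested lists/tuples of sub-modules included)."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            yield from _walk(full, value)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int,
                     neg_slope: float = 0.25) -> np.ndarray:
    # fan-in scaled uniform init, accounting for the PReLU negative slope
    gain = math.sqrt(2.0 / (1.0 + neg_slope ** 2))
    bound = gain * math.sqrt(3.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 stride=1, padding=0, dilation=1, *, rng: np.random.Generator):
        k = F._triple(kernel_size)
        fan_in = in_channels * k[0] * k[1] * k[2]
        self.weight = Tensor(_kaiming_uniform(
            rng, (out_channels, in_channels) + k, fan_in), requires_grad=True)
        bound = 1.0 / math.sqrt(fan_in)
        self.bias = Tensor(rng.uniform(-bound, bound, out_channels).astype(np.float32),
                           requires_grad=True)
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias,
                        stride=self.stride, padding=self.padding,
                        dilation=self.dilation)


class ConvTranspose3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 stride=2, *, rng: np.random.Generator):
        k = F._triple(kernel_size)
        fan_in = in_channels * k[0] * k[1] * k[2]
        self.weight = Tensor(_kaiming_uniform(
            rng, (in_channels, out_channels) + k, fan_in), requires_grad=True)
        bound = 1.0 / math.sqrt(fan_in)
        self.bias = Tensor(rng.uniform(-bound, bound, out_channels).astype(np.float32),
                           requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv_transpose3d(x, self.weight, self.bias, stride=self.stride)


class PReLU(Module):
    def __init__(self, n_channels: int, init: float = 0.25):
        self.slope = Tensor(np.full(n_channels, init, dtype=np.float32),
                            requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return prelu(x, self.slope)
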