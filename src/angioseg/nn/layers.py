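"""Layer modules over the autodiff tape.

Modules hold :class:`Parameter` leaves and recurse through attributes (and
lists of sub-modules) for parameter collection and state (de)serialization.
Weight initialization is Kaiming-style for convolutions, seeded through an
explicit ``numpy.random.Generator`` so identical seeds give identical nets.
"""

from __future__ import annotations

from typing import Dict, Iterator, Optional, Tuple

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container: named parameters, state dict, call syntax."""

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, attr in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(attr, Parameter):
                yield full, attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(full + ".")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray],
                        strict: bool = True) -> None:
        own = dict(self.named_parameters())
        if strict:
            missing = sorted(set(own) - set(state))
            extra = sorted(set(state) - set(own))
            if missing or extra:
                raise KeyError(f"state mismatch; missing={missing} extra={extra}")
        for k, p in own.items():
            if k in state:
                arr = np.asarray(state[k], dtype=np.float32)
                if arr.shape != p.data.shape:
                    raise ValueError(
                        f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
                p.data = arr.copy()


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = True, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.weight = Parameter(
            _kaiming(rng, (out_ch, in_ch, kernel, kernel),
                     in_ch * kernel * kernel))
        self.bias = Parameter(np.zeros(out_ch, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                        self.dilation)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 stride: int = 2, padding: int = 1, output_padding: int = 1,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding = stride, padding
        self.output_padding = output_padding
        self.weight = Parameter(
            _kaiming(rng, (in_ch, out_ch, kernel, kernel),
                     in_ch * kernel * kernel))
        self.bias = Parameter(np.zeros(out_ch, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return T.conv_transpose2d(x, self.weight, self.bias, self.stride,
                                  self.padding, self.output_padding)


class InstanceNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, np.float32))
        self.beta = Parameter(np.zeros(channels, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return T.instance_norm(x, self.gamma, self.beta, self.eps)


class ConvINReLU(Module):
    """Conv -> instance norm -> ReLU, the ubiquitous unit in the net."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng=None):
        self.conv = Conv2d(in_ch, out_ch, kernel, stride, padding, rng=rng)
        self.norm = InstanceNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return T.relu(self.norm(self.conv(x)))


class ResidualBlock(Module):
    """Basic 3x3+3x3 residual block with optional downsampling projection."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1, rng=None):
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, rng=rng)
        self.norm1 = InstanceNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, padding=1, rng=rng)
        self.norm2 = InstanceNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)
            self.proj_norm = InstanceNorm2d(out_ch)
        else:
            self.proj = None
            self.proj_norm = None

    def forward(self, x: Tensor) -> Tensor:
        y = T.relu(self.norm1(self.conv1(x)))
        y = self.norm2(self.conv2(y))
        if self.proj is not None:
            x = self.proj_norm(self.proj(x))
        return T.relu(T.add(y, x))
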