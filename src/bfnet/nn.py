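"""Neural-network layer primitives built on :mod:`bfnet.autodiff`.

A deliberately small module system: layers register :class:`Parameter`
attributes and non-trainable buffers (batch-norm running statistics), and a
``Module`` tree provides parameter traversal, train/eval switching and a
flat ``state_dict`` for checkpointing.

Weight initialisation draws from a process-global generator; call
:func:`seed_all` before constructing a model to make two constructions
bit-identical.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import DTYPE, Parameter, Tensor, conv2d, conv_transpose2d

_init_rng = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Reset the global initialisation RNG (model construction determinism)."""
    global _init_rng
    _init_rng = np.random.default_rng(seed)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal --------------------------------------------------------
    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, ModuleList):
                for i, m in enumerate(value):
                    yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffers", ()):
            yield prefix + name, getattr(self, name)
        for name, child in self.children():
            yield from child.named_buffers(prefix + name + ".")

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- modes -------------------------------------------------------------
    def train(self):
        self.training = True
        for _, c in self.children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self.children():
            c.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state_dict missing entries: {sorted(missing)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}"
                )
            p.data = state[name].astype(DTYPE).copy()
        for name in buffers:
            getattr_owner, attr = self._resolve(name)
            setattr(getattr_owner, attr, state[name].astype(DTYPE).copy())

    def _resolve(self, dotted: str):
        obj = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            if part.isdigit():
                obj = obj[int(part)]
            else:
                obj = getattr(obj, part)
        return obj, parts[-1]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    pass


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.layers:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Conv2d(Module):
    """Square-kernel 2-D convolution with He-normal init."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            _init_rng.normal(
                0.0, std, size=(out_channels, in_channels, kernel_size, kernel_size)
            )
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    """Learnable upsampling; kernel 4 / stride 2 / padding 1 doubles H and W."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 4,
        stride: int = 2,
        padding: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            _init_rng.normal(
                0.0, std, size=(in_channels, out_channels, kernel_size, kernel_size)
            )
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(
            x, self.weight, self.bias, stride=self.stride, padding=self.padding
        )


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel, with running stats."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))
        self.running_mean = np.zeros((1, channels, 1, 1), dtype=DTYPE)
        self.running_var = np.ones((1, channels, 1, 1), dtype=DTYPE)
        self._buffers = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data
            ).astype(DTYPE)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data
            ).astype(DTYPE)
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) * (
                (Tensor(self.running_var) + self.eps) ** -0.5
            )
        return xhat * self.gamma + self.beta


class ChannelLayerNorm(Module):
    """Layer normalisation across the channel axis of an NCHW tensor.

    Used inside the attention bottleneck, where the input is a 1x1 context
    map and per-channel batch statistics would be degenerate.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        if self.channels == 1:
            # single-channel statistics are degenerate (x - mean(x) == 0 would
            # zero the signal and block gradients); apply only the affine part
            return x * self.gamma + self.beta
        mu = x.mean(axis=1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=1, keepdims=True)
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class ConvBlock(Module):
    """Convolution -> batch norm -> ReLU, the network's basic unit."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        padding: int | None = None,
    ):
        super().__init__()
        if padding is None:
            padding = kernel_size // 2
        self.conv = Conv2d(
            in_channels, out_channels, kernel_size, stride=stride, padding=padding,
            bias=False,
        )
        self.norm = BatchNorm2d(out_channels)
        self.act = ReLU()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.norm(self.conv(x)))


class UpBlock(Module):
    """Transposed-conv x2 upsampling -> batch norm -> ReLU."""

    def __init__(self, in_channels: int, out_channels: int):
        super().__init__()
        self.up = ConvTranspose2d(in_channels, out_channels, 4, 2, 1, bias=False)
        self.norm = BatchNorm2d(out_channels)
        self.act = ReLU()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.norm(self.up(x)))
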