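"""Layer/module abstractions on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from . import tensor as F
from .tensor import Tensor

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "SeparableConv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "xavier_uniform",
]


def xavier_uniform(shape, fan_in: int, fan_out: int, rng: np.random.Generator) -> np.ndarray:
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield f"{prefix}{name}", value
        for name, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield f"{prefix}{name}", value
        for name, child in self._children():
            yield from child.buffers(prefix=f"{prefix}{name}.")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"buffer:{name}": b.copy() for name, b in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        bufs = dict(self.buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = bufs[key[len("buffer:") :]]
                buf[...] = value
            else:
                params[key].data[...] = value


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._modules: list[Module] = list(modules)

    def append(self, module: Module):
        self._modules.append(module)

    def __iter__(self):
        return iter(self._modules)

    def __len__(self):
        return len(self._modules)

    def __getitem__(self, i):
        return self._modules[i]

    def _children(self):
        for i, m in enumerate(self._modules):
            yield str(i), m

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError("ModuleList is a container")


class Sequential(ModuleList):
    def forward(self, x: Tensor) -> Tensor:
        for m in self._modules:
            x = m(x)
        return x


class Conv2d(Module):
    """Stride-1 same-padding convolution with Xavier-initialized weights."""

    def __init__(self, in_channels, out_channels, kernel_size, rng, bias=True):
        super().__init__()
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size, kernel_size)
        kh, kw = kernel_size
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {kernel_size}")
        fan_in = in_channels * kh * kw
        fan_out = out_channels * kh * kw
        self.weight = Tensor(
            xavier_uniform((out_channels, in_channels, kh, kw), fan_in, fan_out, rng),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias)


class SeparableConv2d(Module):
    """k x k convolution factored into k x 1 followed by 1 x k passes."""

    def __init__(self, in_channels, out_channels, k, rng, bias=True):
        super().__init__()
        self.vertical = Conv2d(in_channels, out_channels, (k, 1), rng, bias=False)
        self.horizontal = Conv2d(out_channels, out_channels, (1, k), rng, bias=bias)

    def forward(self, x: Tensor) -> Tensor:
        return self.horizontal(self.vertical(x))


class BatchNorm2d(Module):
    def __init__(self, channels, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
        )


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.relu(x)


class MaxPool2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2(x)


class Upsample2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.upsample2(x)
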