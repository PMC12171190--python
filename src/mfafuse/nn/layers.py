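"""Layer/module abstractions on top of the autograd core."""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError
from .autograd import Tensor, batch_norm2d, conv2d, conv_transpose2x

__all__ = ["DTYPE", "Parameter", "Module", "Conv2d", "ConvTranspose2x", "BatchNorm2d", "ModuleList"]

#: working precision of the network; the functional/oracle APIs stay float64
DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data, trainable: bool = True):
        super().__init__(data, requires_grad=trainable)


class Module:
    """Lightweight module base: parameter traversal, state dicts, train/eval."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, (Parameter, Module)):
                yield name, value

    def named_parameters(self, prefix: str = ""):
        for name, value in self._children():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            else:
                yield from value.named_parameters(prefix=full + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield f"{prefix}{name}", value
        for name, value in self._children():
            if isinstance(value, Module):
                yield from value.buffers(prefix=f"{prefix}{name}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"__buffer__{name}": b.copy() for name, b in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.buffers())
        for key, value in state.items():
            if key.startswith("__buffer__"):
                buf = bufs[key[len("__buffer__"):]]
                buf[...] = value
            else:
                params[key].data = np.array(value)

    def train(self):
        self.training = True
        for _, child in self._children():
            if isinstance(child, Module):
                child.train()
        return self

    def eval(self):
        self.training = False
        for _, child in self._children():
            if isinstance(child, Module):
                child.eval()
        return self

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        modules = list(modules)
        for i, m in enumerate(modules):
            setattr(self, f"m{i}", m)
        self._n = len(modules)

    def __len__(self):
        return self._n

    def __getitem__(self, i) -> Module:
        return getattr(self, f"m{int(i) % self._n if i < 0 else i}")

    def __iter__(self):
        return (getattr(self, f"m{i}") for i in range(self._n))

    def forward(self, *a, **k):  # pragma: no cover - containers are not called
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        init: str = "he",
    ):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ConfigurationError(f"kernel_size must be odd, got {kernel_size}")
        self.stride = stride
        self.pad = kernel_size // 2
        fan_in = in_channels * kernel_size * kernel_size
        if init == "zeros":
            w = np.zeros((out_channels, in_channels, kernel_size, kernel_size), dtype=DTYPE)
        else:
            if rng is None:
                raise ConfigurationError("rng required for random initialization")
            w = _he_init(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ConvTranspose2x(Module):
    """Kernel-2, stride-2 transposed convolution: exact 2x spatial upsampling."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * 4
        self.weight = Parameter(_he_init(rng, (in_channels, out_channels, 2, 2), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2x(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=DTYPE))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
        )
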