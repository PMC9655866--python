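"""Layer modules built on the autodiff core: 3D conv, batch norm, blocks."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Var


class Parameter(Var):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class with recursive parameter / submodule discovery."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        def walk(v):
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    yield from walk(item)

        for v in self.__dict__.values():
            yield from walk(v)

    def parameters(self) -> list[Parameter]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
        for child in self._children():
            out.extend(child.parameters())
        return out

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (batch-norm running statistics)."""
        out = []
        for k, v in self.__dict__.items():
            if isinstance(v, np.ndarray) and k.startswith("running_"):
                out.append(v)
        for child in self._children():
            out.extend(child.buffers())
        return out

    def train(self, flag: bool = True):
        self.training = flag
        for child in self._children():
            child.train(flag)
        return self

    def eval(self):
        return self.train(False)

    # -- flat state for checkpointing ---------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()] + self.buffers()

    def load_state_arrays(self, arrays):
        slots = self.state_arrays()
        if len(slots) != len(arrays):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects {len(slots)}"
            )
        for slot, arr in zip(slots, arrays):
            if slot.shape != arr.shape:
                raise ValueError(f"shape mismatch {slot.shape} vs {arr.shape}")
            slot[...] = arr


def kaiming_normal(rng: np.random.Generator, shape, fan_in, a=0.0, dtype=np.float32):
    """He initialisation: N(0, gain^2/fan_in), gain^2 = 2/(1+a^2)."""
    std = np.sqrt(2.0 / ((1.0 + a * a) * fan_in))
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Conv3d(Module):
    def __init__(self, cin, cout, kernel, stride=1, pad=None, bias=True,
                 rng=None, init_a=0.0, dtype=np.float32):
        super().__init__()
        if pad is None:
            pad = (kernel - 1) // 2
        self.cin, self.cout = cin, cout
        self.kernel, self.stride, self.pad = kernel, stride, pad
        rng = rng or np.random.default_rng()
        fan_in = cin * kernel**3
        self.weight = Parameter(
            kaiming_normal(rng, (cout, cin, kernel, kernel, kernel), fan_in,
                           a=init_a, dtype=dtype)
        )
        self.bias = Parameter(np.zeros(cout, dtype=dtype)) if bias else None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x):
        return ad.conv3d(x, self.weight, self.bias, self.stride, self.pad)


class BatchNorm3d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return ad.batchnorm3d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class ConvBlock(Module):
    """conv -> (batch norm) -> activation; bias only when norm is absent."""

    def __init__(self, cin, cout, kernel=3, stride=1, pad=None, act="relu",
                 norm=True, rng=None, dtype=np.float32):
        super().__init__()
        slope = 0.2 if act == "lrelu" else (1.0 if act in (None, "tanh") else 0.0)
        self.conv = Conv3d(cin, cout, kernel, stride, pad, bias=not norm,
                           rng=rng, init_a=slope, dtype=dtype)
        self.norm = BatchNorm3d(cout, dtype=dtype) if norm else None
        self.act = act

    def forward(self, x):
        y = self.conv(x)
        if self.norm is not None:
            y = self.norm(y)
        if self.act == "relu":
            y = ad.relu(y)
        elif self.act == "lrelu":
            y = ad.leaky_relu(y, 0.2)
        elif self.act == "tanh":
            y = ad.tanh(y)
        return y


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x
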