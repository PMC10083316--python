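"""Layer abstractions over the autodiff engine.

Modules register parameters/submodules on attribute assignment, expose
``state_dict``/``load_state_dict`` for checkpointing, and carry a train/eval
flag that batch normalisation consults.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

DEFAULT_DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DEFAULT_DTYPE), requires_grad=True)


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated at two standard deviations (resampled)."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # ----------------------------------------------------------- traversal
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    # --------------------------------------------------------- state dicts
    def state_dict(self) -> dict:
        out = {f"param:{k}": p.data.copy() for k, p in self.named_parameters()}
        out.update({f"buffer:{k}": b.copy() for k, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unexpected parameter {name!r}")
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name!r}")
                params[name].data = value.astype(params[name].data.dtype)
            else:
                mod, attr = self, name
                while "." in attr:
                    head, attr = attr.split(".", 1)
                    mod = mod._modules[head]
                mod.register_buffer(attr, value.copy())
        missing = set(params) - {
            k.split(":", 1)[1] for k in state if k.startswith("param:")
        }
        if missing:
            raise KeyError(f"missing parameters: {sorted(missing)}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 padding=None, bias: bool = True, init: str = "he"):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel * kernel
        if init == "he":
            w = he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        else:
            w = trunc_normal(rng, (out_ch, in_ch, kernel, kernel))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ValueError(
                f"Conv2d configured for {self.in_ch} channels, got {x.shape[1]}"
            )
        return x.conv2d(self.weight, self.bias, padding=self.padding)


class ConvTranspose2d(Module):
    """Kernel-2 stride-2 transposed convolution (the decoder's 2x upsampler)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Parameter(he_normal(rng, (in_ch, out_ch, 2, 2), in_ch * 4))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d_2x(self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator,
                 init: str = "trunc"):
        super().__init__()
        if init == "trunc":
            w = trunc_normal(rng, (in_f, out_f))
        else:
            w = he_normal(rng, (in_f, out_f), in_f)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_f))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    """Normalisation over the last axis with learned affine."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.register_buffer("running_mean", np.zeros(ch, dtype=DEFAULT_DTYPE))
        self.register_buffer("running_var", np.ones(ch, dtype=DEFAULT_DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean[:] = (1 - m) * self.running_mean + m * mu.data.reshape(C)
            self.running_var[:] = (1 - m) * self.running_var + m * var.data.reshape(C)
        else:
            mu = Tensor(self.running_mean.reshape(1, C, 1, 1))
            var = Tensor(self.running_var.reshape(1, C, 1, 1))
            xc = x - mu
        g = self.gamma.reshape(1, C, 1, 1)
        b = self.beta.reshape(1, C, 1, 1)
        return xc / (var + self.eps).sqrt() * g + b


class ConvBNReLU(Module):
    """Convolutional layer: convolution, batch normalisation, ReLU."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, rng, bias=False)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()
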