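"""Neural-network building blocks over the autodiff engine.

Follows the familiar Module/Parameter idiom: modules own parameters and
submodules, expose ``parameters()`` / ``state_dict()`` and a train/eval
switch that controls batch-norm statistics.
"""

from __future__ import annotations

import math

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    # attribute magic keeps registration implicit, like the major frameworks
    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = np.asarray(value, dtype=np.float64)
        object.__setattr__(self, name, self._buffers[name])

    def _set_buffer(self, name: str, value: np.ndarray):
        prev = self._buffers.get(name)
        dtype = prev.dtype if prev is not None else np.float64
        self._buffers[name] = np.asarray(value, dtype=dtype)
        object.__setattr__(self, name, self._buffers[name])

    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield (prefix + k, p)
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def astype(self, dtype):
        """Cast all parameters and buffers (e.g. to float32 for faster
        CPU training)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for m in self.modules():
            for k in list(m._buffers):
                m._buffers[k] = m._buffers[k].astype(dtype)
                object.__setattr__(m, k, m._buffers[k])
        return self

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: p.data.copy() for k, p in self._params.items()}
        out.update({prefix + k: v.copy() for k, v in self._buffers.items()})
        for name, mod in self._modules.items():
            out.update(mod.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for k, p in self._params.items():
            p.data = np.asarray(state[prefix + k], dtype=np.float64).reshape(p.data.shape)
        for k in list(self._buffers):
            self._set_buffer(k, state[prefix + k])
        for name, mod in self._modules.items():
            mod.load_state_dict(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def __iter__(self):
        return iter(self.mods)

    def __getitem__(self, i):
        return self.mods[i]

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self.mods = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self.mods))] = m
        self.mods.append(m)

    def __iter__(self):
        return iter(self.mods)

    def __len__(self):
        return len(self.mods)

    def __getitem__(self, i):
        return self.mods[i]


# ---------------------------------------------------------------------------

def _kaiming(shape, fan_in, rng):
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


_GLOBAL_RNG = np.random.default_rng(0)


def seed_all(seed: int):
    """Reset the global initialization RNG (single source of randomness)."""
    global _GLOBAL_RNG
    _GLOBAL_RNG = np.random.default_rng(seed)


def _rng():
    return _GLOBAL_RNG


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 padding: int | None = None, groups: int = 1, bias: bool = True):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        if in_ch % groups or out_ch % groups:
            raise ValueError("groups must divide both channel counts")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding, self.groups = kernel, stride, padding, groups
        fan_in = in_ch // groups * kernel * kernel
        self.weight = Parameter(_kaiming((out_ch, in_ch // groups, kernel, kernel), fan_in, _rng()))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.weight = Parameter(np.ones(ch))
        self.bias = Parameter(np.zeros(ch))
        self.register_buffer("running_mean", np.zeros(ch))
        self.register_buffer("running_var", np.ones(ch))

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self._set_buffer("running_mean",
                             (1 - m) * self.running_mean + m * mean.data.reshape(-1))
            self._set_buffer("running_var",
                             (1 - m) * self.running_var + m * unbiased)
        else:
            mean = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return (x - mean) / T.sqrt(var + self.eps) * w + b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.dim, self.eps = dim, eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x):
        mean = x.mean(axis=-1, keepdims=True)
        var = ((x - mean) ** 2).mean(axis=-1, keepdims=True)
        return (x - mean) / T.sqrt(var + self.eps) * self.weight + self.bias


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True):
        super().__init__()
        bound = 1.0 / math.sqrt(in_f)
        self.weight = Parameter(_rng().uniform(-bound, bound, size=(in_f, out_f)))
        self.bias = Parameter(_rng().uniform(-bound, bound, size=out_f)) if bias else None
        self.in_f, self.out_f = in_f, out_f

    def forward(self, x):
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class SiLU(Module):
    def forward(self, x):
        return T.silu(x)


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class Identity(Module):
    def forward(self, x):
        return x


class MLP(Module):
    """Stack of Linear layers with ReLU between (DETR-style box head)."""

    def __init__(self, in_f: int, hidden: int, out_f: int, layers: int = 3):
        super().__init__()
        dims = [in_f] + [hidden] * (layers - 1) + [out_f]
        self.layers = ModuleList([Linear(a, b) for a, b in zip(dims[:-1], dims[1:])])

    def forward(self, x):
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = T.relu(x)
        return x


class MultiheadAttention(Module):
    """Standard scaled dot-product attention, batch-first (B, L, D)."""

    def __init__(self, dim: int, heads: int):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must divide by heads")
        self.dim, self.heads = dim, heads
        self.q_proj = Linear(dim, dim)
        self.k_proj = Linear(dim, dim)
        self.v_proj = Linear(dim, dim)
        self.out_proj = Linear(dim, dim)

    def forward(self, query, key, value):
        b, lq, d = query.shape
        lk = key.shape[1]
        h, dh = self.heads, d // self.heads
        q = self.q_proj(query).reshape(b, lq, h, dh).transpose(0, 2, 1, 3)
        k = self.k_proj(key).reshape(b, lk, h, dh).transpose(0, 2, 1, 3)
        v = self.v_proj(value).reshape(b, lk, h, dh).transpose(0, 2, 1, 3)
        attn = T.softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh)), axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, lq, d)
        return self.out_proj(out)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: self-attention + feed-forward."""

    def __init__(self, dim: int, heads: int, ffn_dim: int):
        super().__init__()
        self.attn = MultiheadAttention(dim, heads)
        self.norm1 = LayerNorm(dim)
        self.fc1 = Linear(dim, ffn_dim)
        self.fc2 = Linear(ffn_dim, dim)
        self.norm2 = LayerNorm(dim)

    def forward(self, x, pos=None):
        q = x + pos if pos is not None else x
        x = self.norm1(x + self.attn(q, q, x))
        x = self.norm2(x + self.fc2(T.relu(self.fc1(x))))
        return x
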