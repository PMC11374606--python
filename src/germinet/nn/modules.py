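"""Neural-network layer zoo built on the autodiff tensor core."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import tensor as T
from .tensor import Tensor

_RNG = np.random.default_rng(0)


def manual_seed(seed: int):
    """Seed the global parameter-initialization stream (determinism contract)."""
    global _RNG
    _RNG = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self._modules: dict[str, "Module"] = {}
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def set_child(self, name: str, module: "Module"):
        """Replace a named child module (used by deploy-time fusion)."""
        self._modules[name] = module
        object.__setattr__(self, name, module)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def parameters(self) -> Iterator[Parameter]:
        for m in self.modules():
            yield from m._params.values()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, p in self._params.items():
            yield prefix + k, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for k, b in self._buffers.items():
            yield prefix + k, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def num_params(self) -> int:
        """Total trainable-parameter count."""
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: p.data.copy() for k, p in self.named_parameters()}
        out.update({"buf::" + k: b.copy() for k, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k, p in self.named_parameters():
            p.data[...] = state[k]
        for k, b in self.named_buffers():
            b[...] = state["buf::" + k]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x):
        return x


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = ModuleList(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.mods)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)
        return self

    def set_child(self, name: str, module: Module):
        self._modules[name] = module
        self._list[int(name)] = module

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int | None = None, bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel * kernel
        # He initialization: preserves activation scale through deep SiLU stacks
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(_RNG.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        bound = 1.0 / math.sqrt(fan_in)
        self.bias = Parameter(_RNG.uniform(-bound, bound, out_ch)) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(ch))
        self.bias = Parameter(np.zeros(ch))
        self.momentum, self.eps = momentum, eps
        self.register_buffer("running_mean", np.zeros(ch, dtype=np.float32))
        self.register_buffer("running_var", np.ones(ch, dtype=np.float32))

    def forward(self, x):
        return T.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True):
        super().__init__()
        self.in_f, self.out_f = in_f, out_f
        # Xavier (Glorot) uniform: keeps pre-activation scale through
        # attention/FFN stacks
        bound = math.sqrt(6.0 / (in_f + out_f))
        self.weight = Parameter(_RNG.uniform(-bound, bound, (in_f, out_f)))
        self.bias = Parameter(np.zeros(out_f)) if bias else None

    def forward(self, x):
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(d))
        self.bias = Parameter(np.zeros(d))
        self.eps = eps

    def forward(self, x):
        return T.layer_norm(x, self.weight, self.bias, self.eps)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return T.max_pool2d(x, self.kernel, self.stride, self.padding)


class AvgPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return T.avg_pool2d(x, self.kernel, self.stride, self.padding)


class MLP(Module):
    """Small fully connected stack with SiLU between hidden layers."""

    def __init__(self, in_f: int, hidden: int, out_f: int, n_layers: int = 3):
        super().__init__()
        dims = [in_f] + [hidden] * (n_layers - 1) + [out_f]
        self.layers = ModuleList([Linear(a, b) for a, b in zip(dims[:-1], dims[1:])])

    def forward(self, x):
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.silu()
        return x


class GroupedMultiheadAttention(Module):
    """Multi-head attention whose heads are evaluated in independent groups.

    The heads are partitioned into ``n_groups`` groups; each group attends
    separately and the group outputs are concatenated before the output
    projection.  With shared QKV projections this is numerically identical
    to standard multi-head attention — the grouping expresses how the
    computation is distributed, not a different function.
    """

    def __init__(self, d_model: int, n_heads: int = 8, n_groups: int = 2):
        super().__init__()
        assert d_model % n_heads == 0 and n_heads % n_groups == 0
        self.d_model, self.n_heads, self.n_groups = d_model, n_heads, n_groups
        self.d_head = d_model // n_heads
        self.q_proj = Linear(d_model, d_model)
        self.k_proj = Linear(d_model, d_model)
        self.v_proj = Linear(d_model, d_model)
        # zero-initialized output projection: the block starts as an identity
        # residual and the attention contribution is learned from zero
        self.out_proj = Linear(d_model, d_model)
        self.out_proj.weight.data[...] = 0.0

    def _split(self, t: Tensor, n: int):
        # (B, T, D) -> (B, H, T, dh)
        b, L, _ = t.shape
        return t.reshape(b, L, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _grouped_attend(self, qh: Tensor, kh: Tensor, vh: Tensor) -> Tensor:
        heads_per_group = self.n_heads // self.n_groups
        outs = []
        scale = 1.0 / math.sqrt(self.d_head)
        for g in range(self.n_groups):
            sl = slice(g * heads_per_group, (g + 1) * heads_per_group)
            attn = T.softmax((qh[:, sl] @ kh[:, sl].swapaxes(-1, -2)) * scale, axis=-1)
            outs.append(attn @ vh[:, sl])
        return T.concat(outs, axis=1)  # (B, H, Tq, dh)

    def forward(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        b, lq, _ = q.shape
        qh = self._split(self.q_proj(q), lq)
        kh = self._split(self.k_proj(k), k.shape[1])
        vh = self._split(self.v_proj(v), v.shape[1])
        out = self._grouped_attend(qh, kh, vh)
        out = out.transpose(0, 2, 1, 3).reshape(b, lq, self.d_model)
        return self.out_proj(out)


class GroupedCrossAttention(GroupedMultiheadAttention):
    """Grouped attention against pre-projected keys/values.

    The key/value projections of a large shared memory live outside the
    layer (projected once, reused by every decoder layer); only the query
    and output projections are per-layer.
    """

    def __init__(self, d_model: int, n_heads: int = 8, n_groups: int = 2):
        super().__init__(d_model, n_heads, n_groups)
        del self.k_proj, self.v_proj
        self._modules.pop("k_proj"), self._modules.pop("v_proj")

    def forward(self, q: Tensor, kh: Tensor, vh: Tensor) -> Tensor:
        b, lq, _ = q.shape
        qh = self._split(self.q_proj(q), lq)
        out = self._grouped_attend(qh, kh, vh)
        out = out.transpose(0, 2, 1, 3).reshape(b, lq, self.d_model)
        return self.out_proj(out)
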