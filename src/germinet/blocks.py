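"""Backbone building blocks.

* ``CBS`` — conv + batch norm + SiLU, the elementary unit.
* ``ADown`` — pooling-based downsampling: a 2x2 average pool followed by a
  channel split whose halves go through a stride-2 3x3 CBS and a 3x3
  max-pool + 1x1 CBS respectively, concatenated back together.
* ``RepNCSP`` / ``RepNCSPELAN4`` — the GELAN aggregation block: a CSP-style
  channel split whose second half is pushed through two stacked computation
  blocks, every intermediate concatenated forward (ELAN stacking) before a
  1x1 transition.
* ``Orepa`` — an online re-parameterizable convolution: several linear
  branches (full kxk, 1x1, sequential 1x1->kxk, 1x1 + average pool), each
  behind a per-channel scaling vector, summed and normalized during
  training; ``squeeze()`` folds everything into a single conv for deploy.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor


class ConvBN(nn.Module):
    """Conv2d (no bias) + BatchNorm2d, no activation."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, p: int | None = None):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, s, p if p is not None else k // 2, bias=False)
        self.bn = nn.BatchNorm2d(c2)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x))

    def _fused_wb(self):
        w = self.conv.weight.data.astype(np.float64)
        gamma = self.bn.weight.data.astype(np.float64)
        beta = self.bn.bias.data.astype(np.float64)
        mean = self.bn.running_mean.astype(np.float64)
        var = self.bn.running_var.astype(np.float64)
        scale = gamma / np.sqrt(var + self.bn.eps)
        return w * scale[:, None, None, None], beta - mean * scale

    def fuse(self) -> nn.Module:
        """Fold batch-norm statistics into the conv (deploy form)."""
        w, b = self._fused_wb()
        return FusedConv(w, b, self.conv.stride, self.conv.padding)


class CBS(ConvBN):
    """Conv2d (no bias) + BatchNorm2d + SiLU."""

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).silu()

    def fuse(self) -> nn.Module:
        w, b = self._fused_wb()
        return FusedConvAct(w, b, self.conv.stride, self.conv.padding)


class FusedConv(nn.Module):
    """Single conv + bias, the deploy form of a ConvBN pair."""

    def __init__(self, weight: np.ndarray, bias: np.ndarray, stride: int, padding: int):
        super().__init__()
        self.weight = nn.Parameter(weight)
        self.bias = nn.Parameter(bias)
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class FusedConvAct(FusedConv):
    """Single conv + bias + SiLU, the deploy form of a CBS/Orepa block."""

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, self.stride, self.padding).silu()


class ADown(nn.Module):
    """Average-pool-first downsampling operator (halves H and W).

    ``split`` sets how many of the output channels come from the strided
    3x3 branch (the rest come from the max-pool + 1x1 branch); it defaults
    to an even split.
    """

    def __init__(self, c1: int, c2: int, split: int | None = None):
        super().__init__()
        if c1 % 2:
            raise ValueError(f"ADown input channels must be even, got {c1}")
        self.c1, self.c2 = c1, c2
        s = c2 // 2 if split is None else split
        if not 0 < s < c2:
            raise ValueError("split must leave channels for both branches")
        self.cv1 = CBS(c1 // 2, s, 3, 2)
        self.cv2 = CBS(c1 // 2, c2 - s, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        x = T.avg_pool2d(x, 2, 1, 0)
        x1, x2 = T.chunk(x, 2, axis=1)
        x1 = self.cv1(x1)
        x2 = T.max_pool2d(x2, 3, 2, 1)
        x2 = self.cv2(x2)
        return T.concat([x1, x2], axis=1)


class RepNBottleneck(nn.Module):
    """Two 3x3 CBS convs with a residual shortcut."""

    def __init__(self, c1: int, c2: int):
        super().__init__()
        self.cv1 = CBS(c1, c2, 3, 1)
        self.cv2 = CBS(c2, c2, 3, 1)
        self.add = c1 == c2

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class RepNCSP(nn.Module):
    """CSP sub-block: two 1x1 transitions bracketing ``n`` bottlenecks."""

    def __init__(self, c1: int, c2: int, n: int = 1, e: float = 0.5):
        super().__init__()
        c_ = max(int(c2 * e), 1)
        self.cv1 = CBS(c1, c_, 1, 1)
        self.cv2 = CBS(c1, c_, 1, 1)
        self.cv3 = CBS(2 * c_, c2, 1, 1)
        self.m = nn.Sequential(*[RepNBottleneck(c_, c_) for _ in range(n)])

    def forward(self, x: Tensor) -> Tensor:
        return self.cv3(T.concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class RepNCSPELAN4(nn.Module):
    """GELAN block: CSP split + ELAN stacking + transition.

    The input goes through a 1x1 transition to ``c3`` channels and is split
    in two; the second half is processed by two stacked computation blocks
    (each RepNCSP followed by a 3x3 conv), every stage output concatenated
    forward, and a final 1x1 transition maps to ``c2`` channels.  Spatial
    dims are preserved (stride 1 throughout).

    ``comp1``/``comp2`` override the two trailing 3x3 conv blocks — the
    hook used to swap in re-parameterizable Orepa convs — and may be any
    (c4 -> c4, stride-1) module.
    """

    def __init__(self, c1: int, c2: int, c3: int, c4: int, n: int = 1,
                 comp1: nn.Module | None = None, comp2: nn.Module | None = None):
        super().__init__()
        if c3 % 2:
            raise ValueError("c3 must be even (channel split)")
        self.c3 = c3
        self.cv1 = CBS(c1, c3, 1, 1)
        self.cv2 = nn.Sequential(RepNCSP(c3 // 2, c4, n),
                                 comp1 if comp1 is not None else CBS(c4, c4, 3, 1))
        self.cv3 = nn.Sequential(RepNCSP(c4, c4, n),
                                 comp2 if comp2 is not None else CBS(c4, c4, 3, 1))
        self.cv4 = CBS(c3 + 2 * c4, c2, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        y = list(T.chunk(self.cv1(x), 2, axis=1))
        y.append(self.cv2(y[-1]))
        y.append(self.cv3(y[-1]))
        return self.cv4(T.concat(y, axis=1))


class Orepa(nn.Module):
    """Online re-parameterizable kxk convolution block.

    Training form: four parallel linear branches — the full kxk "origin"
    conv, a 1x1 conv, a sequential 1x1 -> kxk conv pair with ``mid``
    internal channels, and a 1x1 conv followed by a kxk average pool —
    each scaled per output channel, summed, batch-normalized and passed
    through SiLU.  Every branch is a linear map, so the whole pre-norm
    computation collapses exactly into one conv kernel; ``squeeze()``
    performs that collapse (folding the normalization statistics too) and
    swaps the block into its single-conv deploy form.
    """

    def __init__(self, c1: int, c2: int, k: int = 3, s: int = 1, mid: int | None = None):
        super().__init__()
        if k < 1 or k % 2 == 0:
            raise ValueError("kernel must be odd and positive")
        self.c1, self.c2, self.k, self.s = c1, c2, k, s
        self.pad = k // 2
        self.mid = mid if mid is not None else c1
        rng = np.random.default_rng  # init through module RNG below
        from .nn.modules import _RNG

        def u(*shape, fan):
            b = 1.0 / np.sqrt(fan)
            return _RNG.uniform(-b, b, shape)

        self.w_origin = nn.Parameter(u(c2, c1, k, k, fan=c1 * k * k))
        self.w_1x1 = nn.Parameter(u(c2, c1, 1, 1, fan=c1))
        self.w_seq1 = nn.Parameter(u(self.mid, c1, 1, 1, fan=c1))
        self.w_seq2 = nn.Parameter(u(c2, self.mid, k, k, fan=self.mid * k * k))
        self.w_avg = nn.Parameter(u(c2, c1, 1, 1, fan=c1))
        # per-branch, per-output-channel linear scaling vectors
        self.s_origin = nn.Parameter(np.full(c2, 1.0))
        self.s_1x1 = nn.Parameter(np.full(c2, 0.25))
        self.s_seq = nn.Parameter(np.full(c2, 0.25))
        self.s_avg = nn.Parameter(np.full(c2, 0.25))
        self.bn = nn.BatchNorm2d(c2)
        self.squeezed = False

    # -- training form -------------------------------------------------
    def branch_outputs(self, x: Tensor) -> list[Tensor]:
        if self.squeezed:
            raise RuntimeError("block already squeezed; train form unavailable")
        k, s, p = self.k, self.s, self.pad
        o1 = T.conv2d(x, self.w_origin, None, s, p)
        o2 = T.conv2d(x, self.w_1x1, None, s, 0)
        o3 = T.conv2d(T.conv2d(x, self.w_seq1, None, 1, 0), self.w_seq2, None, s, p)
        o4 = T.avg_pool2d(T.conv2d(x, self.w_avg, None, 1, 0), k, s, p)
        return [o1, o2, o3, o4]

    def forward(self, x: Tensor) -> Tensor:
        if self.squeezed:
            return self.deploy(x)
        outs = self.branch_outputs(x)
        scales = [self.s_origin, self.s_1x1, self.s_seq, self.s_avg]
        total = None
        for o, sc in zip(outs, scales):
            scaled = o * sc.reshape(1, -1, 1, 1)
            total = scaled if total is None else total + scaled
        return self.bn(total).silu()

    # -- squeeze -------------------------------------------------------
    def equivalent_kernel(self) -> np.ndarray:
        """Collapse all branches into one (c2, c1, k, k) kernel (float64)."""
        k, c = self.k, self.pad
        w = self.w_origin.data.astype(np.float64) * self.s_origin.data.astype(np.float64)[:, None, None, None]
        w1 = np.zeros_like(w)
        w1[:, :, c, c] = self.w_1x1.data[:, :, 0, 0]
        w += w1 * self.s_1x1.data.astype(np.float64)[:, None, None, None]
        seq = np.einsum("mi,omhw->oihw", self.w_seq1.data[:, :, 0, 0].astype(np.float64),
                        self.w_seq2.data.astype(np.float64))
        w += seq * self.s_seq.data.astype(np.float64)[:, None, None, None]
        avg = np.einsum("oi,hw->oihw", self.w_avg.data[:, :, 0, 0].astype(np.float64),
                        np.full((k, k), 1.0 / (k * k)))
        w += avg * self.s_avg.data.astype(np.float64)[:, None, None, None]
        return w

    def squeeze(self) -> "Orepa":
        """Fold branches + normalization into a single conv (in place)."""
        if self.squeezed:
            warnings.warn("Orepa block already squeezed; no-op")
            return self
        w = self.equivalent_kernel()
        gamma = self.bn.weight.data.astype(np.float64)
        beta = self.bn.bias.data.astype(np.float64)
        mean = self.bn.running_mean.astype(np.float64)
        var = self.bn.running_var.astype(np.float64)
        scale = gamma / np.sqrt(var + self.bn.eps)
        w_f = (w * scale[:, None, None, None]).astype(np.float32)
        b_f = (beta - mean * scale).astype(np.float32)
        # drop branch parameters, keep only the fused conv
        self._params.clear()
        self._modules.clear()
        self.weight = nn.Parameter(w_f)
        self.bias = nn.Parameter(b_f)
        self.squeezed = True
        return self

    def deploy(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, self.s, self.pad).silu()


def squeeze_all(module: nn.Module) -> int:
    """Squeeze every un-squeezed Orepa block under ``module``; returns count."""
    n = 0
    for m in module.modules():
        if isinstance(m, Orepa) and not m.squeezed:
            m.squeeze()
            n += 1
    return n


def orepa_gelan(c1: int, c2: int, c3: int, c4: int, n: int = 1,
                mid1: int | None = None, mid2: int | None = None) -> RepNCSPELAN4:
    """RepNCSPELAN4 whose two trailing 3x3 conv blocks are Orepa blocks."""
    return RepNCSPELAN4(
        c1, c2, c3, c4, n,
        comp1=Orepa(c4, c4, 3, 1, mid=mid1),
        comp2=Orepa(c4, c4, 3, 1, mid=mid2),
    )
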