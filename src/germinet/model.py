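"""Full detector assembly: backbone variants, hybrid encoder, decoder,
post-processing, and the parameter/FLOP accounting.

The detector is an NMS-free set-prediction network: a convolutional
backbone (ResNet-18-style for the baseline; ADown + GELAN stages for the
lightweight variants, optionally with re-parameterizable Orepa convs), a
hybrid encoder (one transformer layer on the deepest P5 map plus
convolutional cross-scale fusion of P3-P5), IoU-free top-K query selection
from encoder tokens, and a small decoder stack with grouped multi-head
attention and iterative box refinement.  Each ablation variant tag
reproduces one row of the architecture-accounting ladder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor
from .blocks import (
    ADown,
    CBS,
    ConvBN,
    Orepa,
    RepNCSP,
    RepNCSPELAN4,
    orepa_gelan,
    squeeze_all,
)

SROOT, LROOT = 0, 1
CLASS_NAMES = ("SROOT", "LROOT")


@dataclass(frozen=True)
class Detection:
    """One predicted box: normalized (cx, cy, w, h), class id, confidence."""

    box: tuple[float, float, float, float]
    class_id: int
    confidence: float


@dataclass
class ModelSpec:
    """Architecture hyperparameters; ``variant`` fixes the layer graph."""

    variant: str = "soilcuc"
    n_classes: int = 2
    image_size: int = 640
    d_model: int = 256
    n_heads: int = 8
    head_groups: int = 2
    enc_layers: int = 1
    enc_ffn: int = 928
    dec_layers: int = 3
    dec_ffn: int = 1817
    n_queries: int = 300
    fusion_depth: int = 1
    # hidden width of the four cross-scale fusion blocks (td4, td3, bu4, bu5)
    fusion_hidden: tuple[int, int, int, int] = (128, 84, 128, 128)
    rng_seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from {sorted(VARIANTS)}"
            )
        if self.image_size % 32:
            raise ValueError("image size must be divisible by 32")


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------


class BasicBlock(nn.Module):
    """Residual block of two 3x3 convs (ResNet-18 style, SiLU activation)."""

    def __init__(self, c1: int, c2: int, stride: int = 1):
        super().__init__()
        self.cbs1 = CBS(c1, c2, 3, stride)
        self.conv2 = ConvBN(c2, c2, 3, 1)
        self.down = ConvBN(c1, c2, 1, stride) if (stride != 1 or c1 != c2) else None

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv2(self.cbs1(x))
        s = self.down(x) if self.down is not None else x
        return (y + s).silu()


class ADownBasicBlock(nn.Module):
    """Stage-entry residual block whose strided 3x3 conv is an ADown operator.

    The pooling downsampler feeds an optional 1x1 fuse conv and the block's
    second 3x3 conv; the identity path keeps the original 1x1 stride-2
    projection.
    """

    def __init__(self, c1: int, c2: int, split: int | None = None, fuse: bool = False):
        super().__init__()
        self.adown = ADown(c1, c2, split)
        self.fuse_conv = CBS(c2, c2, 1, 1) if fuse else None
        self.conv2 = ConvBN(c2, c2, 3, 1)
        self.down = ConvBN(c1, c2, 1, 2)

    def forward(self, x: Tensor) -> Tensor:
        y = self.adown(x)
        if self.fuse_conv is not None:
            y = self.fuse_conv(y)
        y = self.conv2(y)
        return (y + self.down(x)).silu()


class ResNetBackbone(nn.Module):
    """ResNet-18-derived backbone emitting P3/P4/P5 feature maps.

    ``adown_stages`` lists which of the three strided stages (indexed 2..4)
    use the ADown entry block instead of a strided conv.
    """

    out_channels = (128, 256, 512)

    def __init__(self, adown_stages: tuple[int, ...] = (),
                 adown_splits: dict[int, int] | None = None,
                 adown_fuse: tuple[int, ...] = ()):
        super().__init__()
        adown_splits = adown_splits or {}
        self.stem = CBS(3, 64, 7, 2)
        self.stage1 = nn.Sequential(BasicBlock(64, 64), BasicBlock(64, 64))
        chans = [(64, 128), (128, 256), (256, 512)]
        stages = []
        for idx, (c1, c2) in zip((2, 3, 4), chans):
            if idx in adown_stages:
                entry = ADownBasicBlock(c1, c2, adown_splits.get(idx),
                                        fuse=idx in adown_fuse)
            else:
                entry = BasicBlock(c1, c2, stride=2)
            stages.append(nn.Sequential(entry, BasicBlock(c2, c2)))
        self.stage2, self.stage3, self.stage4 = stages

    def forward(self, x: Tensor) -> list[Tensor]:
        x = T.max_pool2d(self.stem(x), 3, 2, 1)
        x = self.stage1(x)
        p3 = self.stage2(x)
        p4 = self.stage3(p3)
        p5 = self.stage4(p4)
        return [p3, p4, p5]


class GelanBackbone(nn.Module):
    """Lightweight backbone: 2-conv stem, then three ADown + GELAN stages.

    ``stage_cfg`` holds one ``(width, c3, c4, n)`` tuple per stage (P3..P5);
    with ``orepa=True`` the two trailing 3x3 convs of every GELAN block are
    Orepa blocks whose sequential-branch widths come from ``orepa_mids``.
    """

    def __init__(self, stem: tuple[int, int], stage_cfg, orepa: bool = False,
                 orepa_mids=None):
        super().__init__()
        s0, s1 = stem
        self.stem1 = CBS(3, s0, 3, 2)
        self.stem2 = CBS(s0, s1, 3, 2)
        self.out_channels = tuple(w for w, _, _, _ in stage_cfg)
        downs, gelans = [], []
        prev = s1
        for i, (w, c3, c4, n) in enumerate(stage_cfg):
            downs.append(ADown(prev, w))
            if orepa:
                mid1, mid2 = orepa_mids[i]
                gelans.append(orepa_gelan(w, w, c3, c4, n, mid1=mid1, mid2=mid2))
            else:
                gelans.append(RepNCSPELAN4(w, w, c3, c4, n))
            prev = w
        self.downs = nn.ModuleList(downs)
        self.gelans = nn.ModuleList(gelans)

    def forward(self, x: Tensor) -> list[Tensor]:
        x = self.stem2(self.stem1(x))
        feats = []
        for down, gelan in zip(self.downs, self.gelans):
            x = gelan(down(x))
            feats.append(x)
        return feats


# ---------------------------------------------------------------------------
# positional encodings
# ---------------------------------------------------------------------------

_POS_CACHE: dict[tuple, np.ndarray] = {}


def sine_pos_2d(h: int, w: int, d: int, temperature: float = 10000.0) -> np.ndarray:
    """2-D sine/cosine positional embedding, shape (h*w, d)."""
    key = (h, w, d)
    if key not in _POS_CACHE:
        gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        quarter = d // 4
        omega = 1.0 / temperature ** (np.arange(quarter) / quarter)
        ex = gx.reshape(-1, 1) * omega
        ey = gy.reshape(-1, 1) * omega
        pos = np.concatenate(
            [np.sin(ex), np.cos(ex), np.sin(ey), np.cos(ey)], axis=1
        ).astype(np.float32)
        _POS_CACHE[key] = pos
    return _POS_CACHE[key]


# ---------------------------------------------------------------------------
# hybrid encoder
# ---------------------------------------------------------------------------


class EncoderLayer(nn.Module):
    def __init__(self, d: int, heads: int, groups: int, ffn: int):
        super().__init__()
        self.attn = nn.GroupedMultiheadAttention(d, heads, groups)
        self.ln1 = nn.LayerNorm(d)
        self.fc1 = nn.Linear(d, ffn)
        self.fc2 = nn.Linear(ffn, d)
        self.ln2 = nn.LayerNorm(d)

    def forward(self, x: Tensor, pos: np.ndarray) -> Tensor:
        qk = x + Tensor(pos)
        x = self.ln1(x + self.attn(qk, qk, x))
        return self.ln2(x + self.fc2(self.fc1(x).silu()))


class HybridEncoder(nn.Module):
    """Single-scale attention on P5 plus convolutional cross-scale fusion."""

    def __init__(self, in_channels, spec: ModelSpec):
        super().__init__()
        d = spec.d_model
        self.d = d
        self.proj = nn.ModuleList([ConvBN(c, d, 1) for c in in_channels])
        self.layers = nn.ModuleList(
            [EncoderLayer(d, spec.n_heads, spec.head_groups, spec.enc_ffn)
             for _ in range(spec.enc_layers)]
        )
        fd = spec.fusion_depth
        h_td4, h_td3, h_bu4, h_bu5 = spec.fusion_hidden
        self.lat5 = CBS(d, d, 1, 1)
        self.fuse_td4 = RepNCSP(2 * d, d, fd, h_td4 / d)
        self.lat4 = CBS(d, d, 1, 1)
        self.fuse_td3 = RepNCSP(2 * d, d, fd, h_td3 / d)
        self.down3 = CBS(d, d, 3, 2)
        self.fuse_bu4 = RepNCSP(2 * d, d, fd, h_bu4 / d)
        self.down4 = CBS(d, d, 3, 2)
        self.fuse_bu5 = RepNCSP(2 * d, d, fd, h_bu5 / d)

    def forward(self, feats: list[Tensor]) -> list[Tensor]:
        p3, p4, p5 = [proj(f) for proj, f in zip(self.proj, feats)]
        # transformer layer on the deepest map
        b, d, h5, w5 = p5.shape
        tokens = p5.reshape(b, d, h5 * w5).swapaxes(1, 2)
        pos = sine_pos_2d(h5, w5, d)
        for layer in self.layers:
            tokens = layer(tokens, pos)
        f5 = tokens.swapaxes(1, 2).reshape(b, d, h5, w5)
        # top-down fusion
        c5 = self.lat5(f5)
        t4 = self.fuse_td4(T.concat([T.upsample_nearest2d(c5, 2), p4], axis=1))
        c4 = self.lat4(t4)
        t3 = self.fuse_td3(T.concat([T.upsample_nearest2d(c4, 2), p3], axis=1))
        # bottom-up fusion
        o3 = t3
        o4 = self.fuse_bu4(T.concat([self.down3(o3), c4], axis=1))
        o5 = self.fuse_bu5(T.concat([self.down4(o4), c5], axis=1))
        return [o3, o4, o5]


# ---------------------------------------------------------------------------
# decoder
# ---------------------------------------------------------------------------


class DecoderLayer(nn.Module):
    def __init__(self, d: int, heads: int, groups: int, ffn: int):
        super().__init__()
        self.self_attn = nn.GroupedMultiheadAttention(d, heads, groups)
        self.ln1 = nn.LayerNorm(d)
        self.cross_attn = nn.GroupedCrossAttention(d, heads, groups)
        self.ln2 = nn.LayerNorm(d)
        self.fc1 = nn.Linear(d, ffn)
        self.fc2 = nn.Linear(ffn, d)
        self.ln3 = nn.LayerNorm(d)

    def forward(self, tgt: Tensor, qpos: Tensor, mem_kh: Tensor, mem_vh: Tensor) -> Tensor:
        # pre-norm residual blocks: the query stream is only ever added to,
        # which preserves per-query identity through the stack
        t = self.ln1(tgt)
        q = t + qpos
        tgt = tgt + self.self_attn(q, q, t)
        t = self.ln2(tgt)
        tgt = tgt + self.cross_attn(t + qpos, mem_kh, mem_vh)
        t = self.ln3(tgt)
        return tgt + self.fc2(self.fc1(t).silu())


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.01, 0.99)
    return np.log(p / (1 - p))


class Decoder(nn.Module):
    """Top-K query selection + grouped-attention decoder with box refinement."""

    def __init__(self, spec: ModelSpec):
        super().__init__()
        d, nc = spec.d_model, spec.n_classes
        self.n_queries = spec.n_queries
        self.n_heads, self.d_head = spec.n_heads, d // spec.n_heads
        self.enc_output = nn.Linear(d, d)
        self.enc_ln = nn.LayerNorm(d)
        self.enc_cls = nn.Linear(d, nc)
        self.enc_box = nn.MLP(d, d, 4, 3)
        self.tgt_proj = nn.Linear(d, d)
        self.query_pos = nn.MLP(4, d, d, 2)
        # memory is layer-normalized, then keys/values are projected once and
        # shared by all decoder layers
        self.mem_ln = nn.LayerNorm(d)
        self.mem_k_proj = nn.Linear(d, d)
        self.mem_v_proj = nn.Linear(d, d)
        self.layers = nn.ModuleList(
            [DecoderLayer(d, spec.n_heads, spec.head_groups, spec.dec_ffn)
             for _ in range(spec.dec_layers)]
        )
        self.cls_head = nn.Linear(d, nc)
        self.box_head = nn.MLP(d, d, 4, 3)
        # boxes start exactly at their anchors; classification starts at a
        # low prior probability (stable focal/varifocal cold start)
        for head in (self.enc_box, self.box_head):
            last = head.layers[-1]
            last.weight.data[...] = 0.0
            last.bias.data[...] = 0.0
        for head in (self.enc_cls, self.cls_head):
            head.bias.data[...] = -4.0

    @staticmethod
    def _anchors(shapes: list[tuple[int, int]]) -> np.ndarray:
        """Per-token (cx, cy, w, h) priors, one grid per feature level."""
        out = []
        for lvl, (h, w) in enumerate(shapes):
            gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
            cx = (gx.reshape(-1) + 0.5) / w
            cy = (gy.reshape(-1) + 0.5) / h
            wh = np.full(h * w, 0.05 * 2**lvl)
            out.append(np.stack([cx, cy, wh, wh], axis=1))
        return np.concatenate(out, axis=0).astype(np.float32)

    def forward(self, memory: Tensor, pos: np.ndarray, shapes) -> dict:
        b, L, d = memory.shape
        enc = self.enc_ln(self.enc_output(memory))
        enc_logits = self.enc_cls(enc)
        anchor_logit = _logit(self._anchors(shapes))
        enc_box_logit = self.enc_box(enc) + Tensor(anchor_logit)

        # top-K tokens by best class score (stable order for determinism)
        with T.no_grad():
            scores = enc_logits.data.max(axis=-1)
        k = min(self.n_queries, L)
        order = np.argsort(-scores, axis=1, kind="stable")[:, :k]
        bidx = np.arange(b)[:, None]
        sel = (bidx, order)

        tgt = self.tgt_proj(enc[sel])
        ref_logit = enc_box_logit.data[sel].copy()  # refinement anchor, detached
        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(b, L, self.n_heads, self.d_head).transpose(0, 2, 1, 3)
        mem_n = self.mem_ln(memory)
        mem_kh = split_heads(self.mem_k_proj(mem_n + Tensor(pos)))
        mem_vh = split_heads(self.mem_v_proj(mem_n))
        aux = [(enc_logits[sel], enc_box_logit[sel].sigmoid())]
        out_logits = out_boxes = None
        for layer in self.layers:
            ref_box = 1.0 / (1.0 + np.exp(-ref_logit))
            qpos = self.query_pos(Tensor(ref_box))
            tgt = layer(tgt, qpos, mem_kh, mem_vh)
            delta = self.box_head(tgt)
            box_logit = delta + Tensor(ref_logit)
            out_logits = self.cls_head(tgt)
            out_boxes = box_logit.sigmoid()
            aux.append((out_logits, out_boxes))
            ref_logit = box_logit.data.copy()
        return {"logits": out_logits, "boxes": out_boxes, "aux": aux}


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

# Channel plans for the lightweight stages; the Orepa sequential-branch
# widths set the train-form capacity of the re-parameterizable convs.
_GELAN_STEM = (32, 64)
_GELAN_STAGES = [
    # (width, c3, c4, n)
    (96, 48, 24, 1),
    (160, 80, 40, 1),
    (288, 144, 72, 1),
]
_OREPA_MIDS = [(24, 24), (627, 627), (3088, 3088)]

VARIANTS: dict[str, dict] = {
    "baseline_r18": {"backbone": "resnet"},
    "adown": {
        "backbone": "resnet",
        "adown_stages": (2, 3, 4),
        "adown_fuse": (3, 4),
        "adown_splits": {4: 460},
    },
    "adown_gelan": {"backbone": "gelan", "orepa": False},
    "adown_gelan_orepa": {"backbone": "gelan", "orepa": True},
    "soilcuc": {"backbone": "gelan", "orepa": True, "use_nwd": True},
}


class DetectionModel(nn.Module):
    """End-to-end detector (set prediction, no NMS)."""

    def __init__(self, spec: ModelSpec):
        super().__init__()
        self.spec = spec
        self.deployed = False
        cfg = VARIANTS[spec.variant]
        nn.manual_seed(spec.rng_seed)
        if cfg["backbone"] == "resnet":
            self.backbone = ResNetBackbone(
                adown_stages=cfg.get("adown_stages", ()),
                adown_splits=cfg.get("adown_splits"),
                adown_fuse=cfg.get("adown_fuse", ()),
            )
        else:
            self.backbone = GelanBackbone(
                _GELAN_STEM, _GELAN_STAGES,
                orepa=cfg.get("orepa", False),
                orepa_mids=_OREPA_MIDS,
            )
        self.encoder = HybridEncoder(self.backbone.out_channels, spec)
        self.decoder = Decoder(spec)

    # -- forward -------------------------------------------------------
    def forward(self, images) -> dict:
        """``images``: float array/Tensor (N, 3, H, W) in [0, 1], H, W % 32 == 0."""
        x = T.as_tensor(images)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.shape}")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("spatial dims must be divisible by 32")
        feats = self.backbone(x)
        o3, o4, o5 = self.encoder(feats)
        d = self.encoder.d
        shapes = [(f.shape[2], f.shape[3]) for f in (o3, o4, o5)]
        tokens = [f.reshape(f.shape[0], d, -1).swapaxes(1, 2) for f in (o3, o4, o5)]
        memory = T.concat(tokens, axis=1)
        pos = np.concatenate([sine_pos_2d(h, w, d) for h, w in shapes], axis=0)
        return self.decoder(memory, pos, shapes)


def build_model(spec: ModelSpec | str, **overrides) -> DetectionModel:
    """Build a detector from a spec or a variant tag."""
    if isinstance(spec, str):
        spec = ModelSpec(variant=spec, **overrides)
    elif overrides:
        spec = replace(spec, **overrides)
    return DetectionModel(spec)


# ---------------------------------------------------------------------------
# post-processing and accounting
# ---------------------------------------------------------------------------


def postprocess(outputs: dict, score_threshold: float = 0.5) -> list[list[Detection]]:
    """Per-query argmax class + sigmoid score; keep score >= threshold.

    No non-maximum suppression is applied: the decoder emits a set."""
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError("score threshold must lie in [0, 1]")
    logits = outputs["logits"].data
    boxes = outputs["boxes"].data
    results = []
    for li, bi in zip(logits, boxes):
        scores = 1.0 / (1.0 + np.exp(-li))
        cls = scores.argmax(axis=-1)
        conf = scores.max(axis=-1)
        keep = conf >= score_threshold
        dets = [
            Detection(tuple(np.clip(box, 0.0, 1.0).tolist()), int(c), float(s))
            for box, c, s in zip(bi[keep], cls[keep], conf[keep])
        ]
        dets.sort(key=lambda det: -det.confidence)
        results.append(dets)
    return results


def count_params(model: nn.Module, millions: bool = False) -> float:
    """Trainable-parameter total (train-form unless the model was deployed)."""
    n = model.num_params()
    return round(n / 1e6, 1) if millions else n


def count_flops(model: DetectionModel, input_size: int | None = None,
                giga: bool = False) -> float:
    """Layer-wise FLOP total for one image at ``input_size``.

    Convs are charged 2*H*W*(Cin*K^2+1)*Cout at their output resolution;
    attention and linear layers 2x their multiply-accumulates; pooling,
    normalization and activations are free.
    """
    size = input_size or model.spec.image_size
    x = np.zeros((1, 3, size, size), dtype=np.float32)
    was_training = model.training
    model.eval()
    with T.no_grad(), T.flop_tally() as tally:
        model(x)
    model.train(was_training)
    total = float(tally["conv"] + tally["matmul"])
    return round(total / 1e9, 1) if giga else total


def reparameterize_model(model: DetectionModel) -> DetectionModel:
    """Squeeze every Orepa block and fold conv+norm pairs (deploy form)."""
    if model.deployed:
        warnings.warn("model already re-parameterized; no-op")
        return model
    squeeze_all(model)
    for m in model.modules():
        for name, child in list(m._modules.items()):
            if isinstance(child, ConvBN):
                m.set_child(name, child.fuse())
    model.deployed = True
    return model
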