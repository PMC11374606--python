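"""Synthetic soil seed-dish scene generator.

Emulates the acquisition setting the detector targets: a dark
substrate-soil background with band-limited texture, a rows x cols grid of
elliptical cucumber seeds (49 per dish by default), thin curved radicles
for the germinated fraction — optionally partially buried under soil —
and distractors (bright stones with seed-like color, thin fibers with
radicle-like color).  Every scene carries full per-seed ground truth, and
annotations are derived from it: one box per germinated seed covering the
seed body plus the *visible* part of the radicle, with the class decided
by the true root length against the seed length (short root = SROOT, long
root = LROOT), exactly as an annotator who watched the dish would label.

Generation is deterministic: the same :class:`SceneParams` (including
``rng_seed``) produce a bit-identical image and identical annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .data_io import Annotation, DatasetConfig, split_dataset, write_annotations

SROOT, LROOT = 0, 1


def label_root_class(root_length: float, seed_length: float) -> int:
    """Root shorter than the seed body -> SROOT, longer -> LROOT.

    Ties break toward SROOT (the rule is stated only for strict
    shorter/longer)."""
    if root_length <= 0 or seed_length <= 0:
        raise ValueError("lengths must be positive")
    return SROOT if root_length <= seed_length else LROOT


@dataclass
class SceneParams:
    """Knobs of the synthetic dish scene (lengths in pixels)."""

    image_size: tuple[int, int] = (640, 640)      # (height, width)
    grid: tuple[int, int] = (7, 7)                # rows x cols
    germination_fraction: float = 0.6
    root_length_ratio_range: tuple[float, float] = (0.3, 2.2)
    seed_length_range: tuple[float, float] = (26.0, 40.0)
    n_stones: int = 8
    n_fibers: int = 6
    burial_probability: float = 0.2
    jitter: float = 6.0
    box_extent: str = "seed_plus_root"            # or "root_only"
    rng_seed: int = 0

    def __post_init__(self):
        if isinstance(self.image_size, int):
            self.image_size = (self.image_size, self.image_size)
        for p in (self.germination_fraction, self.burial_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        h, w = self.image_size
        rows, cols = self.grid
        max_seed = self.seed_length_range[1]
        cell = min(h / rows, w / cols)
        if cell < max_seed * 0.9 + 2 * self.jitter:
            raise ValueError(
                f"grid {rows}x{cols} too dense for image {h}x{w}: "
                f"cell {cell:.0f}px < seed {max_seed:.0f}px + jitter"
            )


@dataclass
class SeedTruth:
    """Ground truth for one seed position."""

    center: tuple[float, float]       # (x, y) pixels
    seed_length: float
    angle: float
    germinated: bool
    root_length: float                # true length, buried or not (0 if dormant)
    buried: bool
    visible_root_length: float


@dataclass
class SeedScene:
    image: np.ndarray                 # (H, W, 3) uint8
    seeds: list[SeedTruth]
    annotations: list[Annotation]
    params: SceneParams


# ---------------------------------------------------------------------------
# painting primitives (float canvas, [0, 255])
# ---------------------------------------------------------------------------


def _paint_ellipse(canvas, cx, cy, a, b, angle, color, rng=None, mottle=0.0):
    h, w, _ = canvas.shape
    r = int(max(a, b)) + 2
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xs - cx) * ca + (ys - cy) * sa
    v = -(xs - cx) * sa + (ys - cy) * ca
    d2 = (u / a) ** 2 + (v / b) ** 2
    mask = d2 <= 1.0
    shade = np.clip(1.0 - 0.25 * d2, 0.6, 1.0)
    col = np.asarray(color, dtype=np.float32)
    patch = canvas[y0:y1, x0:x1]
    tint = col[None, None, :] * shade[..., None]
    if mottle and rng is not None:
        tint = tint + rng.normal(0, mottle, tint.shape)
    patch[mask] = tint[mask]


def _curve_points(p0, direction, length, bend, n=None):
    """Quadratic bezier polyline of given arc length from p0."""
    n = n or max(int(length * 2), 8)
    d = np.asarray(direction) / (np.linalg.norm(direction) + 1e-9)
    normal = np.array([-d[1], d[0]])
    p2 = np.asarray(p0) + d * length
    p1 = np.asarray(p0) + d * length * 0.5 + normal * bend * length
    t = np.linspace(0, 1, n)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    # re-scale to the requested arc length
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
    if seg > 0:
        pts = np.asarray(p0) + (pts - np.asarray(p0)) * (length / seg)
    return pts


def _paint_curve(canvas, pts, thickness, color, alpha=None, soil=None):
    """Paint a polyline with round brush; ``alpha``<1 blends toward ``soil``."""
    h, w, _ = canvas.shape
    col = np.asarray(color, dtype=np.float32)
    r = max(int(round(thickness)), 1)
    for i, (x, y) in enumerate(pts):
        xi, yi = int(round(x)), int(round(y))
        if not (0 <= xi < w and 0 <= yi < h):
            continue
        x0, x1 = max(xi - r, 0), min(xi + r + 1, w)
        y0, y1 = max(yi - r, 0), min(yi + r + 1, h)
        ys, xs = np.mgrid[y0:y1, x0:x1]
        mask = (xs - x) ** 2 + (ys - y) ** 2 <= thickness**2
        patch = canvas[y0:y1, x0:x1]
        a = 1.0 if alpha is None else (alpha[i] if np.ndim(alpha) else alpha)
        base = patch[mask] if soil is None else soil
        patch[mask] = (1 - a) * base + a * col


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def generate_scene(params: SceneParams,
                   germinated_mask: list[bool] | None = None) -> SeedScene:
    """Render one dish scene with ground truth and derived annotations.

    ``germinated_mask`` (row-major, one flag per grid cell) overrides the
    random germination draw while leaving every other random choice —
    layout, seed geometry, root geometry, colors — untouched, so scenes
    that differ only in the mask depict the same dish at different
    stages."""
    rng = np.random.default_rng(params.rng_seed)
    h, w = params.image_size
    rows, cols = params.grid

    # soil: low-luminance brown base + band-limited correlated noise
    base = np.array([52.0, 40.0, 30.0])
    canvas = np.tile(base, (h, w, 1)).astype(np.float32)
    coarse = gaussian_filter(rng.normal(0, 1, (h, w)), 6.0)
    coarse = coarse / (np.abs(coarse).max() + 1e-9)
    fine = rng.normal(0, 1, (h, w, 3)) * 4.0
    canvas += coarse[..., None] * np.array([18.0, 14.0, 10.0]) + fine

    # distractors: bright stones (seed-like color), thin fibers (radicle-like)
    for _ in range(params.n_stones):
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        a = rng.uniform(4, 11)
        b = a * rng.uniform(0.6, 1.0)
        color = np.array([205, 190, 160]) + rng.normal(0, 12, 3)
        _paint_ellipse(canvas, cx, cy, a, b, rng.uniform(0, np.pi), color,
                       rng=rng, mottle=6.0)
    for _ in range(params.n_fibers):
        p0 = np.array([rng.uniform(0, w), rng.uniform(0, h)])
        ang = rng.uniform(0, 2 * np.pi)
        pts = _curve_points(p0, (np.cos(ang), np.sin(ang)),
                            rng.uniform(20, 70), rng.uniform(-0.25, 0.25))
        color = np.array([215, 208, 190]) + rng.normal(0, 10, 3)
        _paint_curve(canvas, pts, rng.uniform(0.8, 1.4), color)

    # seeds on the jittered grid
    cell_h, cell_w = h / rows, w / cols
    seeds: list[SeedTruth] = []
    annotations: list[Annotation] = []
    for r_i in range(rows):
        for c_i in range(cols):
            cell_idx = r_i * cols + c_i
            # draw the whole per-seed parameter block unconditionally so the
            # random stream (and hence the dish) is identical whatever the
            # germination outcome
            cx = (c_i + 0.5) * cell_w + rng.uniform(-params.jitter, params.jitter)
            cy = (r_i + 0.5) * cell_h + rng.uniform(-params.jitter, params.jitter)
            seed_len = rng.uniform(*params.seed_length_range)
            angle = rng.uniform(0, np.pi)
            germ_draw = rng.uniform() < params.germination_fraction
            ratio = rng.uniform(*params.root_length_ratio_range)
            tip_sign = 1 if rng.uniform() < 0.5 else -1
            dir_noise = rng.normal(0, 0.25, 2)
            bend = rng.uniform(-0.3, 0.3)
            burial_draw = rng.uniform() < params.burial_probability
            t0 = rng.uniform(0.2, 0.6)
            t1 = min(1.0, t0 + rng.uniform(0.2, 0.5))
            root_color = np.array([236, 231, 218]) + rng.normal(0, 6, 3)
            color = np.array([228, 212, 175]) + rng.normal(0, 8, 3)
            germinated = (germ_draw if germinated_mask is None
                          else bool(germinated_mask[cell_idx]))

            a, b = seed_len / 2, seed_len * 0.45 / 2
            _paint_ellipse(canvas, cx, cy, a, b, angle, color, rng=rng, mottle=5.0)
            xs_ext = [cx - 1, cx + 1]
            ys_ext = [cy - 1, cy + 1]
            # seed body extent (ellipse bbox)
            ca, sa = np.cos(angle), np.sin(angle)
            ex = np.hypot(a * ca, b * sa)
            ey = np.hypot(a * sa, b * ca)
            seed_ext = (cx - ex, cy - ey, cx + ex, cy + ey)

            root_len = 0.0
            buried = False
            visible_len = 0.0
            if germinated:
                root_len = ratio * seed_len
                tip = np.array([cx + tip_sign * a * ca, cy + tip_sign * a * sa])
                direction = np.array([tip_sign * ca, tip_sign * sa]) + dir_noise
                pts = _curve_points(tip, direction, root_len, bend)
                buried = burial_draw
                n = len(pts)
                visible = np.ones(n, dtype=bool)
                if buried:
                    visible[int(t0 * n):int(t1 * n)] = False
                alpha = np.where(visible, 1.0, 0.12)
                _paint_curve(canvas, pts, 1.5, root_color, alpha=alpha)
                vis_pts = pts[visible]
                inb = (vis_pts[:, 0] >= 0) & (vis_pts[:, 0] < w) \
                    & (vis_pts[:, 1] >= 0) & (vis_pts[:, 1] < h)
                vis_pts = vis_pts[inb]
                seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
                visible_len = float(seg[visible[:-1]].sum())
                if len(vis_pts):
                    xs_ext += [vis_pts[:, 0].min() - 2, vis_pts[:, 0].max() + 2]
                    ys_ext += [vis_pts[:, 1].min() - 2, vis_pts[:, 1].max() + 2]
                if params.box_extent == "seed_plus_root":
                    xs_ext += [seed_ext[0], seed_ext[2]]
                    ys_ext += [seed_ext[1], seed_ext[3]]
                x1 = float(np.clip(min(xs_ext), 0, w - 1))
                x2 = float(np.clip(max(xs_ext), 0, w - 1))
                y1 = float(np.clip(min(ys_ext), 0, h - 1))
                y2 = float(np.clip(max(ys_ext), 0, h - 1))
                cls = label_root_class(root_len, seed_len)
                annotations.append(Annotation(
                    ((x1 + x2) / 2 / w, (y1 + y2) / 2 / h,
                     max(x2 - x1, 2.0) / w, max(y2 - y1, 2.0) / h),
                    cls,
                ))
            seeds.append(SeedTruth((float(cx), float(cy)), float(seed_len),
                                   float(angle), bool(germinated),
                                   float(root_len), bool(buried),
                                   visible_len))

    image = np.clip(canvas, 0, 255).astype(np.uint8)
    return SeedScene(image, seeds, annotations, params)


def scene_detections(scene: SeedScene, confidence: float = 1.0):
    """Perfect detections replayed from ground truth (oracle harness)."""
    from .model import Detection

    return [Detection(a.box, a.class_id, confidence) for a in scene.annotations]


def generate_dataset(n_images: int, params: SceneParams, out_dir,
                     ratios=(0.7, 0.2, 0.1), image_format: str = "png") -> dict:
    """Write a split dataset (images + YOLO-txt labels + YAML config).

    Per-image child seeds are drawn from ``params.rng_seed`` and recorded
    in ``manifest.json`` so any image can be regenerated exactly.
    """
    from PIL import Image

    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out = Path(out_dir)
    rng = np.random.default_rng(params.rng_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_images)
    names = [f"scene_{i:05d}" for i in range(n_images)]
    splits = split_dataset(list(range(n_images)), ratios, rng_seed=params.rng_seed)
    split_of = {}
    for split_name, idxs in zip(("train", "test", "val"), splits):
        for i in idxs:
            split_of[i] = split_name
    records = []
    for i, (name, seed) in enumerate(zip(names, seeds)):
        split = split_of[i]
        img_dir = out / "images" / split
        lbl_dir = out / "labels" / split
        img_dir.mkdir(parents=True, exist_ok=True)
        lbl_dir.mkdir(parents=True, exist_ok=True)
        scene = generate_scene(replace(params, rng_seed=int(seed)))
        Image.fromarray(scene.image).save(img_dir / f"{name}.{image_format}")
        write_annotations(scene.annotations, lbl_dir / f"{name}.txt", "yolo_txt")
        records.append({"name": name, "split": split, "rng_seed": int(seed)})
    cfg = DatasetConfig(train="images/train", test="images/test", val="images/val",
                        ratios=ratios)
    cfg.to_yaml(out / "dataset.yaml")
    manifest = {"params": asdict(params), "n_images": n_images, "images": records}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
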