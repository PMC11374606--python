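"""Training loop binding augmentation, model, and objective.

Full-scale runs follow the canonical hyperparameters (100 epochs, batch 4,
640x640 input, box-loss gain 0.5, no pretrained weights); ``smoke``
configurations run the same code path on a tiny synthetic set at reduced
resolution so the whole loop executes on a desktop CPU in minutes.
Training is deterministic given the seed (single-process loading;
``workers`` is accepted for config compatibility but loading is always
in-process).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from . import augment as A
from . import evaluation as E
from . import scenegen as S
from .nn import AdamW
from .nn import tensor as T
from .model import DetectionModel, ModelSpec, build_model, postprocess
from .objective import NWDParams, total_loss


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 4
    image_size: int = 640
    box_gain: float = 0.5          # gain of the (NWD+GIoU) box loss term
    workers: int = 4
    cache: bool = False
    lr: float = 1e-4
    weight_decay: float = 1e-4
    clip_norm: float = 0.1
    rng_seed: int = 0
    smoke: bool = False

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be positive")
        if self.image_size % 32:
            raise ValueError("image size must be divisible by 32")


def smoke_setup(n_train: int = 50, n_val: int = 10, rng_seed: int = 0):
    """Desk-scale smoke setting: easy low-resolution synthetic scenes.

    3x3 grids of large, fully germinated, unburied short-root seeds at
    160x160 — deliberately easy (single class present, compact uniform
    boxes) so a few epochs of CPU training demonstrate learning."""
    scene = S.SceneParams(
        image_size=(160, 160), grid=(3, 3), germination_fraction=1.0,
        root_length_ratio_range=(0.4, 0.95), seed_length_range=(26.0, 34.0),
        n_stones=2, n_fibers=1, burial_probability=0.0, jitter=2.0,
        rng_seed=rng_seed,
    )
    cfg = TrainConfig(epochs=3, batch_size=1, image_size=160, lr=7e-4,
                      rng_seed=rng_seed, smoke=True)
    spec = ModelSpec(variant="soilcuc", image_size=160, n_queries=60,
                     rng_seed=rng_seed)
    rng = np.random.default_rng(rng_seed)
    def scenes(n, offset):
        out = []
        for i in range(n):
            sc = S.generate_scene(replace(scene, rng_seed=int(rng.integers(2**31 - 1))))
            out.append((sc.image, sc.annotations))
        return out
    return cfg, spec, scenes(n_train, 0), scenes(n_val, n_train)


def _to_batch(images: list[np.ndarray]) -> np.ndarray:
    x = np.stack(images).astype(np.float32) / 255.0
    return x.transpose(0, 3, 1, 2)


def _targets(annots) -> dict:
    boxes = np.array([a.box for a in annots], dtype=np.float32).reshape(-1, 4)
    labels = np.array([a.class_id for a in annots], dtype=int)
    return {"boxes": boxes, "labels": labels}


def _clip_grads(params, max_norm: float):
    total = 0.0
    grads = [p.grad for p in params if p.grad is not None]
    for g in grads:
        total += float((g * g).sum())
    norm = total**0.5
    if norm > max_norm:
        scale = max_norm / (norm + 1e-9)
        for g in grads:
            g *= scale
    return norm


def train(cfg: TrainConfig, dataset: list, model_spec: ModelSpec,
          val_dataset: list | None = None,
          augment_cfg: A.AugmentConfig | None = None,
          loss_params: NWDParams | None = None,
          out_dir=None):
    """From-scratch training on ``dataset`` = [(uint8 image, [Annotation])].

    Returns (model, log): ``log`` is a list of per-epoch dicts with loss
    components (and val mAP when a validation set is given).  Aborts with a
    diagnostic if the loss stops being finite.
    """
    model = build_model(model_spec)
    params = loss_params or NWDParams(lambda_box=cfg.box_gain)
    pipeline = A.build_pipeline(augment_cfg) if augment_cfg else None
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.rng_seed)
    log = []
    run_cfg = {"config": asdict(cfg), "loss": {"C": params.C, "mix_ratio": params.mix_ratio,
               "box_gain": params.lambda_box}, "variant": model_spec.variant}
    for epoch in range(1, cfg.epochs + 1):
        model.train()
        order = rng.permutation(len(dataset))
        sums: dict[str, float] = {}
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            images, targets = [], []
            for i in idx:
                img, annots = dataset[i]
                if pipeline is not None:
                    img = pipeline(img, rng=rng)
                images.append(img)
                targets.append(_targets(annots))
            out = model(_to_batch(images))
            loss, parts = total_loss(out, targets, params)
            if not np.isfinite(parts["total"]):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={parts['total']}"
                )
            opt.zero_grad()
            loss.backward()
            _clip_grads(opt.params, cfg.clip_norm)
            opt.step()
            for k, v in parts.items():
                sums[k] = sums.get(k, 0.0) + v
            n_batches += 1
        entry = {"epoch": epoch, **{k: v / n_batches for k, v in sums.items()}}
        if val_dataset is not None:
            entry["map50"] = validate(model, val_dataset).map50
        log.append(entry)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, out / "checkpoint.npz", cfg)
        (out / "run.json").write_text(json.dumps({"run": run_cfg, "log": log}, indent=1))
        import csv
        with open(out / "metrics.csv", "w", newline="") as f:
            writer = csv.DictWriter(f, fieldnames=sorted({k for e in log for k in e}))
            writer.writeheader()
            writer.writerows(log)
    return model, log


def validate(model: DetectionModel, dataset: list,
             score_threshold: float = 0.01, max_dets: int = 100) -> E.EvalResult:
    """Forward + postprocess + evaluation on a [(image, annotations)] split."""
    if not dataset:
        raise ValueError("empty validation split")
    model.eval()
    dets_all, gts_all = [], []
    with T.no_grad():
        for img, annots in dataset:
            out = model(_to_batch([img]))
            dets = postprocess(out, score_threshold)[0][:max_dets]
            dets_all.append(dets)
            gts_all.append([(a.box, a.class_id) for a in annots])
    return E.evaluate(dets_all, gts_all)


def load_split(data_dir, split: str) -> list:
    """Load one split of a generated dataset as [(image, annotations)]."""
    from PIL import Image
    from .data_io import read_annotations

    root = Path(data_dir)
    img_dir = root / "images" / split
    lbl_dir = root / "labels" / split
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no such split directory: {img_dir}")
    out = []
    for img_path in sorted(img_dir.iterdir()):
        lbl = lbl_dir / (img_path.stem + ".txt")
        annots = read_annotations(lbl) if lbl.exists() else []
        out.append((np.asarray(Image.open(img_path).convert("RGB")), annots))
    return out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: DetectionModel, path, cfg: TrainConfig | None = None):
    state = model.state_dict()
    meta = {
        "spec": asdict(model.spec),
        "deployed": model.deployed,
        "config": asdict(cfg) if cfg else None,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> tuple[DetectionModel, dict]:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(bytes(data["__meta__"]).decode())
    spec_d = meta["spec"]
    spec_d["fusion_hidden"] = tuple(spec_d["fusion_hidden"])
    spec = ModelSpec(**spec_d)
    model = DetectionModel(spec)
    if meta["deployed"]:
        from .model import reparameterize_model
        reparameterize_model(model)
        # deployed checkpoints restore into the deployed graph
    state = {k: data[k] for k in data.files if k != "__meta__"}
    model.load_state_dict(state)
    return model, meta
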