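"""Annotation and dataset I/O.

Two on-disk label formats are supported: YOLO-txt (one ``class cx cy w h``
line per box, normalized to [0, 1]) and LabelImg-style Pascal-VOC XML
(pixel ``xmin/ymin/xmax/ymax``).  In memory everything is a normalized
center-form :class:`Annotation`; pixel corner coordinates appear only at
the file boundary.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import yaml

CLASS_NAMES = ("SROOT", "LROOT")


@dataclass(frozen=True)
class Annotation:
    """Normalized (cx, cy, w, h) box plus class id (0=SROOT, 1=LROOT)."""

    box: tuple[float, float, float, float]
    class_id: int

    def __post_init__(self):
        cx, cy, w, h = self.box
        if not (0.0 <= cx <= 1.0 and 0.0 <= cy <= 1.0):
            raise ValueError(f"box center out of range: {self.box}")
        if not (0.0 < w <= 1.0 and 0.0 < h <= 1.0):
            raise ValueError(f"box size out of range: {self.box}")
        if self.class_id not in (0, 1):
            raise ValueError(f"class_id must be 0 or 1, got {self.class_id}")

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.class_id]


def to_pixel_xyxy(box, width: int, height: int) -> tuple[float, float, float, float]:
    """Normalized center box -> continuous pixel corners (half-open)."""
    cx, cy, w, h = box
    return ((cx - w / 2) * width, (cy - h / 2) * height,
            (cx + w / 2) * width, (cy + h / 2) * height)


def from_pixel_xyxy(xyxy, width: int, height: int) -> tuple[float, float, float, float]:
    x1, y1, x2, y2 = xyxy
    return ((x1 + x2) / 2 / width, (y1 + y2) / 2 / height,
            (x2 - x1) / width, (y2 - y1) / height)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_annotations(path, fmt: str = "yolo_txt",
                     image_size: tuple[int, int] | None = None) -> list[Annotation]:
    """Read a label file; returns normalized annotations regardless of format.

    ``image_size`` (width, height) is required for VOC files lacking a
    ``<size>`` element.
    """
    path = Path(path)
    if fmt == "yolo_txt":
        out = []
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 5:
                raise ValueError(f"{path}:{ln}: expected 5 fields, got {len(fields)}")
            try:
                cls = int(fields[0])
                cx, cy, w, h = (float(v) for v in fields[1:])
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: malformed line: {line!r}") from e
            out.append(Annotation((cx, cy, w, h), cls))
        return out
    if fmt == "voc_xml":
        root = ET.parse(path).getroot()
        size = root.find("size")
        if size is not None:
            width = int(size.findtext("width"))
            height = int(size.findtext("height"))
        elif image_size is not None:
            width, height = image_size
        else:
            raise ValueError(f"{path}: no <size> element and no image_size given")
        out = []
        for obj in root.iter("object"):
            name = obj.findtext("name")
            if name not in CLASS_NAMES:
                raise ValueError(f"{path}: unknown class {name!r}")
            bb = obj.find("bndbox")
            if bb is None:
                raise ValueError(f"{path}: object without bndbox")
            xyxy = tuple(float(bb.findtext(k)) for k in ("xmin", "ymin", "xmax", "ymax"))
            out.append(Annotation(from_pixel_xyxy(xyxy, width, height),
                                  CLASS_NAMES.index(name)))
        return out
    raise ValueError(f"unknown format {fmt!r}")


def write_annotations(annots, path, fmt: str = "yolo_txt",
                      image_size: tuple[int, int] = (640, 640)) -> None:
    """Write annotations; round-trips with :func:`read_annotations` to 1e-6."""
    path = Path(path)
    annots = [a if isinstance(a, Annotation) else Annotation(*a) for a in annots]
    if fmt == "yolo_txt":
        lines = [
            f"{a.class_id} {a.box[0]:.6f} {a.box[1]:.6f} {a.box[2]:.6f} {a.box[3]:.6f}"
            for a in annots
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return
    if fmt == "voc_xml":
        width, height = image_size
        root = ET.Element("annotation")
        ET.SubElement(root, "filename").text = path.stem
        size = ET.SubElement(root, "size")
        ET.SubElement(size, "width").text = str(width)
        ET.SubElement(size, "height").text = str(height)
        ET.SubElement(size, "depth").text = "3"
        for a in annots:
            obj = ET.SubElement(root, "object")
            ET.SubElement(obj, "name").text = a.class_name
            bb = ET.SubElement(obj, "bndbox")
            x1, y1, x2, y2 = to_pixel_xyxy(a.box, width, height)
            for k, v in zip(("xmin", "ymin", "xmax", "ymax"), (x1, y1, x2, y2)):
                ET.SubElement(bb, k).text = f"{v:.4f}"
        ET.ElementTree(root).write(path)
        return
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# dataset config and splitting
# ---------------------------------------------------------------------------


@dataclass
class DatasetConfig:
    """Paths of the train/test/val splits plus class names."""

    train: str
    test: str
    val: str
    names: tuple[str, ...] = CLASS_NAMES
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)

    def __post_init__(self):
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")
        total = sum(self.ratios)
        self.ratios = tuple(r / total for r in self.ratios)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "train": self.train, "test": self.test, "val": self.val,
            "names": list(self.names), "ratios": list(self.ratios),
        }, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "DatasetConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(d["train"], d["test"], d["val"],
                   tuple(d.get("names", CLASS_NAMES)),
                   tuple(d.get("ratios", (0.7, 0.2, 0.1))))


def split_dataset(items, ratios=(0.7, 0.2, 0.1), rng_seed: int = 0):
    """Random disjoint train/test/val partition by largest-remainder sizes.

    Deterministic given the seed; sizes are the largest-remainder
    apportionment of the (normalized) ratios, so 1000 items at 7:2:1 give
    exactly 700/200/100.
    """
    import numpy as np

    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    items = list(items)
    n = len(items)
    total = sum(ratios)
    quotas = [n * r / total for r in ratios]
    counts = [int(q) for q in quotas]
    rem = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    perm = np.random.default_rng(rng_seed).permutation(n)
    out, start = [], 0
    for c in counts:
        out.append([items[i] for i in perm[start:start + c]])
        start += c
    return tuple(out)
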