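"""Online (per-batch) photometric training augmentation.

Four deliberately mild transforms, each fired independently with its own
probability on every call: box blur, median blur, CLAHE (contrast-limited
adaptive histogram equalization), and grayscale conversion.  All four are
geometry-preserving, so bounding boxes pass through untouched — geometric
augmentation is intentionally absent because partially buried radicles do
not survive aggressive spatial edits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter, uniform_filter
from skimage.exposure import equalize_adapthist


@dataclass
class AugmentConfig:
    """Firing probabilities and per-transform parameters.

    Only the blur probability is canonical (1%); the other three default
    to the same mild rate and are configurable."""

    p_blur: float = 0.01
    p_medianblur: float = 0.01
    p_clahe: float = 0.01
    p_togray: float = 0.01
    blur_kernel: int = 5          # max box-blur kernel (odd, "relatively mild")
    median_kernel: int = 5
    clahe_clip: float = 4.0       # clip limit on the 8-bit scale
    rng_seed: int = 0

    def __post_init__(self):
        for p in (self.p_blur, self.p_medianblur, self.p_clahe, self.p_togray):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for k in (self.blur_kernel, self.median_kernel):
            if k < 3 or k % 2 == 0:
                raise ValueError(f"kernel must be odd and >= 3, got {k}")


def _check_image(image: np.ndarray) -> np.ndarray:
    if image.dtype != np.uint8 or image.ndim != 3 or image.shape[2] != 3:
        raise TypeError("expected an 8-bit (H, W, 3) RGB image")
    return image


def blur(image: np.ndarray, kernel: int, rng: np.random.Generator) -> np.ndarray:
    k = int(rng.choice(np.arange(3, kernel + 1, 2)))
    return uniform_filter(image.astype(np.float32), size=(k, k, 1)).round().clip(0, 255).astype(np.uint8)


def medianblur(image: np.ndarray, kernel: int, rng: np.random.Generator) -> np.ndarray:
    k = int(rng.choice(np.arange(3, kernel + 1, 2)))
    return median_filter(image, size=(k, k, 1))


def clahe(image: np.ndarray, clip: float, rng: np.random.Generator) -> np.ndarray:
    out = equalize_adapthist(image, clip_limit=clip / 255.0)
    return (out * 255.0).round().clip(0, 255).astype(np.uint8)


def togray(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    lum = (0.299 * image[..., 0] + 0.587 * image[..., 1] + 0.114 * image[..., 2])
    lum = lum.round().clip(0, 255).astype(np.uint8)
    return np.repeat(lum[..., None], 3, axis=2)


class Pipeline:
    """Sequential random-fire pipeline; boxes are returned unchanged."""

    def __init__(self, cfg: AugmentConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.rng_seed)
        self.fired_counts = {"blur": 0, "medianblur": 0, "clahe": 0, "togray": 0}

    def __call__(self, image: np.ndarray, annotations=None,
                 rng: np.random.Generator | None = None):
        """Apply the pipeline once; different rng states give different outputs."""
        image = _check_image(image)
        rng = rng or self.rng
        cfg = self.cfg
        steps = (
            ("blur", cfg.p_blur, lambda im, r: blur(im, cfg.blur_kernel, r)),
            ("medianblur", cfg.p_medianblur, lambda im, r: medianblur(im, cfg.median_kernel, r)),
            ("clahe", cfg.p_clahe, lambda im, r: clahe(im, cfg.clahe_clip, r)),
            ("togray", cfg.p_togray, lambda im, r: togray(im, r)),
        )
        for name, p, fn in steps:
            if rng.uniform() < p:
                image = fn(image, rng)
                self.fired_counts[name] += 1
        return (image, annotations) if annotations is not None else image


def build_pipeline(cfg: AugmentConfig | None = None) -> Pipeline:
    """Build the four-transform pipeline (Blur, MedianBlur, CLAHE, ToGray)."""
    return Pipeline(cfg or AugmentConfig())


def apply(pipeline: Pipeline, image: np.ndarray, annotations=None,
          rng: np.random.Generator | None = None):
    """Functional wrapper around :class:`Pipeline.__call__`."""
    return pipeline(image, annotations, rng=rng)
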