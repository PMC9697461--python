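"""Contrast enhancement and training-set augmentation.

Luminance-adaptation tone mapping comes in two flavours: a single-stage
transform (SLAT) that strongly enhances local detail and brightens dark
regions, and a multi-stage cascade (MLAT) that compresses the global tone of
the image instead.  Both are implemented here as a surround-adaptive gamma:
each pixel is raised to an exponent that shrinks below 1 where the local
Gaussian surround is dark, so dark structure is expanded while bright
structure is left near-identity.  The geometric augmentations (joint random
crop and horizontal flip of image + masks + boxes) mirror what a segmentation
training loop applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize


class EnhanceError(ValueError):
    pass


@dataclass(frozen=True)
class ToneMapConfig:
    surround_sigma: float = 25.0   # px; scale of the adapting surround
    strength: float = 0.7          # 0 = identity; larger = stronger adaptation
    stages: int = 1                # 1 = single-stage, >1 = cascaded

    def __post_init__(self):
        if self.surround_sigma <= 0:
            raise EnhanceError("surround_sigma must be > 0")
        if self.strength < 0:
            raise EnhanceError("strength must be >= 0")
        if self.stages < 1:
            raise EnhanceError("stages must be >= 1")


@dataclass(frozen=True)
class AugmentationConfig:
    crop_fraction: float = 0.8
    flip_prob: float = 0.5
    gamma_values: tuple = (0.75, 1.25)
    lat_variants: tuple = ("slat", "mlat")

    def __post_init__(self):
        if not 0 < self.crop_fraction <= 1:
            raise EnhanceError("crop_fraction must be in (0, 1]")
        if not 0 <= self.flip_prob <= 1:
            raise EnhanceError("flip_prob must be in [0, 1]")
        if any(g <= 0 for g in self.gamma_values):
            raise EnhanceError("gamma values must be > 0")


# ---------------------------------------------------------------------------
# tone mapping

def _lat_stage(img01: np.ndarray, cfg: ToneMapConfig, strength: float) -> np.ndarray:
    """One adaptation pass: tone-map the Gaussian surround with an exponent
    that shrinks where the surround is dark (brightening dark regions,
    leaving bright ones near identity), then add back the center-surround
    detail with a gain that grows in dark regions (local contrast up)."""
    surround = gaussian_filter(img01, cfg.surround_sigma, mode="nearest")
    gamma = np.clip(1.0 - strength * (1.0 - surround), 0.15, 1.0)
    adapted = np.power(np.clip(surround, 0.0, 1.0), gamma)
    detail_gain = 1.0 + strength * (1.0 - surround)
    out = adapted + detail_gain * (img01 - surround)
    return np.clip(out, 0.0, 1.0)


def slat(image: np.ndarray, cfg: ToneMapConfig = ToneMapConfig()) -> np.ndarray:
    """Single-stage luminance adaptation: local detail enhancement."""
    img01 = np.asarray(image, dtype=float) / 255.0
    out = _lat_stage(img01, cfg, cfg.strength)
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)


def mlat(image: np.ndarray, cfg: ToneMapConfig = ToneMapConfig(stages=3)) -> np.ndarray:
    """Multi-stage cascade: global tone compression.

    The per-stage strength is split so ``stages=1`` reduces exactly to
    :func:`slat` on the same config.
    """
    img01 = np.asarray(image, dtype=float) / 255.0
    per_stage = cfg.strength / cfg.stages
    out = img01
    for _ in range(cfg.stages):
        out = _lat_stage(out, cfg, per_stage)
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)


def gamma_correct(image: np.ndarray, gamma: float) -> np.ndarray:
    """Classic per-pixel power law: 255 * (v/255) ** gamma."""
    if gamma <= 0:
        raise EnhanceError("gamma must be > 0")
    v = np.asarray(image, dtype=float) / 255.0
    return np.clip(np.round(255.0 * np.power(v, gamma)), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# geometric augmentation

def augment_random_crop(
    image: np.ndarray, masks: list, fraction: float, rng: np.random.Generator,
) -> tuple:
    """Crop the same random window from image and masks, resize back.

    The window is ``round(fraction*H) x round(fraction*W)`` with a uniformly
    random top-left corner; the result is resized to the original shape
    (bilinear for the image, nearest for masks).
    """
    if not 0 < fraction <= 1:
        raise EnhanceError("fraction must be in (0, 1]")
    h, w = image.shape
    for m in masks:
        if m.shape != image.shape:
            raise EnhanceError("masks must share the image shape")
    ch, cw = int(round(fraction * h)), int(round(fraction * w))
    y0 = int(rng.integers(0, h - ch + 1))
    x0 = int(rng.integers(0, w - cw + 1))
    win = np.s_[y0:y0 + ch, x0:x0 + cw]
    img_c = resize(image[win].astype(float), (h, w), order=1,
                   preserve_range=True, anti_aliasing=False)
    img_out = np.clip(np.round(img_c), 0, 255).astype(np.uint8)
    masks_out = [
        resize(m[win], (h, w), order=0, preserve_range=True,
               anti_aliasing=False).astype(m.dtype)
        for m in masks
    ]
    return img_out, masks_out


def augment_flip(
    image: np.ndarray, masks: list, rng: np.random.Generator,
    flip_prob: float = 0.5,
) -> tuple:
    """Horizontal mirror of image + masks with probability ``flip_prob``."""
    if rng.random() < flip_prob:
        return np.fliplr(image).copy(), [np.fliplr(m).copy() for m in masks]
    return image, list(masks)


def flip_boxes_normalized(boxes: list) -> list:
    """Mirror YOLO-normalized boxes horizontally: cx -> 1 - cx."""
    return [(cid, 1.0 - cx, cy, w, h) for (cid, cx, cy, w, h) in boxes]


# ---------------------------------------------------------------------------
# training-set expansion

def expand_training_set(
    images: list,
    variants=("slat", "mlat"),
    gamma_values=(),
    tone_cfg: ToneMapConfig | None = None,
) -> list:
    """Originals plus one tone-mapped copy per enabled variant.

    360 inputs with SLAT and MLAT enabled yield 1080 images (tripling); each
    gamma exponent adds one further copy per input.
    """
    if not images:
        raise EnhanceError("images must be nonempty")
    unknown = set(variants) - {"slat", "mlat"}
    if unknown:
        raise EnhanceError(f"unknown variants: {sorted(unknown)}")
    cfg = tone_cfg or ToneMapConfig()
    mcfg = ToneMapConfig(surround_sigma=cfg.surround_sigma,
                         strength=cfg.strength, stages=max(cfg.stages, 3))
    out = list(images)
    for v in variants:
        fn = slat if v == "slat" else (lambda im: mlat(im, mcfg))
        out.extend(fn(im) for im in images)
    for g in gamma_values:
        out.extend(gamma_correct(im, g) for im in images)
    return out
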