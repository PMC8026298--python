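"""Preprocessing, augmentation, and random patch sampling.

Two modes mirror the two imaging settings the segmenter targets:

* ``volume`` (CTA-style slices): geometric augmentation only — affine
  scaling, rotation, vertical flips — applied identically to image and mask
  (mask via nearest-neighbour so it stays binary).
* ``fundus`` (retina-style photographs): intensity preprocessing — grayscale
  conversion, per-image standardization, CLAHE, gamma adjustment.

Training crops are square patches whose centers are drawn uniformly over the
full image; windows that would overhang the border are shifted fully inside
(a zero-padding mode is available instead).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import exposure

from .phantoms import VesselSample


@dataclass(frozen=True)
class AugmentationConfig:
    mode: str = "volume"                      # "volume" or "fundus"
    affine_scale_range: tuple = (0.9, 1.1)
    rotation_degrees_range: tuple = (-15.0, 15.0)
    vertical_flip_prob: float = 0.5
    clahe_clip_limit: float | None = 0.05     # None disables CLAHE
    clahe_tile_size: int = 8
    gamma_range: tuple = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("volume", "fundus"):
            raise ValueError("mode must be 'volume' or 'fundus'")
        if not (0.0 <= self.vertical_flip_prob <= 1.0):
            raise ValueError("vertical_flip_prob must lie in [0, 1]")
        if min(self.gamma_range) <= 0:
            raise ValueError("gamma_range must be positive")
        if min(self.affine_scale_range) <= 0:
            raise ValueError("affine_scale_range must be positive")


@dataclass(frozen=True)
class PatchSpec:
    patch_size: int = 128
    n_patches_per_image: int = 10
    border: str = "clamp"                      # "clamp" shifts inside; "pad" zero-pads
    seed: int = 0

    def __post_init__(self):
        if self.patch_size < 1 or self.n_patches_per_image < 1:
            raise ValueError("patch_size and n_patches_per_image must be >= 1")
        if self.border not in ("clamp", "pad"):
            raise ValueError("border must be 'clamp' or 'pad'")


def _affine_pair(image, mask, angle_deg, scale):
    """Rotate+scale image (bilinear) and mask (nearest) about the center."""
    if scale == 1.0 and angle_deg % 90 == 0:
        k = int(angle_deg // 90) % 4
        return np.rot90(image, k).copy(), np.rot90(mask, k).copy()
    h, w = image.shape
    theta = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]]) / scale
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - rot @ center
    img_t = ndimage.affine_transform(image, rot, offset=offset, order=1, mode="nearest")
    mask_t = ndimage.affine_transform(mask.astype(np.uint8), rot, offset=offset,
                                      order=0, mode="constant", cval=0)
    return img_t, mask_t


def augment(sample: VesselSample, config: AugmentationConfig, rng=None) -> VesselSample:
    """Geometric augmentation of an image/mask pair, deterministic under seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo_a, hi_a = config.rotation_degrees_range
    lo_s, hi_s = config.affine_scale_range
    angle = float(rng.uniform(lo_a, hi_a)) if hi_a > lo_a else float(lo_a)
    scale = float(rng.uniform(lo_s, hi_s)) if hi_s > lo_s else float(lo_s)
    flip = rng.uniform() < config.vertical_flip_prob
    image, mask = sample.image, sample.mask
    if angle != 0.0 or scale != 1.0:
        image, mask = _affine_pair(image, mask, angle, scale)
    if flip:
        image, mask = image[::-1].copy(), mask[::-1].copy()
    return VesselSample(image=np.clip(image, 0.0, 1.0),
                        mask=mask.astype(np.uint8), meta=sample.meta)


def preprocess_fundus(image, config: AugmentationConfig) -> np.ndarray:
    """Fundus intensity pipeline: gray -> standardize -> CLAHE -> gamma.

    Accepts (H, W) or (H, W, 3) arrays in [0, 1] or 8-bit. Output is a
    float image rescaled to [0, 1].
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3:
        # Rec.709 luminance weights
        arr = arr @ np.array([0.2126, 0.7152, 0.0722])
    if arr.max() > 1.0:
        arr = arr / 255.0
    std = arr.std()
    arr = (arr - arr.mean()) / (std + 1e-8)
    arr = _rescale01(arr)
    if config.clahe_clip_limit is not None and config.clahe_clip_limit > 0:
        arr = exposure.equalize_adapthist(
            arr, clip_limit=config.clahe_clip_limit,
            kernel_size=config.clahe_tile_size)
    gamma = float(np.sqrt(config.gamma_range[0] * config.gamma_range[1]))
    if gamma != 1.0:
        arr = np.power(arr, gamma)
    return _rescale01(arr)


def _rescale01(arr):
    span = arr.max() - arr.min()
    if span <= 0:
        return np.full_like(arr, 0.5)
    return (arr - arr.min()) / span


def sample_patches(sample: VesselSample, spec: PatchSpec) -> list:
    """Random square patches with centers uniform over the full image."""
    h, w = sample.image.shape
    ps = spec.patch_size
    if ps > min(h, w) and spec.border == "clamp":
        raise ValueError(f"patch_size {ps} exceeds image size {h}x{w}")
    rng = np.random.default_rng(spec.seed)
    out = []
    half = ps // 2
    for _ in range(spec.n_patches_per_image):
        cy = int(rng.integers(0, h))
        cx = int(rng.integers(0, w))
        if spec.border == "clamp":
            y0 = int(np.clip(cy - half, 0, h - ps))
            x0 = int(np.clip(cx - half, 0, w - ps))
            img = sample.image[y0:y0 + ps, x0:x0 + ps]
            msk = sample.mask[y0:y0 + ps, x0:x0 + ps]
        else:
            img = np.zeros((ps, ps), dtype=sample.image.dtype)
            msk = np.zeros((ps, ps), dtype=sample.mask.dtype)
            y0, x0 = cy - half, cx - half
            ys, xs = slice(max(y0, 0), min(y0 + ps, h)), slice(max(x0, 0), min(x0 + ps, w))
            yd = slice(ys.start - y0, ys.stop - y0)
            xd = slice(xs.start - x0, xs.stop - x0)
            img[yd, xd] = sample.image[ys, xs]
            msk[yd, xd] = sample.mask[ys, xs]
        out.append(VesselSample(image=img.copy(), mask=msk.copy(), meta=sample.meta))
    return out
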