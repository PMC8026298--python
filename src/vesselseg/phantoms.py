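"""Synthetic vessel phantoms with exact ground truth.

A phantom is a branching tree of cubic-smoothed random-walk centerlines,
rasterized as tapering tubes (widths sampled per branch, linearly narrowing
toward the tip), painted over a noisy background.  By default the foreground
is brighter than the background (CTA-like); ``dark_vessels`` inverts the
image for fundus-like data.  A smooth multiplicative-style bias field models
the slowly varying illumination/contrast of real angiographic slices so that
no single global threshold separates the classes perfectly.

Small isolated distractor blobs (``n_noise_blobs``, each at most 3 px) can be
added as extra mask components; they exercise the connected-component
post-filter.

All randomness flows through one ``numpy.random.Generator`` seeded from the
config, so a (config, seed) pair reproduces a sample bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import interpolate
from scipy.ndimage import gaussian_filter


@dataclass(frozen=True)
class PhantomConfig:
    image_size: tuple = (64, 64)
    n_branches: int = 4
    width_range: tuple = (1.0, 8.0)
    tortuosity: float = 0.3
    foreground_intensity_range: tuple = (0.55, 0.9)
    background_intensity_range: tuple = (0.1, 0.4)
    noise_sigma: float = 0.05
    n_noise_blobs: int = 0
    bias_field_amplitude: float = 0.15
    dark_vessels: bool = False
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        wmin, wmax = self.width_range
        if h < 1 or w < 1:
            raise ValueError("image_size must be positive")
        if wmin < 1 or wmax < wmin:
            raise ValueError("width_range requires 1 <= min <= max")
        for name in ("foreground_intensity_range", "background_intensity_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must satisfy 0 <= min <= max <= 1")
        if self.tortuosity < 0 or self.noise_sigma < 0 or self.bias_field_amplitude < 0:
            raise ValueError("tortuosity, noise_sigma and bias_field_amplitude must be >= 0")
        if self.n_branches < 0 or self.n_noise_blobs < 0:
            raise ValueError("counts must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("image_size", "width_range",
                    "foreground_intensity_range", "background_intensity_range"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        for key in ("image_size", "width_range",
                    "foreground_intensity_range", "background_intensity_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class VesselSample:
    image: np.ndarray   # (H, W) float in [0, 1]
    mask: np.ndarray    # (H, W) uint8 in {0, 1}
    meta: PhantomConfig | None = None

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")


def _smooth_centerline(points: np.ndarray) -> np.ndarray:
    """Cubic-spline smoothing of a walk polyline, densely resampled."""
    if len(points) < 4:
        return points
    # parametrize by cumulative length, fit a lightly smoothing cubic spline
    d = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))]
    if d[-1] <= 0:
        return points
    try:
        tck, _ = interpolate.splprep(points.T, u=d, s=len(points) * 0.5, k=3)
    except Exception:
        return points
    u = np.linspace(0.0, d[-1], max(int(d[-1] / 0.5), 2))
    return np.stack(interpolate.splev(u, tck), axis=1)


def _walk(rng, start, heading, shape, tortuosity, max_steps):
    """Random walk with heading diffusion; stops on leaving the image."""
    h, w = shape
    pts = [np.asarray(start, dtype=float)]
    pos = pts[0].copy()
    step = 1.5
    for _ in range(max_steps):
        heading += rng.normal(0.0, 0.35 * tortuosity + 1e-9)
        pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
        if not (0 <= pos[0] < h and 0 <= pos[1] < w):
            break
        pts.append(pos.copy())
    return np.asarray(pts)


def _stamp_tube(mask, fg_map, centerline, widths, intensity):
    """Paint disks of radius width/2 along a centerline."""
    h, w = mask.shape
    for (y, x), wd in zip(centerline, widths):
        r = max(wd / 2.0, 0.5)
        y0, y1 = int(np.floor(y - r)), int(np.ceil(y + r)) + 1
        x0, x1 = int(np.floor(x - r)), int(np.ceil(x + r)) + 1
        y0, x0 = max(y0, 0), max(x0, 0)
        y1, x1 = min(y1, h), min(x1, w)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        hit = (yy - y) ** 2 + (xx - x) ** 2 <= r * r
        mask[y0:y1, x0:x1][hit] = 1
        fg_map[y0:y1, x0:x1][hit] = intensity


def _edge_start(rng, shape):
    """Random point on the image border with an inward-pointing heading."""
    h, w = shape
    side = rng.integers(0, 4)
    if side == 0:    # top, heading downward
        return np.array([0.0, rng.uniform(0, w - 1)]), rng.uniform(-0.6, 0.6)
    if side == 1:    # bottom, heading upward
        return np.array([h - 1.0, rng.uniform(0, w - 1)]), np.pi + rng.uniform(-0.6, 0.6)
    if side == 2:    # left, heading right
        return np.array([rng.uniform(0, h - 1), 0.0]), np.pi / 2 + rng.uniform(-0.6, 0.6)
    return np.array([rng.uniform(0, h - 1), w - 1.0]), -np.pi / 2 + rng.uniform(-0.6, 0.6)


def _place_blobs(rng, mask, n_blobs):
    """Add up to n_blobs isolated <=3 px components, clear of the vessels."""
    h, w = mask.shape
    placed = 0
    for _ in range(200 * max(n_blobs, 1)):
        if placed >= n_blobs:
            break
        y = int(rng.integers(3, max(h - 3, 4)))
        x = int(rng.integers(3, max(w - 3, 4)))
        if mask[max(y - 3, 0):y + 4, max(x - 3, 0):x + 4].any():
            continue
        size = int(rng.integers(1, 4))
        mask[y, x] = 1
        if size >= 2:
            mask[y, x + 1] = 1
        if size >= 3:
            mask[y + 1, x] = 1
        placed += 1


def _bias_field(rng, shape, amplitude):
    field = rng.normal(size=shape)
    field = gaussian_filter(field, sigma=max(shape) / 4.0)
    peak = np.abs(field).max()
    if peak > 0:
        field /= peak
    return amplitude * field


def generate_phantom(config: PhantomConfig) -> VesselSample:
    """Generate one phantom image/mask pair from a config."""
    h, w = config.image_size
    wmin, wmax = config.width_range
    if min(h, w) < 2 * wmax:
        raise ValueError(
            f"image_size {config.image_size} too small for max width {wmax} "
            f"(needs at least {2 * wmax} per side)")
    rng = np.random.default_rng(config.seed)
    mask = np.zeros((h, w), dtype=np.uint8)
    fg_map = np.zeros((h, w), dtype=float)

    centerlines = []
    max_steps = int(max(h, w) / 1.5)
    for b in range(config.n_branches):
        # retry short walks (an edge start can exit immediately)
        walk = None
        for _ in range(20):
            if b == 0 or not centerlines:
                start, heading = _edge_start(rng, (h, w))
            else:
                # branch off an existing centerline at a random interior point
                parent = centerlines[int(rng.integers(0, len(centerlines)))]
                start = parent[int(rng.integers(0, len(parent)))]
                heading = rng.uniform(-np.pi, np.pi)
            walk = _walk(rng, start, heading, (h, w), config.tortuosity, max_steps)
            if len(walk) >= max(3, max_steps // 8):
                break
        if walk is None or len(walk) < 2:
            continue
        line = _smooth_centerline(walk)
        line = np.clip(line, [0, 0], [h - 1, w - 1])
        base_width = rng.uniform(wmin, wmax)
        t = np.linspace(0.0, 1.0, len(line))
        widths = np.maximum(base_width * (1.0 - 0.6 * t), 1.0)   # taper to the tip
        lo, hi = config.foreground_intensity_range
        _stamp_tube(mask, fg_map, line, widths, rng.uniform(lo, hi))
        centerlines.append(line)

    if config.n_noise_blobs > 0:
        _place_blobs(rng, mask, config.n_noise_blobs)
        lo, hi = config.foreground_intensity_range
        fg_map[(mask == 1) & (fg_map == 0)] = rng.uniform(lo, hi)

    blo, bhi = config.background_intensity_range
    background = rng.uniform(blo, bhi)
    image = np.where(mask == 1, fg_map, background)
    if config.bias_field_amplitude > 0:
        image = image + _bias_field(rng, (h, w), config.bias_field_amplitude)
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=(h, w))
    image = np.clip(image, 0.0, 1.0)
    if config.dark_vessels:
        image = 1.0 - image
    return VesselSample(image=image, mask=mask, meta=config)


def generate_dataset(config: PhantomConfig, n: int, seed: int) -> list:
    """Generate ``n`` phantoms with per-sample seeds derived from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    return [
        generate_phantom(dataclasses.replace(config, seed=int(s)))
        for s in child_seeds
    ]


# -- disk round-trip ----------------------------------------------------------

def save_sample(directory, stem: str, sample: VesselSample):
    """Write <stem>_image.png (8-bit gray), <stem>_mask.png (0/255) and a
    JSON sidecar of the generating config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img8 = np.round(np.clip(sample.image, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(img8).save(directory / f"{stem}_image.png")
    Image.fromarray((sample.mask * 255).astype(np.uint8)).save(
        directory / f"{stem}_mask.png")
    if sample.meta is not None:
        (directory / f"{stem}.json").write_text(json.dumps(sample.meta.to_dict(), indent=2))


def load_sample(directory, stem: str) -> VesselSample:
    directory = Path(directory)
    image = np.asarray(Image.open(directory / f"{stem}_image.png"), dtype=float) / 255.0
    mask = (np.asarray(Image.open(directory / f"{stem}_mask.png")) > 127).astype(np.uint8)
    meta_path = directory / f"{stem}.json"
    meta = PhantomConfig.from_dict(json.loads(meta_path.read_text())) if meta_path.exists() else None
    return VesselSample(image=image, mask=mask, meta=meta)
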