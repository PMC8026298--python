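"""Connected-component post-filter for predicted vessel masks.

The vascular tree is connected, so predicted-foreground islands that are
disconnected from the vessel and tiny relative to it are almost surely
mis-segmentation noise.  The filter removes every component whose pixel
count is strictly below ``min_fraction`` (default 0.03%) of the total
predicted foreground; an absolute-pixel threshold mode is also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class ComponentRow:
    label: int
    pixel_count: int
    fraction: float


@dataclass
class ComponentTable:
    rows: list = field(default_factory=list)

    def __len__(self):
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


def _labeled(mask, connectivity):
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask)
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError("mask must be binary (0/1)")
    if mask.ndim == 3:
        # stacked slices: 8 -> full 26-connectivity, 4 -> faces only
        structure = (np.ones((3, 3, 3), dtype=bool) if connectivity == 8
                     else ndimage.generate_binary_structure(3, 1))
    else:
        structure = _STRUCTURES[connectivity]
    labels, n = ndimage.label(mask, structure=structure)
    return mask, labels, n


def label_components(mask, connectivity: int = 8) -> ComponentTable:
    """Connected components with deterministic raster-scan label order."""
    mask, labels, n = _labeled(mask, connectivity)
    if n == 0:
        return ComponentTable()
    counts = np.bincount(labels.ravel())[1:]
    # order labels by the flat index of each component's first pixel
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so that the earliest index wins
    first[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable")
    total = counts.sum()
    rows = [
        ComponentRow(label=rank + 1, pixel_count=int(counts[old]),
                     fraction=float(counts[old] / total))
        for rank, old in enumerate(order)
    ]
    return ComponentTable(rows=rows)


def remove_small(mask, min_fraction: float = 0.0003, connectivity: int = 8,
                 min_pixels: int | None = None) -> np.ndarray:
    """Drop components strictly smaller than a fraction of total foreground.

    With ``min_pixels`` set, the threshold is absolute instead.  The output
    foreground is always a subset of the input; the operation is idempotent
    (survivor fractions only grow after removal).
    """
    if not (0.0 <= min_fraction < 1.0):
        raise ValueError("min_fraction must lie in [0, 1)")
    mask, labels, n = _labeled(mask, connectivity)
    out = mask.copy()
    if n == 0:
        return out
    counts = np.bincount(labels.ravel())[1:]
    total = counts.sum()
    cutoff = min_pixels if min_pixels is not None else min_fraction * total
    drop = np.flatnonzero(counts < cutoff) + 1
    if drop.size:
        out[np.isin(labels, drop)] = 0
    return out
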