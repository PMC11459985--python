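"""Shared helpers for the texture-matrix builders."""

from __future__ import annotations

import numpy as np

#: The 13 unique 3D direction offsets (half of the 26-neighbourhood):
#: every offset in {-1,0,1}^3 \ {0} whose first non-zero component is
#: positive.  Merging counts over these plus their negations covers all
#: 26 directions once.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
    and (dx > 0 or (dx == 0 and (dy > 0 or (dy == 0 and dz > 0))))
)

assert len(DIRECTIONS_13) == 13


class DegenerateROIError(ValueError):
    """The ROI cannot support the requested texture computation."""


def shift(arr: np.ndarray, offset: tuple[int, int, int],
          fill: int = 0) -> np.ndarray:
    """Return ``s`` with ``s[v] = arr[v + offset]`` and ``fill`` off-grid."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for n, o in zip(arr.shape, offset):
        lo, hi = max(o, 0), n + min(o, 0)
        src.append(slice(lo, hi))
        dst.append(slice(lo - o, hi - o))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy in bits of a (possibly sparse) distribution."""
    p = np.asarray(p, dtype=np.float64)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def crop_to_mask(levels: np.ndarray, pad: int = 1) -> np.ndarray:
    """Crop a sentinel-0 level grid to its occupied bounding box + pad.

    Texture matrices only see in-mask voxels, so computing inside the
    padded bounding box is exact and much faster on large grids.
    """
    occupied = np.nonzero(levels > 0)
    if occupied[0].size == 0:
        raise DegenerateROIError("empty ROI")
    slices = tuple(
        slice(int(ax.min()), int(ax.max()) + 1) for ax in occupied)
    cropped = levels[slices]
    if pad:
        cropped = np.pad(cropped, pad, constant_values=0)
    return cropped
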