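"""Fixed-bin-number intensity discretization of a region of interest.

Texture matrices operate on small integer gray levels, not raw
activities.  The fixed-bin-number (FBN) scheme divides the in-ROI
min-max intensity range into ``ng`` equal bins, which makes every
downstream feature invariant to positive affine rescaling of the input
intensities — the property that lets phantom activities and clinical
SUVs share one feature definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..phantom import ActivityVolume, ROIMask

__all__ = ["DiscretizedROI", "discretize_fbn"]


@dataclass
class DiscretizedROI:
    """Integer gray-level grid: 1..ng inside the mask, 0 outside."""

    levels: np.ndarray
    ng: int
    mask: np.ndarray
    degenerate: bool = False  # constant-intensity ROI collapsed to level 1

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def occupied_levels(self) -> np.ndarray:
        return np.unique(self.levels[self.mask])


def discretize_fbn(volume: ActivityVolume | np.ndarray,
                   mask: ROIMask | np.ndarray,
                   ng: int) -> DiscretizedROI:
    """Discretize in-ROI intensities to ``ng`` fixed bins.

    ``level = floor(ng * (x - min) / (max - min)) + 1``, clamped to
    ``ng`` at ``x = max``.  A constant ROI maps every voxel to level 1
    and is flagged degenerate.
    """
    data = volume.data if isinstance(volume, ActivityVolume) else np.asarray(volume)
    m = mask.data if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    if data.shape != m.shape:
        raise ValueError("volume and mask grids do not match")
    if not m.any():
        raise ValueError("empty ROI mask")
    if ng < 2:
        raise ValueError("ng must be at least 2")
    vals = data[m].astype(np.float64)
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(data.shape, dtype=np.int32)
    if hi == lo:
        levels[m] = 1
        return DiscretizedROI(levels, ng, m, degenerate=True)
    binned = np.floor(ng * (vals - lo) / (hi - lo)).astype(np.int32) + 1
    np.clip(binned, 1, ng, out=binned)
    levels[m] = binned
    return DiscretizedROI(levels, ng, m)
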