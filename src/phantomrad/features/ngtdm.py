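"""Neighbourhood gray-tone difference matrix (NGTDM) and its 5 features.

For every in-ROI voxel the absolute difference between its gray level
and the mean level of its valid 26-neighbours is accumulated per level
(``s_g``), alongside the level occurrence probabilities (``p_g``).
Coarseness, contrast, busyness, complexity and strength are functions
of these two vectors.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._util import DegenerateROIError, crop_to_mask
from .discretize import DiscretizedROI

__all__ = ["NGTDM_FEATURE_NAMES", "ngtdm_table", "ngtdm_features"]

NGTDM_FEATURE_NAMES = ("coarseness", "contrast", "busyness", "complexity",
                       "strength")

#: Cap applied to coarseness when its denominator vanishes (flat ROI).
COARSENESS_CAP = 1e6

_KERNEL_26 = np.ones((3, 3, 3))
_KERNEL_26[1, 1, 1] = 0.0


def ngtdm_table(droi: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level occurrence counts n_g and summed differences s_g.

    Only voxels with at least one valid (in-mask) 26-neighbour
    participate.  Returns ``(n_g, s_g, N)`` with arrays of length ng and
    N the total participating voxel count.
    """
    lvl = crop_to_mask(droi.levels, pad=0).astype(np.float64)
    mask = lvl > 0
    if not mask.any():
        raise DegenerateROIError("empty ROI")
    nb_sum = ndimage.correlate(lvl * mask, _KERNEL_26, mode="constant")
    nb_cnt = ndimage.correlate(mask.astype(np.float64), _KERNEL_26,
                               mode="constant")
    valid = mask & (nb_cnt > 0.5)
    diffs = np.abs(lvl[valid] - nb_sum[valid] / nb_cnt[valid])
    levels = lvl[valid].astype(np.int64)
    ng = droi.ng
    n_g = np.bincount(levels - 1, minlength=ng).astype(np.float64)
    s_g = np.bincount(levels - 1, weights=diffs, minlength=ng)
    return n_g, s_g, int(valid.sum())


def ngtdm_features(droi: DiscretizedROI) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity and strength."""
    n_g, s_g, n_tot = ngtdm_table(droi)
    if n_tot == 0:
        raise DegenerateROIError("no voxel has a valid neighbourhood")
    p = n_g / n_tot
    occ = p > 0
    gp = np.arange(1, droi.ng + 1, dtype=np.float64)[occ]
    pp, sp = p[occ], s_g[occ]
    n_levels = int(occ.sum())

    f: dict[str, float] = {}
    denom = float((pp * sp).sum())
    f["coarseness"] = min(1.0 / denom, COARSENESS_CAP) if denom > 0 else COARSENESS_CAP

    if n_levels > 1:
        dmat = gp[:, None] - gp[None, :]
        pij = pp[:, None] * pp[None, :]
        f["contrast"] = (float((pij * dmat**2).sum())
                         / (n_levels * (n_levels - 1))
                         * float(sp.sum()) / n_tot)
        busy_den = float(np.abs(gp[:, None] * pp[:, None]
                                - gp[None, :] * pp[None, :]).sum())
        f["busyness"] = denom / busy_den if busy_den > 0 else 0.0
        pi = pp[:, None] + pp[None, :]
        num = np.abs(dmat) * (pp[:, None] * sp[:, None]
                              + pp[None, :] * sp[None, :]) / pi
        f["complexity"] = float(num.sum()) / n_tot
        s_sum = float(sp.sum())
        f["strength"] = (float((pi * dmat**2).sum()) / s_sum
                         if s_sum > 0 else 0.0)
    else:
        # single occupied level: all neighbourhood differences vanish
        f["contrast"] = 0.0
        f["busyness"] = 0.0
        f["complexity"] = 0.0
        f["strength"] = 0.0
    return f
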