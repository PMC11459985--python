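"""Gray-level run-length matrix (GLRLM) and its 16 features.

A run is a maximal set of collinear consecutive voxels sharing one gray
level.  Runs are counted along the 13 unique 3D directions and pooled
into a single matrix indexed by (gray level, run length).
"""

from __future__ import annotations

import numpy as np

from ._util import DIRECTIONS_13, DegenerateROIError, crop_to_mask, entropy_bits, shift
from .discretize import DiscretizedROI

__all__ = ["GLRLM_FEATURE_NAMES", "glrlm_matrix", "glrlm_features"]

GLRLM_FEATURE_NAMES = (
    "short_runs_emphasis",
    "long_runs_emphasis",
    "low_grey_level_run_emphasis",
    "high_grey_level_run_emphasis",
    "short_run_low_grey_level_emphasis",
    "short_run_high_grey_level_emphasis",
    "long_run_low_grey_level_emphasis",
    "long_run_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "run_length_non_uniformity",
    "run_length_non_uniformity_normalised",
    "run_percentage",
    "grey_level_variance",
    "run_length_variance",
    "run_entropy",
)


def glrlm_matrix(droi: DiscretizedROI,
                 directions=DIRECTIONS_13) -> np.ndarray:
    """Run-length count matrix (ng × Lmax) merged over ``directions``.

    For each direction a run starts at a voxel whose predecessor along
    the direction is off-mask or a different level; the run length is
    found by walking forward until the level changes.  Conservation:
    sum over the matrix of count × length = n_voxels × n_directions.
    """
    if not directions:
        raise ValueError("direction set must be non-empty")
    lvl = crop_to_mask(droi.levels, pad=1)
    n_vox = int((lvl > 0).sum())
    if n_vox == 0:
        raise DegenerateROIError("empty ROI")
    max_len = max(lvl.shape)
    ng = droi.ng
    counts = np.zeros((ng, max_len), dtype=np.float64)
    for d in directions:
        back = tuple(-c for c in d)
        prev = shift(lvl, back)
        starts = (lvl > 0) & (prev != lvl)
        pos = np.argwhere(starts)
        vals = lvl[starts]
        alive = np.arange(pos.shape[0])
        length = 1
        step = np.asarray(d)
        cur = pos
        while alive.size:
            cur = cur + step  # padded border guarantees in-bounds
            nxt = lvl[cur[:, 0], cur[:, 1], cur[:, 2]]
            ended = nxt != vals[alive]
            if ended.any():
                np.add.at(counts[:, length - 1], vals[alive[ended]] - 1, 1.0)
            alive = alive[~ended]
            cur = cur[~ended]
            length += 1
    assert counts.sum(axis=0) @ np.arange(1, max_len + 1) == n_vox * len(directions)
    return counts


def glrlm_features(droi: DiscretizedROI,
                   directions=DIRECTIONS_13) -> dict[str, float]:
    """The 16 run-length features of the merged matrix."""
    counts = glrlm_matrix(droi, directions)
    n_runs = counts.sum()
    n_vox = int((droi.levels > 0).sum())
    ng, lmax = counts.shape
    g = np.arange(1, ng + 1, dtype=np.float64)
    l = np.arange(1, lmax + 1, dtype=np.float64)
    r_g = counts.sum(axis=1)
    r_l = counts.sum(axis=0)
    p = counts / n_runs

    f: dict[str, float] = {}
    f["short_runs_emphasis"] = float((r_l / l**2).sum() / n_runs)
    f["long_runs_emphasis"] = float((r_l * l**2).sum() / n_runs)
    f["low_grey_level_run_emphasis"] = float((r_g / g**2).sum() / n_runs)
    f["high_grey_level_run_emphasis"] = float((r_g * g**2).sum() / n_runs)
    gl2 = np.outer(1.0 / g**2, 1.0 / l**2)
    f["short_run_low_grey_level_emphasis"] = float((counts * gl2).sum() / n_runs)
    f["short_run_high_grey_level_emphasis"] = float(
        (counts * np.outer(g**2, 1.0 / l**2)).sum() / n_runs)
    f["long_run_low_grey_level_emphasis"] = float(
        (counts * np.outer(1.0 / g**2, l**2)).sum() / n_runs)
    f["long_run_high_grey_level_emphasis"] = float(
        (counts * np.outer(g**2, l**2)).sum() / n_runs)
    f["grey_level_non_uniformity"] = float((r_g**2).sum() / n_runs)
    f["grey_level_non_uniformity_normalised"] = float((r_g**2).sum() / n_runs**2)
    f["run_length_non_uniformity"] = float((r_l**2).sum() / n_runs)
    f["run_length_non_uniformity_normalised"] = float((r_l**2).sum() / n_runs**2)
    f["run_percentage"] = float(n_runs / (n_vox * len(directions)))
    mu_g = float((g * p.sum(axis=1)).sum())
    f["grey_level_variance"] = float(((g - mu_g) ** 2 * p.sum(axis=1)).sum())
    mu_l = float((l * p.sum(axis=0)).sum())
    f["run_length_variance"] = float(((l - mu_l) ** 2 * p.sum(axis=0)).sum())
    f["run_entropy"] = entropy_bits(p)
    return f
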