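"""Gray-level size-zone matrix (GLSZM) and its 16 features.

A zone is a 26-connected component of voxels sharing one gray level;
the matrix counts zones by (gray level, zone size).  Unlike run-length
counting the zone partition is direction-free, so there is exactly one
matrix per ROI.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._util import DegenerateROIError, crop_to_mask, entropy_bits
from .discretize import DiscretizedROI

__all__ = ["GLSZM_FEATURE_NAMES", "glszm_matrix", "glszm_features", "zone_table"]

GLSZM_FEATURE_NAMES = (
    "small_zone_emphasis",
    "large_zone_emphasis",
    "low_grey_level_zone_emphasis",
    "high_grey_level_zone_emphasis",
    "small_zone_low_grey_level_emphasis",
    "small_zone_high_grey_level_emphasis",
    "large_zone_low_grey_level_emphasis",
    "large_zone_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "zone_size_non_uniformity",
    "zone_size_non_uniformity_normalised",
    "zone_percentage",
    "grey_level_variance",
    "zone_size_variance",
    "zone_size_entropy",
)

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


def zone_table(droi: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-zone (gray level, size) plus the labelled zone grid.

    Returns ``(levels, sizes, label_grid)`` where ``label_grid`` holds a
    globally unique positive label per zone (0 outside the mask); it is
    shared with the distance-zone matrix so both families see the same
    partition.
    """
    lvl = crop_to_mask(droi.levels, pad=0)
    zone_levels: list[np.ndarray] = []
    zone_sizes: list[np.ndarray] = []
    label_grid = np.zeros(lvl.shape, dtype=np.int32)
    next_label = 0
    for g in range(1, droi.ng + 1):
        comp, n = ndimage.label(lvl == g, structure=_STRUCTURE_26)
        if n == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        zone_levels.append(np.full(n, g))
        zone_sizes.append(sizes)
        sel = comp > 0
        label_grid[sel] = comp[sel] + next_label
        next_label += n
    if next_label == 0:
        raise DegenerateROIError("empty ROI")
    return (np.concatenate(zone_levels), np.concatenate(zone_sizes), label_grid)


def glszm_matrix(droi: DiscretizedROI) -> np.ndarray:
    """Zone count matrix (ng × Smax)."""
    levels, sizes, _ = zone_table(droi)
    counts = np.zeros((droi.ng, int(sizes.max())), dtype=np.float64)
    np.add.at(counts, (levels - 1, sizes - 1), 1.0)
    return counts


def _zone_family_features(counts: np.ndarray, n_vox: int,
                          axis_name: str) -> dict[str, float]:
    """Shared formula block for size-zone and distance-zone matrices.

    ``axis_name`` is "size" or "distance" and fixes the second-axis
    feature names; the algebra is identical in the two families.
    """
    n_zones = counts.sum()
    ng, smax = counts.shape
    g = np.arange(1, ng + 1, dtype=np.float64)
    s = np.arange(1, smax + 1, dtype=np.float64)
    z_g = counts.sum(axis=1)
    z_s = counts.sum(axis=0)
    p = counts / n_zones
    small = "small_zone" if axis_name == "size" else "small_distance"
    large = "large_zone" if axis_name == "size" else "large_distance"
    axis2 = "zone_size" if axis_name == "size" else "zone_distance"

    f: dict[str, float] = {}
    f[f"{small}_emphasis"] = float((z_s / s**2).sum() / n_zones)
    f[f"{large}_emphasis"] = float((z_s * s**2).sum() / n_zones)
    f["low_grey_level_zone_emphasis"] = float((z_g / g**2).sum() / n_zones)
    f["high_grey_level_zone_emphasis"] = float((z_g * g**2).sum() / n_zones)
    f[f"{small}_low_grey_level_emphasis"] = float(
        (counts * np.outer(1.0 / g**2, 1.0 / s**2)).sum() / n_zones)
    f[f"{small}_high_grey_level_emphasis"] = float(
        (counts * np.outer(g**2, 1.0 / s**2)).sum() / n_zones)
    f[f"{large}_low_grey_level_emphasis"] = float(
        (counts * np.outer(1.0 / g**2, s**2)).sum() / n_zones)
    f[f"{large}_high_grey_level_emphasis"] = float(
        (counts * np.outer(g**2, s**2)).sum() / n_zones)
    f["grey_level_non_uniformity"] = float((z_g**2).sum() / n_zones)
    f["grey_level_non_uniformity_normalised"] = float((z_g**2).sum() / n_zones**2)
    f[f"{axis2}_non_uniformity"] = float((z_s**2).sum() / n_zones)
    f[f"{axis2}_non_uniformity_normalised"] = float((z_s**2).sum() / n_zones**2)
    f["zone_percentage"] = float(n_zones / n_vox)
    mu_g = float((g * p.sum(axis=1)).sum())
    f["grey_level_variance"] = float(((g - mu_g) ** 2 * p.sum(axis=1)).sum())
    mu_s = float((s * p.sum(axis=0)).sum())
    f[f"{axis2}_variance"] = float(((s - mu_s) ** 2 * p.sum(axis=0)).sum())
    f[f"{axis2}_entropy"] = entropy_bits(p)
    return f


def glszm_features(droi: DiscretizedROI) -> dict[str, float]:
    """The 16 size-zone features."""
    counts = glszm_matrix(droi)
    return _zone_family_features(counts, droi.n_voxels, "size")
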