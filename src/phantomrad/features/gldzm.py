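"""Gray-level distance-zone matrix (GLDZM) and its 16 features.

Shares the 26-connected zone partition with the size-zone matrix, but
tabulates each zone by its minimum city-block (Manhattan) distance to
the ROI border instead of its size.  A voxel adjacent to any
outside-ROI voxel has distance 1, so distances are always >= 1 and the
two matrices have identical zone counts on the same input.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._util import crop_to_mask
from .discretize import DiscretizedROI
from .glszm import _zone_family_features, zone_table

__all__ = ["GLDZM_FEATURE_NAMES", "gldzm_matrix", "gldzm_features"]

GLDZM_FEATURE_NAMES = (
    "small_distance_emphasis",
    "large_distance_emphasis",
    "low_grey_level_zone_emphasis",
    "high_grey_level_zone_emphasis",
    "small_distance_low_grey_level_emphasis",
    "small_distance_high_grey_level_emphasis",
    "large_distance_low_grey_level_emphasis",
    "large_distance_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "zone_distance_non_uniformity",
    "zone_distance_non_uniformity_normalised",
    "zone_percentage",
    "grey_level_variance",
    "zone_distance_variance",
    "zone_distance_entropy",
)


def roi_border_distance(droi: DiscretizedROI) -> np.ndarray:
    """City-block distance of each in-ROI voxel to the nearest outside voxel.

    Computed on the mask bounding box padded with one outside layer, so
    voxels on the image edge count as bordering the outside.
    """
    lvl = crop_to_mask(droi.levels, pad=0)
    padded = np.pad(lvl > 0, 1, constant_values=False)
    dist = ndimage.distance_transform_cdt(padded, metric="taxicab")
    return dist[1:-1, 1:-1, 1:-1].astype(np.int32)


def gldzm_matrix(droi: DiscretizedROI) -> np.ndarray:
    """Zone count matrix (ng × Dmax) by minimum border distance."""
    levels, _, label_grid = zone_table(droi)
    dist = roi_border_distance(droi)
    n = levels.size
    zone_dist = ndimage.minimum(dist, labels=label_grid,
                                index=np.arange(1, n + 1))
    zone_dist = np.asarray(zone_dist, dtype=np.int32)
    counts = np.zeros((droi.ng, int(zone_dist.max())), dtype=np.float64)
    np.add.at(counts, (levels - 1, zone_dist - 1), 1.0)
    return counts


def gldzm_features(droi: DiscretizedROI) -> dict[str, float]:
    """The 16 distance-zone features."""
    counts = gldzm_matrix(droi)
    return _zone_family_features(counts, droi.n_voxels, "distance")
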