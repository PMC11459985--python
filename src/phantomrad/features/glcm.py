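"""Gray-level co-occurrence matrix (GLCM) and its 25 features.

The GLCM tabulates how often gray levels i and j co-occur at a fixed
voxel offset.  Here a single symmetric matrix is pooled over all 13
unique 3D directions at a given Chebyshev distance (the "3D merged"
aggregation), so every feature is a function of one joint probability
distribution p(i, j).
"""

from __future__ import annotations

import numpy as np

from ._util import DIRECTIONS_13, DegenerateROIError, crop_to_mask, entropy_bits, shift
from .discretize import DiscretizedROI

__all__ = ["GLCM_FEATURE_NAMES", "glcm_matrix", "glcm_features"]

GLCM_FEATURE_NAMES = (
    "joint_maximum",
    "joint_average",
    "joint_variance",
    "joint_entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "angular_second_moment",
    "contrast",
    "dissimilarity",
    "inverse_difference",
    "inverse_difference_normalised",
    "inverse_difference_moment",
    "inverse_difference_moment_normalised",
    "inverse_variance",
    "correlation",
    "autocorrelation",
    "cluster_tendency",
    "cluster_shade",
    "cluster_prominence",
    "information_correlation_1",
    "information_correlation_2",
)


def glcm_matrix(droi: DiscretizedROI, distance: int = 1,
                directions=DIRECTIONS_13) -> np.ndarray:
    """Symmetric co-occurrence count matrix merged over ``directions``.

    Each in-mask voxel pair at offset ``distance * d`` contributes one
    count in each ordering, so the matrix equals its transpose by
    construction.
    """
    if not directions:
        raise ValueError("direction set must be non-empty")
    if distance < 1:
        raise ValueError("distance must be a positive voxel count")
    lvl = crop_to_mask(droi.levels, pad=distance)
    ng = droi.ng
    counts = np.zeros((ng, ng), dtype=np.float64)
    for d in directions:
        off = tuple(distance * c for c in d)
        nb = shift(lvl, off)
        valid = (lvl > 0) & (nb > 0)
        if not valid.any():
            continue
        pairs = (lvl[valid].astype(np.int64) - 1) * ng + (nb[valid] - 1)
        counts += np.bincount(pairs, minlength=ng * ng).reshape(ng, ng)
    counts = counts + counts.T
    if counts.sum() == 0:
        raise DegenerateROIError("no co-occurring voxel pairs in ROI")
    return counts


def glcm_features(droi: DiscretizedROI, distance: int = 1,
                  directions=DIRECTIONS_13) -> dict[str, float]:
    """The 25 co-occurrence features of the merged symmetric matrix."""
    counts = glcm_matrix(droi, distance, directions)
    ng = counts.shape[0]
    p = counts / counts.sum()
    i = np.arange(1, ng + 1, dtype=np.float64)
    I = i[:, None] * np.ones((1, ng))
    J = I.T

    p_i = p.sum(axis=1)          # marginal (symmetric: rows == cols)
    mu = float((i * p_i).sum())
    sigma2 = float(((i - mu) ** 2 * p_i).sum())

    # difference and sum marginals
    k_diff = np.arange(ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    absdiff = np.abs(I - J).astype(np.int64)
    sums = (I + J).astype(np.int64)
    np.add.at(p_diff, absdiff.ravel(), p.ravel())
    np.add.at(p_sum, sums.ravel() - 2, p.ravel())

    da = float((k_diff * p_diff).sum())
    sa = float((k_sum * p_sum).sum())

    f: dict[str, float] = {}
    f["joint_maximum"] = float(p.max())
    f["joint_average"] = mu
    f["joint_variance"] = sigma2
    f["joint_entropy"] = entropy_bits(p)
    f["difference_average"] = da
    f["difference_variance"] = float(((k_diff - da) ** 2 * p_diff).sum())
    f["difference_entropy"] = entropy_bits(p_diff)
    f["sum_average"] = sa
    f["sum_variance"] = float(((k_sum - sa) ** 2 * p_sum).sum())
    f["sum_entropy"] = entropy_bits(p_sum)
    f["angular_second_moment"] = float((p**2).sum())
    f["contrast"] = float(((I - J) ** 2 * p).sum())
    f["dissimilarity"] = float((np.abs(I - J) * p).sum())
    f["inverse_difference"] = float((p / (1.0 + np.abs(I - J))).sum())
    f["inverse_difference_normalised"] = float(
        (p / (1.0 + np.abs(I - J) / ng)).sum())
    f["inverse_difference_moment"] = float((p / (1.0 + (I - J) ** 2)).sum())
    f["inverse_difference_moment_normalised"] = float(
        (p / (1.0 + ((I - J) / ng) ** 2)).sum())
    off = ~np.eye(ng, dtype=bool)
    f["inverse_variance"] = float((p[off] / (I - J)[off] ** 2).sum())
    autoc = float((I * J * p).sum())
    # a flat marginal (single occupied level) has zero variance; the
    # matrix is then perfectly "correlated" by convention
    f["correlation"] = (autoc - mu * mu) / sigma2 if sigma2 > 0 else 1.0
    f["autocorrelation"] = autoc
    dev = I + J - 2.0 * mu
    f["cluster_tendency"] = float((dev**2 * p).sum())
    f["cluster_shade"] = float((dev**3 * p).sum())
    f["cluster_prominence"] = float((dev**4 * p).sum())

    hxy = f["joint_entropy"]
    hx = entropy_bits(p_i)
    pi_pj = p_i[:, None] * p_i[None, :]
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log2(pi_pj[nz])).sum())
    hxy2 = entropy_bits(pi_pj)
    f["information_correlation_1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    f["information_correlation_2"] = float(
        np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    return f
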