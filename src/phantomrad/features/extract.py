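"""Full 78-feature extraction for one (volume, mask) pair.

Canonical feature order: 25 GLCM, 16 GLRLM, 16 GLSZM, 16 GLDZM and
5 NGTDM features, each prefixed by its family.  Volumes are resampled
to a fixed isotropic spacing before fixed-bin-number discretization so
that voxel dimensions never vary between images entering the stability
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..phantom import ActivityVolume, ROIMask
from .discretize import DiscretizedROI, discretize_fbn
from .glcm import GLCM_FEATURE_NAMES, glcm_features
from .glrlm import GLRLM_FEATURE_NAMES, glrlm_features
from .glszm import GLSZM_FEATURE_NAMES, glszm_features
from .gldzm import GLDZM_FEATURE_NAMES, gldzm_features
from .ngtdm import NGTDM_FEATURE_NAMES, ngtdm_features
from ._util import DIRECTIONS_13

__all__ = ["ExtractionParams", "FEATURE_NAMES", "FAMILY_SIZES",
           "feature_family", "extract_all"]

FAMILY_SIZES = {"glcm": 25, "glrlm": 16, "glszm": 16, "gldzm": 16, "ngtdm": 5}

#: The canonical ordered catalogue of the 78 feature names.
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"glcm_{n}" for n in GLCM_FEATURE_NAMES)
    + tuple(f"glrlm_{n}" for n in GLRLM_FEATURE_NAMES)
    + tuple(f"glszm_{n}" for n in GLSZM_FEATURE_NAMES)
    + tuple(f"gldzm_{n}" for n in GLDZM_FEATURE_NAMES)
    + tuple(f"ngtdm_{n}" for n in NGTDM_FEATURE_NAMES)
)

assert len(FEATURE_NAMES) == 78 == sum(FAMILY_SIZES.values())


def feature_family(name: str) -> str:
    """Family label ("glcm", ..., "ngtdm") of a canonical feature name."""
    return name.split("_", 1)[0]


@dataclass(frozen=True)
class ExtractionParams:
    """Knobs of the feature-extraction stage.

    ng:            fixed bin number for discretization (64 gray levels).
    spacing:       target isotropic voxel spacing in mm.
    glcm_distance: co-occurrence offset in voxels.
    families:      subset of families to compute (all by default); a
                   reduced set is useful for targeted analyses.
    """

    ng: int = 64
    spacing: float = 2.0
    glcm_distance: int = 1
    families: tuple[str, ...] = ("glcm", "glrlm", "glszm", "gldzm", "ngtdm")


def _resample(volume: ActivityVolume, mask: ROIMask,
              target: float) -> tuple[ActivityVolume, ROIMask]:
    """Trilinear volume / nearest-neighbour mask resampling."""
    factor = volume.spacing / target
    data = ndimage.zoom(volume.data, factor, order=1)
    m = ndimage.zoom(mask.data.astype(np.uint8), factor, order=0) > 0
    if m.shape != data.shape:  # zoom rounds per-axis; align defensively
        m = m[tuple(slice(0, s) for s in data.shape)]
    return (ActivityVolume(np.clip(data, 0, None), target, volume.origin),
            ROIMask(m, target, mask.origin))


def extract_all(volume: ActivityVolume, mask: ROIMask,
                params: ExtractionParams | None = None) -> dict[str, float]:
    """Compute the feature catalogue for one image and ROI.

    Returns an ordered name→value mapping; with the default parameters
    it holds all 78 features in canonical order.
    """
    if params is None:
        params = ExtractionParams()
    if volume.data.shape != mask.data.shape:
        raise ValueError("volume and mask grids do not match")
    if abs(volume.spacing - params.spacing) > 1e-9:
        volume, mask = _resample(volume, mask, params.spacing)
    droi = discretize_fbn(volume, mask, params.ng)
    dirs = DIRECTIONS_13
    out: dict[str, float] = {}
    if "glcm" in params.families:
        for k, v in glcm_features(droi, params.glcm_distance, dirs).items():
            out[f"glcm_{k}"] = v
    if "glrlm" in params.families:
        for k, v in glrlm_features(droi, dirs).items():
            out[f"glrlm_{k}"] = v
    if "glszm" in params.families:
        for k, v in glszm_features(droi).items():
            out[f"glszm_{k}"] = v
    if "gldzm" in params.families:
        for k, v in gldzm_features(droi).items():
            out[f"gldzm_{k}"] = v
    if "ngtdm" in params.families:
        for k, v in ngtdm_features(droi).items():
            out[f"ngtdm_{k}"] = v
    return out
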