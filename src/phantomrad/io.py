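"""NIfTI input/output for activity volumes and ROI masks."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import ActivityVolume, ROIMask

__all__ = ["save_volume", "load_volume", "save_mask", "load_mask"]


def _affine(spacing: float, origin) -> np.ndarray:
    aff = np.diag([spacing, spacing, spacing, 1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(volume: ActivityVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32),
                          _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> ActivityVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], atol=1e-6):
        raise ValueError("anisotropic volumes must be resampled on load")
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return ActivityVolume(np.asarray(img.dataobj, dtype=np.float64),
                          float(zooms[0]), origin)


def save_mask(mask: ROIMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8),
                          _affine(mask.spacing, mask.origin))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> ROIMask:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return ROIMask(np.asarray(img.dataobj) > 0, float(zooms[0]), origin)
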