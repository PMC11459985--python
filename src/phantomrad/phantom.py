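"""Digital PET phantom: syringe-array tumour inserts in a water cylinder.

The phantom emulated here is a water-filled cylinder at low background
activity holding four artificial tumour inserts, each built from seven
parallel syringes mounted on a 38 mm pitch-circle (six on the ring, one
central).  Filling the syringes with different F-18 activity
concentrations produces homogeneous and heterogeneous uptake patterns;
an omitted ("necrotic") syringe models a cold tumour core.

The module voxelizes these geometries into activity volumes, applies an
image-space surrogate of iterative PET reconstruction (PSF blur,
iteration/subset-scaled noise, TOF noise gain, Gaussian post-filter) and
produces the fixed syringe-footprint ROI mask that is overlaid on every
image so that delineation never contributes to feature variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "NECROTIC",
    "PhantomGeometry",
    "InsertConfig",
    "ReconSetting",
    "NoiseModel",
    "ActivityVolume",
    "ROIMask",
    "TABLE1_VARIATIONS",
    "DEFAULT_SETTING",
    "default_geometry",
    "default_insert_configs",
    "build_activity_volume",
    "enumerate_settings",
    "emulate_reconstruction",
    "make_roi_mask",
]

#: Marker for a cold, water-filled syringe (necrotic tumour core).
NECROTIC = "NECROTIC"

#: Conversion from Gaussian FWHM to standard deviation.
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class GeometryError(ValueError):
    """Phantom geometry is physically inconsistent."""


class ConfigError(ValueError):
    """An insert or setting configuration violates its contract."""


@dataclass(frozen=True)
class PhantomGeometry:
    """Geometry of the cylinder phantom and one 7-syringe insert.

    All lengths in mm, activities in kBq/ml.  Syringe axes run along z;
    six syringes sit on the pitch circle, one at the insert centre.  The
    defaults give an insert volume of 7·pi·r²·L = 144.9 cm³, matching
    the ~145 cm³ synthetic tumour, with adjacent syringes exactly
    touching (ring spacing 19 mm = 2 × 9.5 mm radius).
    """

    cylinder_radius: float = 100.0
    cylinder_length: float = 120.0
    voxel_spacing: float = 2.0
    syringe_radius: float = 9.5
    syringe_length: float = 73.0
    pitch_circle_diameter: float = 38.0
    background_activity: float = 5.0
    insert_centers: tuple[tuple[float, float, float], ...] = (
        (56.0, 0.0, 0.0),
        (0.0, 56.0, 0.0),
        (-56.0, 0.0, 0.0),
        (0.0, -56.0, 0.0),
    )

    @property
    def n_syringes(self) -> int:
        return 7

    def syringe_offsets(self) -> np.ndarray:
        """(7, 3) in-plane offsets of syringe axes from the insert centre.

        Index 0 is the central syringe; 1..6 run anticlockwise around
        the pitch circle starting on the +x axis.
        """
        ring = self.pitch_circle_diameter / 2.0
        offsets = [(0.0, 0.0, 0.0)]
        for k in range(6):
            a = math.pi * k / 3.0
            offsets.append((ring * math.cos(a), ring * math.sin(a), 0.0))
        return np.asarray(offsets)

    def insert_volume_cm3(self) -> float:
        """Nominal (analytic) volume of one 7-syringe insert in cm³."""
        one = math.pi * self.syringe_radius**2 * self.syringe_length
        return 7 * one / 1000.0

    def validate(self) -> None:
        if self.voxel_spacing <= 0:
            raise GeometryError("voxel_spacing must be positive")
        if min(self.cylinder_radius, self.cylinder_length,
               self.syringe_radius, self.syringe_length) <= 0:
            raise GeometryError("all phantom dimensions must be positive")
        offs = self.syringe_offsets()[:, :2]
        # pairwise overlap of parallel cylinders: centre spacing < 2r
        for i in range(len(offs)):
            for j in range(i + 1, len(offs)):
                d = float(np.linalg.norm(offs[i] - offs[j]))
                if d < 2.0 * self.syringe_radius - 1e-9:
                    raise GeometryError(
                        f"syringes {i} and {j} overlap (spacing {d:.2f} mm "
                        f"< {2 * self.syringe_radius:.2f} mm)")
        ring = self.pitch_circle_diameter / 2.0
        reach = ring + self.syringe_radius
        for cx, cy, cz in self.insert_centers:
            if math.hypot(cx, cy) + reach > self.cylinder_radius + 1e-9:
                raise GeometryError("insert protrudes from the cylinder wall")
            if abs(cz) + self.syringe_length / 2.0 > self.cylinder_length / 2.0 + 1e-9:
                raise GeometryError("insert protrudes axially from the cylinder")
        vol = self.insert_volume_cm3()
        if not (0.9 * 145.0 <= vol <= 1.1 * 145.0):
            raise GeometryError(
                f"insert volume {vol:.1f} cm³ outside 145 cm³ ± 10%")

    def grid_shape(self) -> tuple[int, int, int]:
        n_xy = int(math.ceil(2.0 * self.cylinder_radius / self.voxel_spacing))
        n_z = int(math.ceil(self.cylinder_length / self.voxel_spacing))
        return (n_xy, n_xy, n_z)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1D physical coordinates of voxel centres along x, y, z (mm)."""
        nx, ny, nz = self.grid_shape()

        def axis(n: int) -> np.ndarray:
            return (np.arange(n) - (n - 1) / 2.0) * self.voxel_spacing

        return axis(nx), axis(ny), axis(nz)


@dataclass(frozen=True)
class InsertConfig:
    """Activity assignment for the seven syringes of one insert.

    ``syringe_activities`` is ordered (centre first, then the six ring
    positions) and holds activities in kBq/ml or :data:`NECROTIC`.
    """

    shape_id: int
    syringe_activities: tuple

    def validate(self) -> None:
        acts = self.syringe_activities
        if len(acts) != 7:
            raise ConfigError("an insert has exactly 7 syringes")
        hot = [a for a in acts if a != NECROTIC]
        n_necrotic = 7 - len(hot)
        if any(not (isinstance(a, (int, float)) and a >= 0) for a in hot):
            raise ConfigError("activities must be non-negative numbers")
        if self.shape_id in (1, 2):
            if any(a != 40.0 for a in hot):
                raise ConfigError("homogeneous inserts use 40 kBq/ml syringes")
        elif self.shape_id in (3, 4):
            if any(a not in (20.0, 40.0, 80.0) for a in hot):
                raise ConfigError(
                    "heterogeneous inserts draw from {20, 40, 80} kBq/ml")
            if max(hot) / min(hot) != 4.0:
                raise ConfigError("heterogeneous max/min activity ratio must be 4")
        else:
            raise ConfigError("shape_id must be 1..4")
        expected_necrotic = 1 if self.shape_id in (2, 4) else 0
        if n_necrotic != expected_necrotic:
            raise ConfigError(
                f"shape {self.shape_id} requires {expected_necrotic} "
                f"necrotic syringe(s), got {n_necrotic}")


def default_geometry() -> PhantomGeometry:
    geom = PhantomGeometry()
    geom.validate()
    return geom


def default_insert_configs() -> tuple[InsertConfig, ...]:
    """The four study insert configurations.

    1: homogeneous (7 × 40); 2: homogeneous necrotic (cold centre);
    3: heterogeneous (centre 40, ring alternating 80/20);
    4: heterogeneous necrotic (cold centre, ring alternating 80/20).
    The spatial assignment of the ring activities is a fixed convention,
    exposed here so alternative layouts can be configured.
    """
    ring_alt = (80.0, 20.0, 80.0, 20.0, 80.0, 20.0)
    configs = (
        InsertConfig(1, (40.0,) * 7),
        InsertConfig(2, (NECROTIC,) + (40.0,) * 6),
        InsertConfig(3, (40.0,) + ring_alt),
        InsertConfig(4, (NECROTIC,) + ring_alt),
    )
    for c in configs:
        c.validate()
    return configs


@dataclass(frozen=True)
class ReconSetting:
    """One reconstruction-parameter combination.

    ``family`` names the varied parameter ("subsets", "iterations",
    "filter", "tof") or "default" for the clinical reference setting.
    """

    setting_id: str
    subsets: int
    iterations: int
    filter_fwhm: float
    tof: bool
    family: str = "default"

    def physical_key(self) -> tuple:
        """Key identifying the physical parameters (ignores the label)."""
        return (self.subsets, self.iterations,
                round(self.filter_fwhm * 100), self.tof)


DEFAULT_SETTING = ReconSetting("default", 24, 2, 6.4, True)

#: One-at-a-time variation lists of the reconstruction parameter grid.
TABLE1_VARIATIONS: dict[str, tuple] = {
    "subsets": (12, 16, 18, 24, 32),
    "iterations": (1, 2, 3, 4, 5, 6),
    "filter": (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0),
    "tof": (True, False),
}


def enumerate_settings(
    variations: dict[str, Sequence] | None = None,
    default: ReconSetting = DEFAULT_SETTING,
) -> list[ReconSetting]:
    """Enumerate one setting per one-at-a-time parameter variation.

    Every parameter in ``variations`` is swept over its list while the
    other three stay at the default, giving 5 + 6 + 8 + 2 = 21 settings
    for the standard grid.  Setting ids are unique even where different
    labels share the default's physical parameters.
    """
    if variations is None:
        variations = TABLE1_VARIATIONS
    settings: list[ReconSetting] = []
    for family in ("subsets", "iterations", "filter", "tof"):
        values = variations.get(family, ())
        if len(values) == 0:
            raise ConfigError(f"empty variation list for {family!r}")
        for v in values:
            if family == "subsets":
                s = replace(default, subsets=int(v))
                sid = f"subsets_{int(v)}"
            elif family == "iterations":
                s = replace(default, iterations=int(v))
                sid = f"iterations_{int(v)}"
            elif family == "filter":
                if v < 0:
                    raise ConfigError("filter FWHM must be non-negative")
                s = replace(default, filter_fwhm=float(v))
                sid = f"filter_{v:g}"
            else:
                s = replace(default, tof=bool(v))
                sid = "tof_on" if v else "tof_off"
            settings.append(replace(s, setting_id=sid, family=family))
    ids = [s.setting_id for s in settings]
    assert len(set(ids)) == len(ids)
    return settings


@dataclass(frozen=True)
class NoiseModel:
    """Image-space surrogate for iterative PET reconstruction.

    psf_fwhm:          intrinsic scanner resolution applied before noise (mm).
    base_noise_sd:     noise SD at the reference iteration×subset product,
                       in kBq/ml (default 10% of the 5 kBq/ml background).
    reference_product: iterations×subsets product of the clinical default
                       (2 × 24 = 48); noise SD scales with
                       sqrt(product / reference).
    tof_gain:          factor by which time-of-flight information divides
                       the noise SD.
    """

    psf_fwhm: float = 5.0
    base_noise_sd: float = 0.5
    reference_product: float = 48.0
    tof_gain: float = 1.35

    def noise_sd(self, setting: ReconSetting) -> float:
        sd = self.base_noise_sd * math.sqrt(
            setting.iterations * setting.subsets / self.reference_product)
        if setting.tof:
            sd /= self.tof_gain
        return sd


@dataclass
class ActivityVolume:
    """3D activity grid (kBq/ml) with isotropic spacing.

    ``origin`` is the physical coordinate (mm) of the centre of voxel
    (0, 0, 0); axes are (x, y, z).
    """

    data: np.ndarray
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("activity volume must be 3D")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("activity must be finite and non-negative")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


@dataclass
class ROIMask:
    """Boolean ROI aligned to an :class:`ActivityVolume`."""

    data: np.ndarray
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("ROI mask must be 3D")
        if self.voxel_count < 2:
            raise ValueError("ROI must contain at least 2 voxels")

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def volume_cm3(self) -> float:
        return self.voxel_count * self.spacing**3 / 1000.0


def _syringe_masks(geometry: PhantomGeometry,
                   insert_center: tuple[float, float, float]) -> list[np.ndarray]:
    """Centre-point voxelization of the 7 syringe cylinders of one insert."""
    xs, ys, zs = geometry.voxel_centers()
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]
    cx, cy, cz = insert_center
    masks = []
    half_len = geometry.syringe_length / 2.0
    r2 = geometry.syringe_radius**2
    axial = np.abs(Z - cz) <= half_len
    for ox, oy, _ in geometry.syringe_offsets():
        radial = (X - cx - ox) ** 2 + (Y - cy - oy) ** 2 < r2
        masks.append(radial & axial)
    return masks


def _cylinder_mask(geometry: PhantomGeometry) -> np.ndarray:
    xs, ys, zs = geometry.voxel_centers()
    radial = xs[:, None] ** 2 + ys[None, :] ** 2 < geometry.cylinder_radius**2
    axial = np.abs(zs) <= geometry.cylinder_length / 2.0
    return radial[:, :, None] & axial[None, None, :]


def _origin(geometry: PhantomGeometry) -> tuple[float, float, float]:
    xs, ys, zs = geometry.voxel_centers()
    return (float(xs[0]), float(ys[0]), float(zs[0]))


def build_activity_volume(geometry: PhantomGeometry,
                          config: InsertConfig) -> ActivityVolume:
    """Voxelize one insert configuration into an activity volume.

    A voxel belongs to a syringe iff its centre lies inside the syringe
    cylinder (no partial-volume subsampling).  Necrotic syringes and the
    water bath carry the background activity; voxels outside the
    cylinder are zero.  The insert sits at
    ``geometry.insert_centers[config.shape_id - 1]``.
    """
    geometry.validate()
    config.validate()
    if config.shape_id > len(geometry.insert_centers):
        raise ConfigError("no insert position defined for this shape_id")
    center = geometry.insert_centers[config.shape_id - 1]
    data = np.zeros(geometry.grid_shape(), dtype=np.float64)
    data[_cylinder_mask(geometry)] = geometry.background_activity
    for activity, mask in zip(config.syringe_activities,
                              _syringe_masks(geometry, center)):
        if activity == NECROTIC:
            continue  # cold water-filled syringe stays at background
        data[mask] = float(activity)
    return ActivityVolume(data, geometry.voxel_spacing, _origin(geometry))


def make_roi_mask(geometry: PhantomGeometry, insert_index: int) -> ROIMask:
    """Fixed ROI: the 7-syringe footprint translated to one insert position.

    The same contour (the homogeneous insert's syringe union) is reused
    for every shape and every reconstruction setting, eliminating
    delineation variability.  ``insert_index`` is 0-based.
    """
    geometry.validate()
    if not 0 <= insert_index < len(geometry.insert_centers):
        raise IndexError("insert_index out of range")
    center = geometry.insert_centers[insert_index]
    mask = np.zeros(geometry.grid_shape(), dtype=bool)
    for m in _syringe_masks(geometry, center):
        mask |= m
    return ROIMask(mask, geometry.voxel_spacing, _origin(geometry))


def emulate_reconstruction(volume: ActivityVolume,
                           setting: ReconSetting,
                           noise_model: NoiseModel | None = None,
                           seed: int = 0) -> ActivityVolume:
    """Apply the image-space reconstruction surrogate to a volume.

    Pipeline: Gaussian PSF blur at the intrinsic scanner FWHM → additive
    zero-mean Gaussian noise with SD ∝ sqrt(iterations × subsets),
    divided by the TOF gain when TOF is on → Gaussian post-filter at the
    setting's cut-off FWHM (0 mm means no post-filter) → clip negatives.
    Deterministic for fixed (volume, setting, noise_model, seed).
    """
    if noise_model is None:
        noise_model = NoiseModel()
    if setting.filter_fwhm < 0 or noise_model.psf_fwhm < 0:
        raise ValueError("Gaussian FWHM must be non-negative")
    spacing = volume.spacing
    out = volume.data.astype(np.float64, copy=True)
    if noise_model.psf_fwhm > 0:
        out = gaussian_filter(out, noise_model.psf_fwhm * _FWHM_TO_SIGMA / spacing)
    sd = noise_model.noise_sd(setting)
    if sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, sd, size=out.shape)
    if setting.filter_fwhm > 0:
        out = gaussian_filter(out, setting.filter_fwhm * _FWHM_TO_SIGMA / spacing)
    np.clip(out, 0.0, None, out=out)
    return ActivityVolume(out, spacing, volume.origin)
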