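"""PET volume container, NIfTI I/O and body-weight SUV conversion.

The standardized uptake value (SUV) normalizes measured tracer activity
concentration by the injected dose per gram of body weight, so that a
uniform whole-body distribution of the decayed dose maps to SUV 1.  All
geometry is voxel-center, millimeters; volumes are reported in ml.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "SuvVolume",
    "InjectionMeta",
    "F18_HALF_LIFE_MIN",
    "load_volume",
    "save_volume",
    "to_suv",
    "voxel_volume_ml",
]

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77


@dataclass
class SuvVolume:
    """A 3-D scalar grid of SUV values with voxel geometry.

    Parameters
    ----------
    values
        3-D array of SUV (dimensionless, g/ml convention).
    spacing_mm
        Per-axis voxel size in millimeters, all positive.
    origin_mm
        World position of the center of voxel (0, 0, 0).
    axis_order
        Tag recording the axis convention of ``values`` (default "xyz":
        axis 0 = x, axis 1 = y, axis 2 = z in world coordinates).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"SuvVolume requires a 3-D grid, got {self.values.ndim}-D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis (1-D arrays)."""
        return tuple(
            self.origin_mm[a] + np.arange(self.shape[a]) * self.spacing_mm[a]
            for a in range(3)
        )


@dataclass
class InjectionMeta:
    """Injection metadata needed to convert activity concentration to SUV."""

    injected_dose_bq: float
    injection_to_scan_min: float
    body_weight_kg: float
    isotope_half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        for name in ("injected_dose_bq", "injection_to_scan_min", "body_weight_kg",
                     "isotope_half_life_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


def load_volume(path: str | Path) -> SuvVolume:
    """Load a 3-D NIfTI volume; spacing and origin come from the header.

    Raises
    ------
    ValueError
        If the image is not 3-D or lacks positive voxel spacing.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI volume, got {data.ndim} dims in {path}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel spacing {zooms} in {path}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return SuvVolume(values=data, spacing_mm=tuple(float(z) for z in zooms),
                     origin_mm=origin)


def save_volume(vol: SuvVolume, path: str | Path) -> None:
    """Write a volume as NIfTI with spacing/origin encoded in the affine."""
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    affine[:3, 3] = vol.origin_mm
    img = nib.Nifti1Image(vol.values.astype(np.float64), affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))


def to_suv(activity_bq_per_ml: SuvVolume, meta: InjectionMeta) -> SuvVolume:
    """Convert an activity-concentration volume (Bq/ml) to body-weight SUV.

    SUV = C · W / (D · 2^(−t/T½)) with C the measured concentration in
    Bq/ml, W body weight in grams, D the injected dose in Bq decayed over
    the uptake time t.  A uniform concentration equal to decayed dose per
    body gram maps to SUV 1 everywhere.
    """
    decayed_dose_bq = meta.injected_dose_bq * 2.0 ** (
        -meta.injection_to_scan_min / meta.isotope_half_life_min
    )
    weight_g = meta.body_weight_kg * 1000.0
    suv = activity_bq_per_ml.values * weight_g / decayed_dose_bq
    if np.any(suv < 0):
        raise ValueError("negative activity yields negative SUV; input must be >= 0")
    return SuvVolume(values=suv, spacing_mm=activity_bq_per_ml.spacing_mm,
                     origin_mm=activity_bq_per_ml.origin_mm,
                     axis_order=activity_bq_per_ml.axis_order)


def voxel_volume_ml(vol: SuvVolume) -> float:
    """Volume of one voxel in ml (product of spacings / 1000)."""
    return float(np.prod(vol.spacing_mm)) / 1000.0
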