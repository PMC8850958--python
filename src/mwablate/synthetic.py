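"""Synthetic mDIXON-like fat-fraction volumes with liver and vessel masks.

Stands in for protected patient imaging: generates a smooth, spatially
correlated fat-percent field inside an ellipsoidal liver mask, with a simple
cylindrical vessel tree excluded from sampling.  Field statistics target the
disease-state means/SDs observed clinically (e.g. 29.90 +/- 3.7 percent for
high fatty liver disease); the sample mean and SD over the liver mask match
the targets exactly before clipping to the physical [0, 100] range.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .materials import DISEASE_FAT_MEANS, DISEASE_FAT_SDS

__all__ = ["VesselCylinder", "FatMapSpec", "FatFractionVolume",
           "generate_fat_map", "spec_for_state"]


@dataclass(frozen=True)
class VesselCylinder:
    """Straight vessel segment: endpoints in mm (world), radius in mm."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float


def _default_vessels() -> list[VesselCylinder]:
    # a crude portal-vein fork through the liver midline
    return [
        VesselCylinder((-60, 0, 0), (60, 20, 10), 6.0),
        VesselCylinder((0, 8, 3), (50, -30, -15), 4.0),
        VesselCylinder((0, 8, 3), (-45, -30, 12), 4.0),
    ]


@dataclass(frozen=True)
class FatMapSpec:
    """Targets for one synthetic fat-fraction volume.

    ``target_mean``/``target_sd`` are in fat percent over the liver mask;
    ``correlation_length`` (mm) sets the spatial smoothness of the
    heterogeneity; ``liver_shape`` are ellipsoid semi-axes in mm.
    """

    target_mean: float = 29.90
    target_sd: float = 3.7
    correlation_length: float = 8.0
    liver_shape: tuple[float, float, float] = (80.0, 60.0, 50.0)
    spacing: tuple[float, float, float] = (2.083, 2.083, 3.0)
    margin: float = 6.0          # mm of background around the liver
    vessel_tree: tuple[VesselCylinder, ...] = dataclass_field(
        default_factory=lambda: tuple(_default_vessels()))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_sd < 0:
            raise ValueError("target_sd must be >= 0")
        if self.target_mean < 0 or self.target_mean > 100:
            raise ValueError("target_mean must be in [0, 100]")
        if min(self.liver_shape) <= 0 or min(self.spacing) <= 0:
            raise ValueError("degenerate liver shape or voxel spacing")


@dataclass
class FatFractionVolume:
    """3D fat-percent field with congruent liver/vessel masks.

    ``values`` are percent in [0, 100]; ``spacing`` is mm per voxel along
    (x, y, z); ``vessel_mask`` is a subset of ``liver_mask``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    liver_mask: np.ndarray
    vessel_mask: np.ndarray

    def __post_init__(self) -> None:
        if not (self.values.shape == self.liver_mask.shape == self.vessel_mask.shape):
            raise ValueError("masks must be congruent with the value field")
        if np.any(self.vessel_mask & ~self.liver_mask):
            raise ValueError("vessel mask must lie inside the liver mask")
        if self.values.min() < 0 or self.values.max() > 100:
            raise ValueError("fat percentages must lie in [0, 100]")

    def to_nifti(self, path: str | Path, masks: bool = True) -> None:
        """Write values (float32) and optionally masks (uint8) as NIfTI."""
        import nibabel as nib

        affine = np.diag([*self.spacing, 1.0])
        path = Path(path)
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), path)
        if masks:
            stem = path.name.replace(".nii.gz", "").replace(".nii", "")
            for name, m in (("liver", self.liver_mask), ("vessel", self.vessel_mask)):
                nib.save(nib.Nifti1Image(m.astype(np.uint8), affine),
                         path.with_name(f"{stem}_{name}_mask.nii.gz"))

    @classmethod
    def from_nifti(cls, values_path, liver_mask_path, vessel_mask_path=None
                   ) -> "FatFractionVolume":
        import nibabel as nib

        img = nib.load(str(values_path))
        values = np.clip(np.asarray(img.dataobj, dtype=float), 0.0, 100.0)
        spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
        liver = np.asarray(nib.load(str(liver_mask_path)).dataobj) > 0
        if vessel_mask_path is None:
            vessel = np.zeros_like(liver)
        else:
            vessel = np.asarray(nib.load(str(vessel_mask_path)).dataobj) > 0
        return cls(values=values, spacing=spacing, liver_mask=liver,
                   vessel_mask=vessel & liver)


def spec_for_state(index: int, seed: int = 0, **kw) -> FatMapSpec:
    """Fat-map spec targeting the clinical mean/SD of a disease index."""
    return FatMapSpec(target_mean=DISEASE_FAT_MEANS[index],
                      target_sd=DISEASE_FAT_SDS[index], seed=seed, **kw)


def generate_fat_map(spec: FatMapSpec) -> FatFractionVolume:
    """Correlated random fat-percent field inside an ellipsoidal liver.

    White noise is smoothed by a Gaussian kernel of width
    ``correlation_length`` and affinely rescaled so that the sample mean and
    SD over the liver mask equal the targets exactly; values are then
    clipped to [0, 100] (a no-op for clinically realistic targets).
    Deterministic for a given spec (seeded generator).
    """
    a = np.asarray(spec.liver_shape, float)
    sp = np.asarray(spec.spacing, float)
    half = a + spec.margin
    shape = tuple(int(np.ceil(2 * h / s)) | 1 for h, s in zip(half, sp))
    coords = [(np.arange(n) - (n - 1) / 2) * s for n, s in zip(shape, sp)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    liver = (X / a[0]) ** 2 + (Y / a[1]) ** 2 + (Z / a[2]) ** 2 <= 1.0
    if not liver.any():
        raise ValueError("degenerate liver shape: empty mask")

    rng = np.random.default_rng(spec.seed)
    field = rng.standard_normal(shape)
    if spec.correlation_length > 0:
        field = ndimage.gaussian_filter(field, sigma=spec.correlation_length / sp)
    sample = field[liver]
    sd = sample.std()
    if spec.target_sd == 0 or sd == 0:
        field = np.full(shape, spec.target_mean)
    else:
        field = (field - sample.mean()) / sd * spec.target_sd + spec.target_mean
    values = np.clip(field, 0.0, 100.0)

    vessel = np.zeros(shape, bool)
    pts = np.stack([X, Y, Z], axis=-1)
    for cyl in spec.vessel_tree:
        p0 = np.asarray(cyl.p0, float)
        d = np.asarray(cyl.p1, float) - p0
        L2 = d @ d
        if L2 == 0:
            continue
        t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
        closest = p0 + t[..., None] * d
        vessel |= np.linalg.norm(pts - closest, axis=-1) <= cyl.radius
    vessel &= liver
    return FatFractionVolume(values=values, spacing=tuple(sp), liver_mask=liver,
                             vessel_mask=vessel)
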