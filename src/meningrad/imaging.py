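"""Volume and mask containers, NIfTI I/O, and MRI preprocessing.

The analysis operates on contrast-enhanced T1 volumes paired with binary
tumor segmentations.  Preprocessing follows the standard radiomics recipe:
winsorize tumor intensities at mean +/- 3 SD, then resample image and mask
onto a common isotropic lattice (3 mm by default) so that texture offsets
correspond to a fixed physical distance across patients.

Arrays are indexed (x, y, z); spacing and origin are stored per axis in mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Input file violates the expected single-channel 3D NIfTI layout."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but too degenerate to process."""


@dataclass
class VolumeImage:
    """A 3D scalar grid with per-axis voxel spacing and origin (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise FormatError(f"expected a 3D grid, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise FormatError("all dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class SegmentationMask:
    """Binary tumor mask aligned to a :class:`VolumeImage` grid."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise FormatError(f"expected a 3D mask, got ndim={arr.ndim}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise FormatError(f"mask values must be in {{0, 1}}, got {uniq[:10]}")
        self.values = arr.astype(bool)
        if not self.values.any():
            raise DegenerateInputError("mask has no foreground voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def check_aligned(self, img: VolumeImage) -> None:
        if self.shape != img.shape:
            raise FormatError(f"mask shape {self.shape} != image shape {img.shape}")
        if not np.allclose(self.spacing, img.spacing):
            raise FormatError(f"mask spacing {self.spacing} != image spacing {img.spacing}")


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _load_grid(path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    nii = nib.load(str(path))
    data = np.asanyarray(nii.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a single-channel 3D image, got shape {data.shape}")
    zooms = tuple(float(z) for z in nii.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel spacing {zooms}")
    origin = tuple(float(v) for v in nii.affine[:3, 3])
    return data, zooms, origin


def read_volume(path) -> VolumeImage:
    """Read a single-channel 3D NIfTI volume."""
    data, spacing, origin = _load_grid(path)
    return VolumeImage(values=data.astype(np.float64), spacing=spacing, origin=origin)


def read_mask(path) -> SegmentationMask:
    """Read a binary 3D NIfTI segmentation."""
    data, spacing, origin = _load_grid(path)
    return SegmentationMask(values=data, spacing=spacing, origin=origin)


def write_volume(img: VolumeImage, path) -> None:
    """Write a volume as NIfTI; integer-valued arrays keep their dtype exactly."""
    arr = img.values
    nii = nib.Nifti1Image(arr, _affine(img.spacing, img.origin))
    nii.header.set_zooms(img.spacing)
    nib.save(nii, str(path))


def write_mask(mask: SegmentationMask, path) -> None:
    arr = mask.values.astype(np.uint8)
    nii = nib.Nifti1Image(arr, _affine(mask.spacing, mask.origin))
    nii.header.set_zooms(mask.spacing)
    nib.save(nii, str(path))


# ---------------------------------------------------------------------------
# Preprocessing


def clip_outliers(img: VolumeImage, mask: SegmentationMask) -> VolumeImage:
    """Winsorize tumor intensities at mean +/- 3 SD of the foreground.

    Mean and SD are computed over mask-foreground voxels only (the tumor is
    the analysis substrate); voxels outside the band are set to the nearer
    bound, background voxels are untouched.  Single pass: re-applying
    re-estimates the band on clipped data and may clip further.
    """
    mask.check_aligned(img)
    fg = mask.values
    n_fg = int(fg.sum())
    if n_fg < 2:
        raise DegenerateInputError("clip_outliers needs >= 2 foreground voxels to define an SD")
    vals = img.values[fg]
    mu = float(vals.mean())
    sigma = float(vals.std())  # population SD
    lo, hi = mu - 3.0 * sigma, mu + 3.0 * sigma
    out = img.values.copy()
    out[fg] = np.clip(out[fg], lo, hi)
    return VolumeImage(values=out, spacing=img.spacing, origin=img.origin)


def resample_isotropic(
    img: VolumeImage, mask: SegmentationMask, spacing_mm: float
) -> tuple[VolumeImage, SegmentationMask]:
    """Resample image (trilinear) and mask (nearest-neighbor) to an isotropic lattice.

    The output lattice starts at the input origin and covers the input
    extent; requesting the existing spacing of an already-isotropic grid is
    an identity.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")
    mask.check_aligned(img)
    in_sp = np.asarray(img.spacing)
    shape = np.asarray(img.shape)
    n_out = np.floor((shape - 1) * in_sp / spacing_mm).astype(int) + 1
    n_out = np.maximum(n_out, 1)
    # output voxel i sits at physical position i * spacing_mm along each axis
    coords = np.meshgrid(
        *[np.arange(n) * spacing_mm / in_sp[a] for a, n in enumerate(n_out)],
        indexing="ij",
    )
    coords = np.stack(coords)
    vals = ndimage.map_coordinates(img.values.astype(np.float64), coords, order=1, mode="nearest")
    msk = ndimage.map_coordinates(mask.values.astype(np.uint8), coords, order=0, mode="nearest")
    if not msk.any():
        raise DegenerateInputError("resampling produced an empty mask; target spacing too coarse")
    sp = (float(spacing_mm),) * 3
    return (
        VolumeImage(values=vals, spacing=sp, origin=img.origin),
        SegmentationMask(values=msk, spacing=sp, origin=img.origin),
    )


def preprocess(
    img: VolumeImage, mask: SegmentationMask, spacing_mm: float = 3.0
) -> tuple[VolumeImage, SegmentationMask]:
    """Standard preprocessing: outlier clipping then isotropic resampling."""
    clipped = clip_outliers(img, mask)
    return resample_isotropic(clipped, mask, spacing_mm)
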