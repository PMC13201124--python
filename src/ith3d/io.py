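"""Reading, validating and cropping CT lesion (image + mask) pairs.

Coordinate convention: voxel indices, 0-based, axis order ``(z, y, x)``
with ``z`` the axial (slice) axis.  NIfTI files store axes as ``(x, y, z)``;
arrays are transposed on load/save so that in-memory code always sees
``(z, y, x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import nibabel as nib

AFFINE_ATOL = 1e-3  # tolerated header rounding when checking grid alignment


class AlignmentError(ValueError):
    """Image and mask do not live on the same voxel grid."""


@dataclass
class CTLesion:
    """A CT intensity volume (HU) with an aligned binary lesion mask.

    Attributes
    ----------
    image : (z, y, x) float array of Hounsfield intensities.
    mask : (z, y, x) bool array, True inside the lesion.
    spacing : voxel spacing in mm per axis, (z, y, x) order.
    lesion_id : free-form identifier used in reports.
    """

    image: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_id: str = "lesion"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.image.ndim != 3:
            raise ValueError("image must be a 3D (z, y, x) array")
        if self.image.shape != self.mask.shape:
            raise AlignmentError(
                f"mask shape {self.mask.shape} != image shape {self.image.shape}"
            )
        if not self.mask.any():
            raise ValueError("mask is empty")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _to_zyx(arr: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))


def _to_xyz(arr: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))


def load_lesion(image_path, mask_path, lesion_id: str | None = None) -> CTLesion:
    """Load an image/mask NIfTI pair and validate grid alignment.

    The mask is binarized (any nonzero voxel becomes 1).  Shapes must match
    exactly and affines must agree within ``AFFINE_ATOL``.
    """
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    if img.shape != msk.shape:
        raise AlignmentError(f"mask shape {msk.shape} != image shape {img.shape}")
    if not np.allclose(img.affine, msk.affine, atol=AFFINE_ATOL):
        raise AlignmentError("image and mask affines disagree beyond tolerance")
    data = _to_zyx(np.asanyarray(img.dataobj))
    mask = _to_zyx(np.asanyarray(msk.dataobj)) != 0
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    if lesion_id is None:
        lesion_id = str(image_path)
    return CTLesion(image=data, mask=mask, spacing=spacing, lesion_id=lesion_id)


def save_lesion(lesion: CTLesion, image_path, mask_path, labels: np.ndarray | None = None,
                labels_path=None) -> None:
    """Write a lesion (and optionally a label map) as NIfTI files."""
    sz, sy, sx = lesion.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    nib.save(nib.Nifti1Image(_to_xyz(lesion.image), affine), str(image_path))
    nib.save(nib.Nifti1Image(_to_xyz(lesion.mask.astype(np.uint8)), affine), str(mask_path))
    if labels is not None:
        if labels_path is None:
            raise ValueError("labels_path required when labels are given")
        nib.save(nib.Nifti1Image(_to_xyz(labels.astype(np.int16)), affine), str(labels_path))


def largest_axial_slice(lesion: CTLesion) -> tuple[np.ndarray, np.ndarray, int]:
    """Return (intensity slice, mask slice, index) of the largest axial slice.

    The axial slice maximising the in-mask pixel count is selected; ties are
    broken by the lowest slice index so the choice is deterministic.
    """
    counts = lesion.mask.sum(axis=(1, 2))
    idx = int(np.argmax(counts))  # argmax returns the first maximum
    return lesion.image[idx], lesion.mask[idx], idx


def crop_to_mask(lesion: CTLesion, margin: int = 0) -> CTLesion:
    """Crop to the mask bounding box plus ``margin`` voxels, clipped to bounds.

    The mask voxel count is conserved; all downstream scores are invariant
    under this crop (they depend on in-mask geometry only).
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    slices = []
    for ax in range(3):
        proj = np.any(lesion.mask, axis=tuple(a for a in range(3) if a != ax))
        nz = np.flatnonzero(proj)
        lo = max(int(nz[0]) - margin, 0)
        hi = min(int(nz[-1]) + 1 + margin, lesion.mask.shape[ax])
        slices.append(slice(lo, hi))
    sl = tuple(slices)
    return replace(lesion, image=lesion.image[sl].copy(), mask=lesion.mask[sl].copy())
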