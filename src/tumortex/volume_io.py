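"""Reading, writing and discretizing CT volumes with segmentation masks.

A :class:`VolumeWithMask` couples a 3D scalar image in Hounsfield units
with an aligned binary region of interest (ROI) on a known voxel grid.
:func:`quantize_roi` maps the ROI intensities onto ``Ng`` integer gray
levels, the substrate of the co-occurrence and run-length matrices.

File formats are NRRD (``.nrrd``) and NIfTI (``.nii``/``.nii.gz``), read
and written through SimpleITK.  Arrays are stored in SimpleITK's index
order (z, y, x); ``spacing`` and ``origin`` are stored in the same axis
order so that ``spacing[i]`` is the physical step along array axis ``i``.
Orientation metadata is read but the analysis is grid-based: masks are
never resampled, and mismatched geometry is an error rather than
something silently fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import EmptyROIError, FormatError, GeometryError, ParameterError

_SPACING_RTOL = 1e-4


@dataclass
class VolumeWithMask:
    """A 3D HU image with an aligned binary ROI.

    Parameters
    ----------
    intensities : ndarray, shape (n0, n1, n2)
        Scalar image in Hounsfield units.
    spacing : tuple of float
        Physical voxel size in mm per array axis; all strictly positive.
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0) in mm.
    mask : ndarray of bool, same shape as ``intensities``
        Foreground marks the tumor ROI.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.mask = np.asarray(self.mask) != 0
        if self.intensities.ndim != 3:
            raise GeometryError("intensities must be a 3D array")
        if self.mask.shape != self.intensities.shape:
            raise GeometryError(
                f"mask shape {self.mask.shape} != image shape {self.intensities.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(s) for s in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    @property
    def roi_values(self) -> np.ndarray:
        """Intensities of the foreground voxels (1D, float)."""
        vals = self.intensities[self.mask]
        if vals.size == 0:
            raise EmptyROIError("mask contains no foreground voxel")
        return vals.astype(float)

    def require_roi(self) -> None:
        if not self.mask.any():
            raise EmptyROIError("mask contains no foreground voxel")


@dataclass
class QuantizedROI:
    """ROI voxels mapped to integer gray levels 1..Ng.

    ``levels`` lives on the original grid with background flagged as 0.
    ``bin_edges`` is the strictly increasing (Ng+1)-vector of HU edges;
    the upper edge of the last bin is inclusive.
    """

    levels: np.ndarray
    ng: int
    bin_edges: np.ndarray
    mask: np.ndarray

    @property
    def roi_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def _read_image(path: str | Path) -> sitk.Image:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffixes = "".join(path.suffixes).lower()
    if not (suffixes.endswith(".nrrd") or suffixes.endswith(".nii") or suffixes.endswith(".nii.gz")):
        raise FormatError(f"unsupported format (want .nrrd/.nii/.nii.gz): {path}")
    try:
        return sitk.ReadImage(str(path))
    except Exception as exc:  # SimpleITK raises bare RuntimeError
        raise FormatError(f"could not read {path}: {exc}") from exc


def _array_and_geometry(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return arr, spacing, origin


def read_volume_with_mask(image_path: str | Path, mask_path: str | Path) -> VolumeWithMask:
    """Read an image/mask NRRD or NIfTI pair and validate their geometry.

    Any nonzero mask voxel is foreground.  Raises
    :class:`~tumortex.errors.GeometryError` on dimension or spacing
    mismatch and :class:`~tumortex.errors.EmptyROIError` if the mask has
    no foreground voxel.
    """
    img_arr, img_sp, img_or = _array_and_geometry(_read_image(image_path))
    msk_arr, msk_sp, _ = _array_and_geometry(_read_image(mask_path))
    if img_arr.shape != msk_arr.shape:
        raise GeometryError(
            f"image {img_arr.shape} and mask {msk_arr.shape} dimensions differ"
        )
    if not np.allclose(img_sp, msk_sp, rtol=_SPACING_RTOL, atol=0):
        raise GeometryError(f"image spacing {img_sp} != mask spacing {msk_sp}")
    v = VolumeWithMask(img_arr, img_sp, img_or, msk_arr)
    v.require_roi()
    return v


def write_volume(
    path: str | Path,
    array: np.ndarray,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> None:
    """Write a 3D array as NRRD or NIfTI with the given geometry."""
    img = sitk.GetImageFromArray(np.asarray(array))
    img.SetSpacing(tuple(reversed([float(s) for s in spacing])))
    img.SetOrigin(tuple(reversed([float(s) for s in origin])))
    sitk.WriteImage(img, str(path))


def write_volume_with_mask(
    v: VolumeWithMask, image_path: str | Path, mask_path: str | Path
) -> None:
    write_volume(image_path, v.intensities, v.spacing, v.origin)
    write_volume(mask_path, v.mask.astype(np.uint8), v.spacing, v.origin)


def quantize_roi(v: VolumeWithMask, ng: int = 64) -> QuantizedROI:
    """Discretize ROI intensities into ``ng`` equal-width gray levels.

    Bins span the observed [min, max] of the ROI; the top edge is
    inclusive, so the maximum maps to level ``ng``.  A constant ROI maps
    every voxel to level 1.  The mapping is monotone in HU and invariant
    to adding a constant to all ROI intensities.
    """
    if ng < 2:
        raise ParameterError(f"ng must be >= 2, got {ng}")
    v.require_roi()
    vals = v.roi_values
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(v.intensities.shape, dtype=np.int32)
    if hi == lo:
        levels[v.mask] = 1
        edges = lo + np.arange(ng + 1, dtype=float)
    else:
        edges = np.linspace(lo, hi, ng + 1)
        idx = np.floor((vals - lo) / (hi - lo) * ng).astype(np.int64)
        np.clip(idx, 0, ng - 1, out=idx)
        levels[v.mask] = idx + 1
    return QuantizedROI(levels=levels, ng=int(ng), bin_edges=edges, mask=v.mask.copy())
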