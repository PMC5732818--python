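"""Image preprocessing: isotropic resampling and gray-level quantization.

All texture features operate on quantized ROI voxels.  Intensities inside
the contoured region Ω are mapped to a finite set of ``2**k`` gray levels

    V(x) = floor( 2**k * (I(x) - min_Ω I) / (max_Ω I - min_Ω I) )

with voxels attaining the ROI maximum clamped to ``2**k - 1`` so the output
occupies exactly ``2**k`` discrete values (0 … 2**k − 1).  The default
``k = 4`` (16 levels) is the setting under which all downstream statistics
are reported.

Volumes are resampled to isotropic 1×1×1 mm voxels (cubic interpolation for
intensities, nearest-neighbour for masks) before any feature is computed,
so texture offsets are isotropic in physical space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class DegenerateRoiError(ValueError):
    """Raised when an ROI becomes empty or otherwise unusable."""


@dataclass
class ImageVolume:
    """A 3D scalar image with voxel spacing metadata.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities (HU-like, finite).
    spacing : tuple of float
        Voxel size in mm along each axis; axial = third axis.
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")


@dataclass
class QuantizedRoi:
    """ROI voxels after gray-level quantization.

    ``levels`` holds integer levels in ``[0, 2**k - 1]`` over the full array
    grid; only entries under ``roi_mask`` are meaningful (outside the mask
    the value is -1).
    """

    levels: np.ndarray
    roi_mask: np.ndarray
    k: int
    dimensionality: str  # "2D" or "3D"

    @property
    def n_levels(self) -> int:
        return 2 ** self.k

    @property
    def roi_levels(self) -> np.ndarray:
        """Levels of the in-mask voxels only (1D array)."""
        return self.levels[self.roi_mask]


def resample_isotropic(
    volume: ImageVolume,
    mask: np.ndarray,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    order: int = 3,
) -> tuple[ImageVolume, np.ndarray]:
    """Resample a volume and its mask to a target voxel spacing.

    Intensities use spline interpolation of the given ``order`` (default
    cubic); the mask is resampled with nearest-neighbour interpolation and
    re-binarized.  The physical extent of the array is preserved to within
    one voxel.

    Raises
    ------
    DegenerateRoiError
        If the mask is empty after resampling.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != volume.data.shape:
        raise ValueError("mask shape does not match volume shape")
    zoom = tuple(s / t for s, t in zip(volume.spacing, target_spacing))
    if np.allclose(zoom, 1.0):
        return ImageVolume(volume.data.copy(), tuple(target_spacing), volume.origin), mask.copy()
    data = ndimage.zoom(volume.data, zoom, order=order, mode="nearest", grid_mode=True)
    new_mask = ndimage.zoom(mask.astype(np.uint8), zoom, order=0, mode="nearest",
                            grid_mode=True).astype(bool)
    if new_mask.shape != data.shape:  # defensive; zoom uses identical rounding
        raise RuntimeError("volume/mask resampling produced inconsistent shapes")
    if not new_mask.any():
        raise DegenerateRoiError("ROI is empty after resampling")
    return ImageVolume(data, tuple(target_spacing), volume.origin), new_mask


def quantize_gray_levels(
    data: np.ndarray, mask: np.ndarray, k: int = 4, dimensionality: str = "3D"
) -> QuantizedRoi:
    """Quantize ROI intensities to ``2**k`` discrete gray levels.

    The minimum and maximum are taken over the ROI voxels only.  A flat ROI
    (max == min) maps every voxel to level 0 with a warning.

    Parameters
    ----------
    data : ndarray
        Intensity array (2D section or 3D volume).
    mask : boolean ndarray
        ROI membership, same shape as ``data``.
    k : int
        Bit depth.  The analysis setting is ``2**k`` in [16, 128] with 16
        levels (k=4) the reporting default; smaller k is allowed for
        worked examples and diagnostics.
    """
    n_levels = 2 ** k
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != data.shape:
        raise ValueError("mask shape does not match data shape")
    if not mask.any():
        raise DegenerateRoiError("cannot quantize an empty ROI")
    roi = data[mask]
    lo, hi = roi.min(), roi.max()
    levels = np.full(data.shape, -1, dtype=np.int64)
    if hi == lo:
        warnings.warn("flat ROI: all intensities identical; all levels set to 0",
                      stacklevel=2)
        levels[mask] = 0
    else:
        v = np.floor(n_levels * (data[mask] - lo) / (hi - lo)).astype(np.int64)
        levels[mask] = np.minimum(v, n_levels - 1)
    return QuantizedRoi(levels=levels, roi_mask=mask, k=k,
                        dimensionality=dimensionality)


def largest_axial_section(mask: np.ndarray) -> int:
    """Index of the axial slice (third axis) with the largest in-mask area.

    Ties are broken toward the lowest slice index.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise DegenerateRoiError("mask is empty")
    areas = mask.sum(axis=(0, 1))
    return int(np.argmax(areas))
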