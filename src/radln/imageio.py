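"""Volume I/O, in-plane resampling and intensity normalization.

Conventions
-----------
Arrays are indexed ``(row, col, slice)``: axial slices are the planes of the
third axis.  Working volumes hold float32 intensities normalized to [0, 1];
raw scanner data are unsigned integers with a known bit depth and are
normalized by division with the dtype maximum (MATLAB ``im2double``
semantics), never by the per-image maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "RawVolume",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_mask",
    "normalize_intensity",
    "denormalize_intensity",
    "resample_slices",
]


@dataclass
class Volume:
    """Normalized 3D intensity volume.

    Attributes
    ----------
    data : (R, C, S) float32 array with values in [0, 1].
    spacing : physical voxel size per axis in mm (metadata, passed through).
    affine : 4x4 voxel-to-world matrix, passed through opaquely.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"Volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume intensities must be finite")
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError(
                "Volume intensities must lie in [0, 1]; "
                "call normalize_intensity on raw data first"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class RawVolume:
    """Unnormalized integer volume as read from disk.

    ``bit_depth`` is 8 or 16; values must be < 2**bit_depth.
    """

    data: np.ndarray
    bit_depth: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"RawVolume must be 3D, got shape {self.data.shape}")
        if self.data.max(initial=0) >= 2**self.bit_depth:
            raise ValueError("values exceed the stated bit depth")


def _spacing_from_header(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def load_volume(path) -> "Volume | RawVolume":
    """Load a NIfTI volume.

    Integer data yield a :class:`RawVolume` (bit depth from the dtype);
    floating-point data already in [0, 1] yield a :class:`Volume`.
    """
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise FileNotFoundError(f"volume file not found: {path}") from None
    except Exception as exc:  # corrupt / non-NIfTI
        raise IOError(f"cannot read NIfTI volume at {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image at {path}, got shape {data.shape}")
    spacing = _spacing_from_header(img)
    if np.issubdtype(data.dtype, np.integer):
        bit_depth = 8 if data.dtype.itemsize == 1 else 16
        return RawVolume(data=data, bit_depth=bit_depth, spacing=spacing, affine=img.affine)
    return Volume(data=data, spacing=spacing, affine=img.affine)


def load_mask(path) -> np.ndarray:
    """Load a binary mask volume; values must be {0, 1}."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D mask at {path}, got shape {data.shape}")
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"mask at {path} has values outside {{0, 1}}: {uniq[:5]}")
    return data.astype(np.uint8)


def save_volume(path, vol: "Volume | RawVolume") -> None:
    dtype = np.float32 if isinstance(vol, Volume) else vol.data.dtype
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def save_mask(path, mask: np.ndarray, affine: np.ndarray | None = None,
              spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), np.eye(4) if affine is None else affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def normalize_intensity(raw: "RawVolume | Volume") -> Volume:
    """Map integer intensities to [0, 1] by dividing by the dtype maximum.

    A :class:`Volume` (already normalized) passes through unchanged with a
    log note, matching the convention that float data in range need no work.
    """
    if isinstance(raw, Volume):
        logger.info("normalize_intensity: input already normalized, passing through")
        return raw
    denom = float(2**raw.bit_depth - 1)
    return Volume(
        data=(raw.data.astype(np.float64) / denom).astype(np.float32),
        spacing=raw.spacing,
        affine=raw.affine,
    )


def denormalize_intensity(vol: Volume, bit_depth: int) -> RawVolume:
    """Inverse of :func:`normalize_intensity` (round-trip identity for raw input)."""
    denom = float(2**bit_depth - 1)
    data = np.rint(vol.data.astype(np.float64) * denom)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return RawVolume(data=data.astype(dtype), bit_depth=bit_depth,
                     spacing=vol.spacing, affine=vol.affine)


def resample_slices(data: np.ndarray, target_rows: int = 384, target_cols: int = 384,
                    order: int = 1) -> np.ndarray:
    """Resample every axial slice to ``target_rows x target_cols``.

    Linear interpolation on the pixel-corner-free grid: output coordinates
    are ``linspace(0, n-1, target)``, so slice corners map to corners exactly
    and a constant slice stays exactly constant.  ``order=0`` (nearest) keeps
    binary masks binary.  Input already at the target shape is returned
    unchanged (the same array).
    """
    if target_rows <= 0 or target_cols <= 0:
        raise ValueError("target size must be positive")
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[:, :, None]
        squeeze = True
    else:
        squeeze = False
    if data.ndim != 3:
        raise ValueError(f"expected 2D slice or 3D volume, got shape {data.shape}")
    rows, cols, _ = data.shape
    if rows < 2 or cols < 2:
        raise ValueError("in-plane dimensions must be >= 2")
    if (rows, cols) == (target_rows, target_cols):
        return data[:, :, 0] if squeeze else data

    rr = np.linspace(0.0, rows - 1.0, target_rows)
    cc = np.linspace(0.0, cols - 1.0, target_cols)
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    out = np.empty((target_rows, target_cols, data.shape[2]), dtype=np.float64)
    for s in range(data.shape[2]):
        out[:, :, s] = map_coordinates(data[:, :, s].astype(np.float64),
                                       [grid_r, grid_c], order=order, mode="nearest")
    out = out.astype(data.dtype if order == 0 else np.float64)
    return out[:, :, 0] if squeeze else out
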