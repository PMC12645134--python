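"""Scalar CT-like volumes.

A :class:`Volume` is a 3-D grid of Hounsfield units with per-axis spacing and
a world-space origin.  Axis order is (x, y, z) throughout the package and the
world position of voxel index ``(i, j, k)`` is ``origin + index * spacing``
(axis-aligned grids; oblique direction matrices are out of scope).

I/O goes through SimpleITK, so both NIfTI (``.nii``/``.nii.gz``) and MetaImage
(``.mha``/``.mhd``) are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import DataError


@dataclass
class Volume:
    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DataError("volume data must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise DataError("voxel spacing must be positive on every axis")

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the grid along each axis."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def index_to_world(self, index) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index, float) * np.asarray(self.spacing)

    def world_to_index(self, world) -> np.ndarray:
        return (np.asarray(world, float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def axis_coords(self, axis: int, dtype=np.float64) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return (self.origin[axis] + np.arange(n, dtype=dtype) * self.spacing[axis])

    def crop(self, lo, hi, margin: int = 0) -> "Volume":
        """Sub-volume over the half-open voxel box [lo, hi), optionally padded
        by ``margin`` voxels (clipped to the grid); origin is adjusted."""
        lo = np.maximum(np.asarray(lo, int) - margin, 0)
        hi = np.minimum(np.asarray(hi, int) + margin, self.shape)
        if np.any(hi <= lo):
            raise DataError("empty crop box")
        sub = self.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        return Volume(sub, self.spacing, tuple(self.index_to_world(lo)))

    # -- SimpleITK bridge --------------------------------------------------
    def to_sitk(self, dtype=np.float32) -> sitk.Image:
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(self.data.transpose(2, 1, 0).astype(dtype))
        )
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @staticmethod
    def from_sitk(img: sitk.Image) -> "Volume":
        direction = np.asarray(img.GetDirection()).reshape(3, 3)
        if not np.allclose(direction, np.eye(3), atol=1e-6):
            raise DataError("only axis-aligned volumes are supported")
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return Volume(data, img.GetSpacing(), img.GetOrigin())

    # -- file I/O ----------------------------------------------------------
    def save(self, path, dtype=np.float32) -> None:
        sitk.WriteImage(self.to_sitk(dtype=dtype), str(path), useCompression=True)

    @staticmethod
    def load(path) -> "Volume":
        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:  # unreadable / missing file
            raise DataError(f"cannot read volume {path!s}: {exc}") from exc
        return Volume.from_sitk(img)


def mask_bbox(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Half-open bounding box (lo, hi) of the True voxels of a 3-D mask."""
    if not mask.any():
        raise DataError("mask is empty")
    idx = np.nonzero(mask)
    lo = np.array([a.min() for a in idx])
    hi = np.array([a.max() + 1 for a in idx])
    return lo, hi
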