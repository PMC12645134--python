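"""Threshold-based segmentation of the migrating / reference / align objects.

The clinical workflow builds three binary objects from the baseline CT:

* migrating object — the implant, thresholded at 2200 HU and dilated;
* reference object — the bone, thresholded at 200 HU, with the baseplate
  slices excluded, dilated, and with the implant subtracted;
* align object — the whole body outline at 3 HU (scanner bench excluded),
  used only for coarse initial registration.

Interactive manual refinement is replaced by rule-based stand-ins
(largest connected component + explicit exclusion regions), trading fidelity
to hand editing for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import DataError
from .volume import Volume

_AXES = {"x": 0, "y": 1, "z": 2}
_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class SegmentModel:
    """Binary mask congruent with its source volume, plus provenance."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = "reference"  # one of migrating / reference / align
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise DataError("segment mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    def congruent_with(self, other: "SegmentModel") -> bool:
        return (
            self.mask.shape == other.mask.shape
            and self.spacing == other.spacing
            and np.allclose(self.origin, other.origin)
        )

    def centroid_world(self) -> np.ndarray:
        idx = np.argwhere(self.mask)
        if len(idx) == 0:
            raise DataError("segment mask is empty")
        return np.asarray(self.origin) + idx.mean(axis=0) * np.asarray(self.spacing)

    def threshold_from_provenance(self) -> float | None:
        for entry in self.provenance:
            if entry.get("op") == "threshold":
                return float(entry["hu_min"])
        return None

    def with_mask(self, mask: np.ndarray, op: dict) -> "SegmentModel":
        return SegmentModel(mask, self.spacing, self.origin, self.role,
                            self.provenance + [op])


def threshold_segment(volume: Volume, hu_min: float, role: str = "reference") -> SegmentModel:
    """All voxels with HU >= ``hu_min``; errors on an empty result."""
    if not np.isfinite(hu_min):
        raise DataError("threshold must be finite")
    mask = volume.data >= hu_min
    if not mask.any():
        raise DataError(f"threshold {hu_min} HU is above the data range (empty mask)")
    return SegmentModel(mask, volume.spacing, volume.origin, role,
                        [{"op": "threshold", "hu_min": float(hu_min)}])


def largest_component(model: SegmentModel, connectivity: int = 26) -> SegmentModel:
    """Keep only the largest connected component (6/18/26-neighborhood).

    Ties are broken toward the component containing the lowest flat voxel
    index, with a warning — ties essentially never occur on real masks.
    """
    if connectivity not in _CONNECTIVITY:
        raise DataError("connectivity must be 6, 18 or 26")
    if not model.mask.any():
        raise DataError("segment mask is empty")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, n = ndimage.label(model.mask, structure=structure)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = sizes.max()
    tied = np.flatnonzero(sizes == best)
    if len(tied) > 1:
        warnings.warn(f"{len(tied)} equal-size components; keeping the one seeded first")
        flat = labels.ravel()
        first = {lab: np.argmax(flat == lab) for lab in tied}
        keep = min(tied, key=lambda lab: first[lab])
    else:
        keep = tied[0]
    return model.with_mask(labels == keep,
                           {"op": "largest_component", "connectivity": connectivity})


def exclude_slices(model: SegmentModel, axis: str, index_range: tuple[int, int]) -> SegmentModel:
    """Zero the mask on the half-open slice interval [lo, hi) along an axis."""
    if axis not in _AXES:
        raise DataError("axis must be one of x, y, z")
    ax = _AXES[axis]
    lo, hi = int(index_range[0]), int(index_range[1])
    size = model.mask.shape[ax]
    if not (0 <= lo <= hi <= size):
        raise DataError(f"slice range [{lo}, {hi}) out of bounds for axis {axis} (size {size})")
    if hi - lo >= size:
        raise DataError("exclusion range covers the full axis extent")
    mask = model.mask.copy()
    sl = [slice(None)] * 3
    sl[ax] = slice(lo, hi)
    mask[tuple(sl)] = False
    if not mask.any():
        raise DataError("slice exclusion emptied the mask")
    return model.with_mask(mask, {"op": "exclude_slices", "axis": axis, "range": [lo, hi]})


def dilate(model: SegmentModel, radius_voxels: int = 1) -> SegmentModel:
    """Morphological dilation with a (2r+1)^3 cube element (26-connected for
    r=1), applied as r passes of the 3^3 cube — equivalent by Minkowski
    additivity.  One voxel per axis is anisotropic in mm, matching the
    clinical '1 pixel' dilation on anisotropic grids."""
    if radius_voxels < 0:
        raise DataError("dilation radius must be non-negative")
    mask = model.mask
    if radius_voxels > 0:
        cube = np.ones((3, 3, 3), dtype=bool)
        mask = ndimage.binary_dilation(mask, structure=cube, iterations=radius_voxels)
    return model.with_mask(mask, {"op": "dilate", "radius_voxels": int(radius_voxels)})


def subtract(bone: SegmentModel, implant: SegmentModel) -> SegmentModel:
    """Remove the implant voxels from the bone model (prevents overlap
    between the reference and migrating objects)."""
    if not bone.congruent_with(implant):
        raise DataError("bone and implant masks are not on the same grid")
    mask = bone.mask & ~implant.mask
    if not mask.any():
        raise DataError("subtracting the implant emptied the bone mask")
    return bone.with_mask(mask, {"op": "subtract_implant"})


def build_align_object(
    volume: Volume,
    hu_min: float = 3.0,
    bench_exclusion: tuple[str, int, int] | None = None,
) -> SegmentModel:
    """Body outline for initial alignment: threshold at ``hu_min`` (3 HU by
    default), optionally zero the scanner-bench slab (axis, lo, hi), then
    keep the largest connected component."""
    model = threshold_segment(volume, hu_min, role="align")
    if bench_exclusion is not None:
        axis, lo, hi = bench_exclusion
        model = exclude_slices(model, axis, (lo, hi))
    model = largest_component(model)
    model.role = "align"
    return model
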