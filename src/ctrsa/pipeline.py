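"""Per-scan object preparation and per-pair migration analysis.

This module glues segmentation, registration and kinematics into the
two-scan comparison the clinical protocol describes: prepare the migrating /
reference / align objects on the baseline, align the scans coarsely, run the
final registrations in the configured mode, and express the implant's motion
relative to the bone in the anatomical frame marked on the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .errors import DataError
from .kinematics import MigrationResult, build_frame, migration_result
from .register import (
    PointSet,
    RegistrationResult,
    extract_surface_points,
    fit_model_to_mask,
    grayvalue_register,
    initial_align,
    relative_motion,
    surface_register,
)
from .segment import (
    SegmentModel,
    build_align_object,
    dilate,
    exclude_slices,
    largest_component,
    subtract,
    threshold_segment,
)
from .transforms import RigidTransform
from .volume import Volume


@dataclass
class StudyConfig:
    """Knobs of the analysis pipeline (defaults follow the clinical recipe)."""

    bone_threshold_hu: float = 200.0
    implant_threshold_hu: float = 2200.0
    align_threshold_hu: float = 3.0
    dilate_radius_voxels: int = 1
    mode: str = "grayvalue"              # 'grayvalue' | 'surface'
    align_object: str = "bone"           # 'bone' | 'whole_scene'
    bench_exclusion: tuple | None = None  # (axis, lo, hi) voxel slab, if a bench is present
    mid_mm: float = 0.10                 # minimal important difference for MTPM
    max_surface_points: int = 40000      # stored surface density (ICP targets)
    implant_clearance_mm: float = 4.0    # drop bone-surface points this close to the implant
    bone_clearance_voxels: int = 4       # implant dilation subtracted from the bone
                                         # reference: the implant's partial-volume
                                         # tails reach a few voxels into the bone, and
                                         # any voxel they touch moves with the implant,
                                         # not the bone
    baseplate_margin_mm: float = 2.0     # extra slab thickness around the baseplate slices
    side: str = "right"

    def __post_init__(self) -> None:
        from .errors import ConfigError

        if self.mode not in ("grayvalue", "surface"):
            raise ConfigError("mode must be 'grayvalue' or 'surface'")
        if self.align_object not in ("bone", "whole_scene"):
            raise ConfigError("align_object must be 'bone' or 'whole_scene'")
        if self.mid_mm <= 0:
            raise ConfigError("MID must be positive")


@dataclass
class ScanObjects:
    """Everything derived from one scan that the pair analysis needs."""

    implant: SegmentModel             # migrating object (dilated)
    bone: SegmentModel                # reference object (processed)
    align: SegmentModel
    model_fit: RigidTransform
    posed_points: PointSet            # implant model posed onto this scan
    features: PointSet                # the 5 posed feature points
    bone_surface: PointSet | None = None
    implant_surface: PointSet | None = None


def _baseplate_slab(volume: Volume, features: PointSet, margin_mm: float) -> tuple[int, int]:
    """Axial (z) slice interval covering the baseplate, from the posed
    baseplate feature points — the automated stand-in for the manual choice."""
    base = np.vstack([features.select(l) for l in ("medial", "lateral", "anterior", "posterior")])
    z_lo = base[:, 2].min() - margin_mm
    z_hi = base[:, 2].max() + margin_mm
    k_lo = int(np.floor((z_lo - volume.origin[2]) / volume.spacing[2]))
    k_hi = int(np.ceil((z_hi - volume.origin[2]) / volume.spacing[2])) + 1
    return max(k_lo, 0), min(k_hi, volume.shape[2])


def prepare_scan(
    volume: Volume,
    model_points: PointSet,
    config: StudyConfig = StudyConfig(),
    *,
    surfaces: bool = False,
) -> ScanObjects:
    """Build the migrating, reference and align objects for one scan.

    Follows the clinical data-preparation recipe: threshold the implant at
    2200 HU and the bone at 200 HU, keep the largest component (the stand-in
    for manual removal of other structures), register the implant point
    model to the implant segmentation, exclude the axial slices covering the
    baseplate from the bone, dilate both by one voxel, and subtract the
    implant from the bone.  With ``surfaces=True`` also extracts the
    iso-surface point sets used by the surface registration mode.
    """
    implant_raw = largest_component(
        threshold_segment(volume, config.implant_threshold_hu, role="migrating")
    )
    fit = fit_model_to_mask(model_points, implant_raw, volume=volume)
    posed = model_points.transformed(fit)
    feat_idx = [i for i, l in enumerate(posed.labels) if l != "surface"]
    features = PointSet(posed.points[feat_idx], [posed.labels[i] for i in feat_idx])

    implant = dilate(implant_raw, config.dilate_radius_voxels)
    implant.role = "migrating"

    bone_raw = largest_component(threshold_segment(volume, config.bone_threshold_hu))
    k_lo, k_hi = _baseplate_slab(volume, features, config.baseplate_margin_mm)
    if k_hi > k_lo:
        bone_proc = exclude_slices(bone_raw, "z", (k_lo, k_hi))
    else:
        bone_proc = bone_raw
    bone = subtract(
        dilate(bone_proc, config.dilate_radius_voxels),
        dilate(implant_raw, max(config.bone_clearance_voxels, config.dilate_radius_voxels)),
    )

    if config.align_object == "whole_scene":
        align = build_align_object(volume, config.align_threshold_hu, config.bench_exclusion)
    else:
        align = bone

    bone_surface = implant_surface = None
    if surfaces:
        bs = extract_surface_points(bone_raw, max_points=None, volume=volume,
                                    level=config.bone_threshold_hu)
        dist = cKDTree(posed.points).query(bs.points)[0]
        keep = dist > config.implant_clearance_mm
        pts, nrm = bs.points[keep], bs.normals[keep]
        if len(pts) < 100:
            raise DataError("too few bone surface points after implant clearance")
        if len(pts) > config.max_surface_points:
            sel = np.unique(np.linspace(0, len(pts) - 1, config.max_surface_points).astype(int))
            pts, nrm = pts[sel], nrm[sel]
        bone_surface = PointSet(pts, normals=nrm)
        implant_surface = extract_surface_points(
            implant_raw, config.max_surface_points, volume=volume,
            level=config.implant_threshold_hu,
        )
    return ScanObjects(
        implant=implant, bone=bone, align=align, model_fit=fit,
        posed_points=posed, features=features,
        bone_surface=bone_surface, implant_surface=implant_surface,
    )


def analyze_pair(
    baseline: Volume,
    followup: Volume,
    base_objects: ScanObjects,
    config: StudyConfig = StudyConfig(),
    *,
    followup_objects: ScanObjects | None = None,
    pair_id: str = "1-2",
) -> MigrationResult:
    """Measure implant migration from a baseline/follow-up scan pair."""
    fmask = followup_objects.align.mask if followup_objects is not None else None
    init = initial_align(baseline, followup, base_objects.align, followup_mask=fmask)

    if config.mode == "grayvalue":
        bone_reg = grayvalue_register(baseline, followup, base_objects.bone, init.transform)
        impl_reg = grayvalue_register(baseline, followup, base_objects.implant, init.transform)
    else:
        if followup_objects is None:
            followup_objects = prepare_scan(
                followup, base_objects.posed_points, config, surfaces=True
            )
        if base_objects.bone_surface is None or followup_objects.bone_surface is None:
            raise DataError("surface mode requires objects prepared with surfaces=True")
        bone_reg = surface_register(
            base_objects.bone_surface, followup_objects.bone_surface, init.transform
        )
        impl_reg = surface_register(
            base_objects.implant_surface, followup_objects.implant_surface, init.transform
        )

    motion = relative_motion(bone_reg, impl_reg)
    frame = build_frame(base_objects.features, side=config.side)
    qc = {
        "bone_transform": bone_reg.transform.to_dict(),
        "initial_similarity": init.similarity_final,
        "bone_similarity": bone_reg.similarity_final,
        "bone_iterations": bone_reg.n_iterations,
        "implant_similarity": impl_reg.similarity_final,
        "implant_iterations": impl_reg.n_iterations,
    }
    return migration_result(
        pair_id, motion, frame, base_objects.posed_points, base_objects.features,
        align_object=config.align_object, mode=config.mode,
        converged=bool(bone_reg.converged and impl_reg.converged), qc=qc,
    )


def save_overlay(baseline: Volume, followup: Volume, transform: RigidTransform, path) -> None:
    """Orthogonal-slice overlay snapshot for visual alignment verification:
    baseline slices in gray, aligned-follow-up difference in color."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(10, 4))
    center_idx = np.asarray(baseline.shape) // 2
    for ax_i, axis in enumerate((0, 1, 2)):
        sl = [slice(None)] * 3
        sl[axis] = center_idx[axis]
        others = [a for a in (0, 1, 2) if a != axis]
        grids = np.meshgrid(
            *[baseline.axis_coords(a) for a in others], indexing="ij"
        )
        pts = np.empty(grids[0].shape + (3,))
        pts[..., axis] = baseline.axis_coords(axis)[center_idx[axis]]
        for g, a in zip(grids, others):
            pts[..., a] = g
        moved = transform.apply(pts.reshape(-1, 3))
        fol_idx = (moved - np.asarray(followup.origin)) / np.asarray(followup.spacing)
        resampled = map_coordinates(
            followup.data, fol_idx.T, order=1, mode="constant", cval=-1000.0
        ).reshape(grids[0].shape)
        base_slice = baseline.data[tuple(sl)]
        axes[ax_i].imshow(base_slice.T, cmap="gray", origin="lower")
        axes[ax_i].imshow(
            (resampled - base_slice).T, cmap="coolwarm", origin="lower",
            alpha=0.4, vmin=-500, vmax=500,
        )
        axes[ax_i].set_title("xyz"[axis] + " slice")
        axes[ax_i].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=80)
    plt.close(fig)
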