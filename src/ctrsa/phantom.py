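"""Synthetic CT phantom: a tibia-like bone with a metal baseplate implant.

The phantom stands in for a cadaver specimen rescanned several times on the
same day: the whole scene is rigidly repositioned between scans while the
implant stays fixed relative to the bone (true migration zero), and an
optional implant-relative-to-bone motion can be injected for accuracy tests.

Geometry is deliberately simple — a tapered, elliptical cortical shell
around an eccentric marrow canal (the cross-sectional asymmetry a real
tibia has, without which rotation about the bone axis would be
unobservable), a soft-tissue cylinder, and a plate-plus-stem implant seated
on the proximal end — but the Hounsfield palette is chosen so that the clinically
used segmentation thresholds (200 HU bone, 2200 HU implant, 3 HU body
outline) separate the tissue classes by construction:

    air -1000  <  soft 40  <  200 <= cortical 1200  <  2200 <= metal 3000

Scanner-dependent degradation is modelled as i.i.d. Gaussian HU noise plus
planar bright/dark streaks emanating from the metal centroid.  This is not a
physics simulation; it is a controllable stand-in for the metal-artifact
severity differences seen between scanner models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import erfc

from .errors import ConfigError, FieldOfViewError
from .transforms import RigidTransform, random_rigid
from .volume import Volume

# voxel class labels used by the rasterizer
AIR, SOFT, CORTICAL, METAL, BENCH = 0, 1, 2, 3, 4

FEATURE_LABELS = ("medial", "lateral", "anterior", "posterior", "tip")


@dataclass(frozen=True)
class PhantomSpec:
    """Scene geometry (mm) and Hounsfield palette of the digital phantom.

    The bone is a tube along the world z axis (proximal = +z), capped
    proximally by the implant baseplate whose stem reaches down the canal.
    Anatomical directions at identity pose: medial = +x, anterior = -y,
    proximal = +z (right-knee convention).
    """

    bone_length: float = 105.0
    bone_outer_radius: float = 16.0   # major (x) semi-axis of the cortical shell
    bone_ellipticity: float = 0.8     # minor/major axis ratio of the cross-section
    bone_inner_radius: float = 5.5    # marrow canal radius
    canal_offset_mm: float = 2.0      # posterior (+y) eccentricity of the canal
    bone_taper: float = 0.12          # fractional radius reduction at the distal end
    soft_radius: float = 26.0
    plate_extent: tuple[float, float, float] = (38.0, 28.0, 4.0)
    stem_length: float = 45.0
    stem_radius: float = 3.0
    stem_offset_mm: float = 1.5       # posterior (+y) stem offset from the plate
                                      # center; also breaks the 2-fold symmetry a
                                      # centered stem + rectangular plate would
                                      # have, which would make model fitting and
                                      # frame orientation ambiguous
    hu_air: float = -1000.0
    hu_soft: float = 40.0
    hu_cortical: float = 1200.0
    hu_metal: float = 3000.0
    hu_bench: float = 100.0
    spacing: tuple[float, float, float] = (0.390625, 0.390625, 0.625)
    volume_shape: tuple[int, int, int] = (160, 160, 220)
    edge_sigma_voxels: float = 0.5    # partial-volume smoothing of the HU field
    bench: bool = False               # render a static scanner-bench slab

    def __post_init__(self) -> None:
        if not (self.hu_air < self.hu_soft < 200.0 <= self.hu_cortical < 2200.0 <= self.hu_metal):
            raise ConfigError(
                "HU palette must satisfy air < soft < 200 <= cortical < 2200 <= metal"
            )
        if abs(self.stem_offset_mm - self.canal_offset_mm) + self.stem_radius > self.bone_inner_radius:
            raise ConfigError("implant stem must fit inside the (eccentric) bone canal")
        if self.stem_length >= self.bone_length:
            raise ConfigError("implant stem must be shorter than the bone")
        if not (0.0 <= self.bone_taper < 1.0):
            raise ConfigError("bone taper must be in [0, 1)")
        if not (0.0 < self.bone_ellipticity <= 1.0):
            raise ConfigError("bone ellipticity must be in (0, 1]")
        b_min = self.bone_outer_radius * (1.0 - self.bone_taper) * self.bone_ellipticity
        if self.bone_inner_radius + self.canal_offset_mm >= b_min:
            raise ConfigError("bone canal must stay inside the cortical shell")
        if self.soft_radius <= self.bone_outer_radius:
            raise ConfigError("soft-tissue radius must exceed the bone radius")
        ext = self.extent_mm
        if self.bone_length + self.plate_extent[2] >= ext[2]:
            raise ConfigError("bone plus baseplate is longer than the field of view")

    # -- derived geometry --------------------------------------------------
    # The scene is placed a fixed sub-voxel fraction off the grid center so
    # that no flat shape boundary coincides exactly with a voxel-center
    # plane: an exactly-on-lattice face gains or loses a whole voxel layer
    # depending on rounding, which would make the identity-pose render a
    # systematically different object than any rotated render.
    _LATTICE_OFFSET = 0.37  # voxels

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.volume_shape) * np.asarray(self.spacing)

    @property
    def center_xy(self) -> tuple[float, float]:
        ext = self.extent_mm
        return (
            float(ext[0] / 2 + self._LATTICE_OFFSET * self.spacing[0]),
            float(ext[1] / 2 + self._LATTICE_OFFSET * self.spacing[1]),
        )

    @property
    def bone_z0(self) -> float:
        """Distal (lowest) z of the bone; centers bone+plate in the FOV."""
        ext = self.extent_mm
        return float(
            (ext[2] - self.bone_length - self.plate_extent[2]) / 2
            + self._LATTICE_OFFSET * self.spacing[2]
        )

    @property
    def bone_z_top(self) -> float:
        return self.bone_z0 + self.bone_length

    @classmethod
    def compact(cls) -> "PhantomSpec":
        """Smaller grid for quick multi-series studies (same construction)."""
        return cls(
            bone_length=80.0, bone_outer_radius=13.0, bone_inner_radius=4.5,
            canal_offset_mm=1.5, bone_taper=0.12, soft_radius=21.0,
            plate_extent=(30.0, 22.0, 3.5), stem_length=34.0, stem_radius=2.6,
            stem_offset_mm=1.5,
            spacing=(0.55, 0.55, 0.85), volume_shape=(96, 96, 128),
        )


@dataclass(frozen=True)
class ScannerProfile:
    """Noise / metal-artifact severity of a scanner model."""

    name: str
    noise_sd: float = 0.0             # HU, i.i.d. Gaussian
    artifact_amplitude: float = 0.0   # HU, peak streak intensity
    artifact_n_streaks: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.artifact_amplitude < 0 or self.artifact_n_streaks < 0:
            raise ConfigError("scanner degradation parameters must be non-negative")

    @property
    def is_noop(self) -> bool:
        return self.noise_sd == 0 and (self.artifact_amplitude == 0 or self.artifact_n_streaks == 0)


NO_DEGRADATION = ScannerProfile("none")
GE_LIKE = ScannerProfile("ge-like", noise_sd=10.0, artifact_amplitude=60.0, artifact_n_streaks=2)
SIEMENS_LIKE = ScannerProfile("siemens-like", noise_sd=25.0, artifact_amplitude=140.0, artifact_n_streaks=6)


@dataclass(frozen=True)
class GroundTruth:
    """Manifest serialized alongside every generated scan."""

    scene_pose: RigidTransform
    implant_migration: RigidTransform
    seed: int

    def to_dict(self) -> dict:
        return {
            "pose": self.scene_pose.to_dict(),
            "migration": self.implant_migration.to_dict(),
            "seed": int(self.seed),
        }

    @staticmethod
    def from_dict(d: dict) -> "GroundTruth":
        return GroundTruth(
            RigidTransform.from_dict(d["pose"]),
            RigidTransform.from_dict(d["migration"]),
            int(d["seed"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @staticmethod
    def load(path) -> "GroundTruth":
        with open(path) as fh:
            return GroundTruth.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _check_rigid(T: RigidTransform, name: str) -> None:
    if abs(np.linalg.det(T.rotation) - 1.0) > 1e-6:
        raise ConfigError(f"{name} is not a proper rigid transform")


def _fov_check(spec: PhantomSpec, scene_pose: RigidTransform, implant_pose: RigidTransform) -> None:
    """Raise if any posed shape would leave the grid (names the shape)."""
    cx, cy = spec.center_xy
    theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)

    def circle(r, z):
        return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta), np.full_like(theta, z)])

    z0, zt = spec.bone_z0, spec.bone_z_top
    az = spec.plate_extent[2]
    shapes = {
        "soft_tissue": (np.vstack([circle(spec.soft_radius, z0 - 4.0),
                                   circle(spec.soft_radius, zt + az + 2.0)]), scene_pose),
        "bone": (np.vstack([circle(spec.bone_outer_radius, zt),
                            circle(spec.bone_outer_radius * (1 - spec.bone_taper), z0)]), scene_pose),
    }
    ax, ay, az = spec.plate_extent
    corners = np.array([(cx + sx * ax / 2, cy + sy * ay / 2, zt + sz * az)
                        for sx in (-1, 1) for sy in (-1, 1) for sz in (0, 1)])
    tipring = circle(spec.stem_radius, zt - spec.stem_length)
    tipring[:, 1] += spec.stem_offset_mm
    shapes["implant"] = (np.vstack([corners, tipring]), implant_pose)

    lo = np.asarray(spec.spacing)
    hi = spec.extent_mm - lo
    for name, (pts, pose) in shapes.items():
        posed = pose.apply(pts)
        if np.any(posed < lo) or np.any(posed > hi):
            raise FieldOfViewError(f"{name} extends outside the field of view after posing")


def rasterize_labels(
    spec: PhantomSpec,
    scene_pose: RigidTransform = RigidTransform.identity(),
    implant_migration: RigidTransform = RigidTransform.identity(),
) -> np.ndarray:
    """Voxel class labels (AIR/SOFT/CORTICAL/METAL/BENCH) for the posed scene.

    Each voxel takes the label of the innermost shape containing its center.
    Bone and soft tissue move with ``scene_pose``; the implant moves with
    ``scene_pose @ implant_migration``; the bench (if any) is static.
    """
    _check_rigid(scene_pose, "scene_pose")
    _check_rigid(implant_migration, "implant_migration")
    implant_pose = scene_pose @ implant_migration
    _fov_check(spec, scene_pose, implant_pose)

    nx, ny, nz = spec.volume_shape
    sx, sy, sz = spec.spacing
    X = (np.arange(nx, dtype=np.float32) * sx)[:, None, None]
    Y = (np.arange(ny, dtype=np.float32) * sy)[None, :, None]
    Z = (np.arange(nz, dtype=np.float32) * sz)[None, None, :]

    def inverse_coords(pose: RigidTransform):
        inv = pose.inverse()
        R = inv.rotation.astype(np.float32)
        t = inv.translation.astype(np.float32)
        qx = R[0, 0] * X + R[0, 1] * Y + R[0, 2] * Z + t[0]
        qy = R[1, 0] * X + R[1, 1] * Y + R[1, 2] * Z + t[1]
        qz = R[2, 0] * X + R[2, 1] * Y + R[2, 2] * Z + t[2]
        return qx, qy, qz

    cx, cy = spec.center_xy
    z0, zt = spec.bone_z0, spec.bone_z_top
    ax, ay, az = spec.plate_extent

    labels = np.zeros(spec.volume_shape, dtype=np.uint8)

    xb, yb, zb = inverse_coords(scene_pose)
    dx2 = (xb - cx) ** 2
    rho2 = dx2 + (yb - cy) ** 2
    soft = (rho2 <= spec.soft_radius ** 2) & (zb >= z0 - 4.0) & (zb <= zt + az + 2.0)
    labels[soft] = SOFT
    # elliptical cortical shell (tapered) around an eccentric marrow canal:
    # the cross-sectional asymmetry is what anchors rotation about the bone
    # axis during registration, as the ridges of a real tibia do
    s = np.clip((zb - z0) / spec.bone_length, 0.0, 1.0)
    a_s = spec.bone_outer_radius * (1.0 - spec.bone_taper * (1.0 - s))
    b_s = a_s * spec.bone_ellipticity
    outer = dx2 / (a_s * a_s) + ((yb - cy) / b_s) ** 2 <= 1.0
    canal = dx2 + (yb - cy - spec.canal_offset_mm) ** 2 <= spec.bone_inner_radius ** 2
    cortical = outer & ~canal & (zb >= z0) & (zb <= zt)
    labels[cortical] = CORTICAL
    del xb, yb, zb, dx2, rho2, s, a_s, b_s, outer, canal, soft, cortical

    xi, yi, zi = inverse_coords(implant_pose)
    plate = (
        (np.abs(xi - cx) <= ax / 2) & (np.abs(yi - cy) <= ay / 2)
        & (zi >= zt) & (zi <= zt + az)
    )
    stem = (
        ((xi - cx) ** 2 + (yi - cy - spec.stem_offset_mm) ** 2 <= spec.stem_radius ** 2)
        & (zi >= zt - spec.stem_length) & (zi <= zt + az)
    )
    labels[plate | stem] = METAL
    del xi, yi, zi, plate, stem

    if spec.bench:
        ext_y = spec.extent_mm[1]
        bench = (Y >= ext_y - 5.5) & (Y <= ext_y - 2.5) & (labels == AIR)
        labels[np.broadcast_to(bench, labels.shape)] = BENCH
    return labels


def rasterize_scene(
    spec: PhantomSpec,
    scene_pose: RigidTransform = RigidTransform.identity(),
    implant_migration: RigidTransform = RigidTransform.identity(),
    *,
    smooth: bool = True,
) -> Volume:
    """HU volume of the posed scene.

    Voxels are shaded by analytic signed-distance occupancy (a linear ramp
    about half a voxel wide across every shape boundary) rather than binary
    center-in/out tests: hard voxelization leaves pose-dependent staircase
    patterns on flat faces that act as a systematic registration bias, while
    the smooth occupancy field is exactly rigid-covariant up to grid
    sampling of an already-smooth function.  An additional Gaussian
    partial-volume blur (``edge_sigma_voxels``) is applied on top unless
    ``smooth=False``.
    """
    _check_rigid(scene_pose, "scene_pose")
    _check_rigid(implant_migration, "implant_migration")
    implant_pose = scene_pose @ implant_migration
    _fov_check(spec, scene_pose, implant_pose)

    nx, ny, nz = spec.volume_shape
    sx, sy, sz = spec.spacing
    X = (np.arange(nx, dtype=np.float32) * sx)[:, None, None]
    Y = (np.arange(ny, dtype=np.float32) * sy)[None, :, None]
    Z = (np.arange(nz, dtype=np.float32) * sz)[None, None, :]
    # Occupancy edge scale. The Gaussian-CDF edge has pre-sampling sigma
    # edge_mm/sqrt(2); at 1.25 x the coarsest spacing the spectral energy at
    # the grid Nyquist frequency is ~1%, so flat faces that happen to align
    # with grid planes (notably in the identity pose) carry no coherent
    # aliasing that registration could mistake for motion.
    edge_mm = np.float32(1.25 * float(np.max(spec.spacing)))

    def inverse_coords(pose: RigidTransform):
        inv = pose.inverse()
        R = inv.rotation.astype(np.float32)
        t = inv.translation.astype(np.float32)
        return (
            R[0, 0] * X + R[0, 1] * Y + R[0, 2] * Z + t[0],
            R[1, 0] * X + R[1, 1] * Y + R[1, 2] * Z + t[1],
            R[2, 0] * X + R[2, 1] * Y + R[2, 2] * Z + t[2],
        )

    def occupancy(d: np.ndarray) -> np.ndarray:
        # Gaussian-CDF edge profile: infinitely smooth, so grid sampling of
        # the field is essentially alias-free (a clipped-linear ramp leaves
        # kinks whose sampling still biases registration measurably)
        return np.float32(0.5) * erfc(d / edge_mm)

    cx, cy = (np.float32(v) for v in spec.center_xy)
    z0 = np.float32(spec.bone_z0)
    zt = np.float32(spec.bone_z_top)
    ax, ay, az = (np.float32(v) for v in spec.plate_extent)

    hu = np.full(spec.volume_shape, np.float32(spec.hu_air))

    if spec.bench:
        ext_y = np.float32(spec.extent_mm[1])
        d = np.maximum(ext_y - 5.5 - Y, Y - (ext_y - 2.5)).astype(np.float32)
        w = occupancy(np.broadcast_to(d, hu.shape))
        hu += (np.float32(spec.hu_bench) - hu) * w

    xb, yb, zb = inverse_coords(scene_pose)
    dx = xb - cx
    dy = yb - cy
    rho = np.sqrt(dx * dx + dy * dy)
    d_soft = np.maximum(rho - np.float32(spec.soft_radius),
                        np.maximum(z0 - 4.0 - zb, zb - (zt + az + 2.0)))
    hu += (np.float32(spec.hu_soft) - hu) * occupancy(d_soft)
    del d_soft, rho
    s = np.clip((zb - z0) / np.float32(spec.bone_length), 0.0, 1.0)
    a_s = np.float32(spec.bone_outer_radius) * (1.0 - np.float32(spec.bone_taper) * (1.0 - s))
    b_s = a_s * np.float32(spec.bone_ellipticity)
    d_outer = (np.sqrt((dx / a_s) ** 2 + (dy / b_s) ** 2) - 1.0) * b_s
    rho_c = np.sqrt(dx * dx + (dy - np.float32(spec.canal_offset_mm)) ** 2)
    d_cort = np.maximum.reduce([
        d_outer, np.float32(spec.bone_inner_radius) - rho_c, z0 - zb, zb - zt,
    ])
    hu += (np.float32(spec.hu_cortical) - hu) * occupancy(d_cort)
    del xb, yb, zb, dx, dy, s, a_s, b_s, d_outer, rho_c, d_cort

    xi, yi, zi = inverse_coords(implant_pose)
    dxi = xi - cx
    dyi = yi - cy
    d_plate = np.maximum.reduce([
        np.abs(dxi) - ax / 2, np.abs(dyi) - ay / 2, zt - zi, zi - (zt + az),
    ])
    dys = dyi - np.float32(spec.stem_offset_mm)
    # the stem extends into the plate so that the two interiors overlap: a
    # min-union of signed distances whose boundaries merely touch leaves a
    # half-occupancy seam right through the solid metal
    d_stem = np.maximum.reduce([
        np.sqrt(dxi * dxi + dys * dys) - np.float32(spec.stem_radius),
        zt - np.float32(spec.stem_length) - zi, zi - (zt + az),
    ])
    hu += (np.float32(spec.hu_metal) - hu) * occupancy(np.minimum(d_plate, d_stem))
    del xi, yi, zi, dxi, dyi, d_plate, d_stem

    if smooth and spec.edge_sigma_voxels > 0:
        hu = gaussian_filter(hu, sigma=spec.edge_sigma_voxels, mode="nearest")
    return Volume(hu, spec.spacing)


# ---------------------------------------------------------------------------
# degradation
# ---------------------------------------------------------------------------

_STREAK_SIGMA_MM = 1.2


def degrade(volume: Volume, profile: ScannerProfile, seed: int) -> Volume:
    """Apply scanner degradation: Gaussian HU noise plus planar streaks
    through the metal centroid.  Deterministic given ``seed``; a no-op
    profile returns the input data unchanged (bit-identical)."""
    if profile.is_noop:
        return Volume(volume.data.copy(), volume.spacing, volume.origin)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    data = volume.data.astype(np.float32).copy()

    if profile.artifact_n_streaks > 0 and profile.artifact_amplitude > 0:
        metal = np.argwhere(volume.data >= 2200.0)
        if len(metal):
            c = np.asarray(volume.origin) + metal.mean(axis=0) * np.asarray(volume.spacing)
        else:
            c = np.asarray(volume.origin) + volume.extent_mm / 2
        X = volume.axis_coords(0, np.float32)[:, None, None] - np.float32(c[0])
        Y = volume.axis_coords(1, np.float32)[None, :, None] - np.float32(c[1])
        Z = volume.axis_coords(2, np.float32)[None, None, :] - np.float32(c[2])
        for k in range(profile.artifact_n_streaks):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            sign = 1.0 if k % 2 == 0 else -1.0
            amp = sign * profile.artifact_amplitude * rng.uniform(0.6, 1.0)
            d = np.float32(n[0]) * X + np.float32(n[1]) * Y + np.float32(n[2]) * Z
            data += np.float32(amp) * np.exp(np.float32(-0.5 / _STREAK_SIGMA_MM**2) * d * d)

    if profile.noise_sd > 0:
        data += rng.normal(0.0, profile.noise_sd, size=data.shape).astype(np.float32)
    return Volume(data, volume.spacing, volume.origin)


# ---------------------------------------------------------------------------
# series simulation
# ---------------------------------------------------------------------------

def simulate_series(
    spec: PhantomSpec,
    profile: ScannerProfile = NO_DEGRADATION,
    n_poses: int = 7,
    pose_magnitude: float = 2.0,
    migration: RigidTransform = RigidTransform.identity(),
    seed: int = 0,
) -> list[tuple[Volume, GroundTruth]]:
    """Simulate one same-day rescan series.

    Scan 1 is at identity pose; scans 2..n are random rigid repositionings
    with translations and rotations bounded by ``pose_magnitude`` (mm / deg).
    ``migration`` (implant relative to bone) is identical for every scan, so
    the true relative motion between any two scans of the series is zero.
    """
    if n_poses < 2:
        raise ConfigError("a series needs at least 2 scans")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_poses + 1)
    pose_rng = np.random.default_rng(children[0])
    cx, cy = spec.center_xy
    pivot = (cx, cy, (spec.bone_z0 + spec.bone_z_top) / 2)
    out: list[tuple[Volume, GroundTruth]] = []
    for k in range(n_poses):
        pose = (
            RigidTransform.identity()
            if k == 0
            else random_rigid(pose_rng, pose_magnitude, pose_magnitude, center=pivot)
        )
        scan_seed = int(children[k + 1].generate_state(1)[0] % (2**31))
        vol = degrade(rasterize_scene(spec, pose, migration), profile, scan_seed)
        out.append((vol, GroundTruth(pose, migration, scan_seed)))
    return out


def migration_pair(
    spec: PhantomSpec,
    migration: RigidTransform,
    profile: ScannerProfile = NO_DEGRADATION,
    pose_magnitude: float = 2.0,
    seed: int = 0,
) -> tuple[tuple[Volume, GroundTruth], tuple[Volume, GroundTruth]]:
    """Baseline/follow-up pair with a known injected implant migration.

    The baseline is at identity pose with zero migration; the follow-up is
    rigidly repositioned and carries ``migration`` relative to the bone, so
    the true measured relative motion equals ``migration`` exactly.
    """
    ss = np.random.SeedSequence(seed)
    c0, c1, c2 = ss.spawn(3)
    rng = np.random.default_rng(c0)
    base_seed = int(c1.generate_state(1)[0] % (2**31))
    fol_seed = int(c2.generate_state(1)[0] % (2**31))
    ident = RigidTransform.identity()
    base = degrade(rasterize_scene(spec, ident, ident), profile, base_seed)
    cx, cy = spec.center_xy
    pivot = (cx, cy, (spec.bone_z0 + spec.bone_z_top) / 2)
    pose = random_rigid(rng, pose_magnitude, pose_magnitude, center=pivot)
    fol = degrade(rasterize_scene(spec, pose, migration), profile, fol_seed)
    return (base, GroundTruth(ident, ident, base_seed)), (fol, GroundTruth(pose, migration, fol_seed))


def truth_relative_motion(baseline: GroundTruth, followup: GroundTruth) -> RigidTransform:
    """True implant-relative-to-bone motion between two scans, expressed in
    the baseline scan's world frame: ``S_b (J_f J_b^-1) S_b^-1``."""
    S = baseline.scene_pose
    rel = followup.implant_migration @ baseline.implant_migration.inverse()
    return S @ rel @ S.inverse()


# ---------------------------------------------------------------------------
# implant point model
# ---------------------------------------------------------------------------

def implant_point_model(spec: PhantomSpec, step_mm: float = 2.0):
    """Deterministic surface point model of the implant (the CAD stand-in).

    Points are in scene (identity-pose) world coordinates.  The first five
    points are the labeled feature points — medial, lateral, anterior and
    posterior edge midpoints of the baseplate and the stem tip — followed by
    regular samples of the plate faces and stem surface labeled 'surface'.
    """
    from .register import PointSet  # local import to avoid a cycle

    cx, cy = spec.center_xy
    zt = spec.bone_z_top
    ax, ay, az = spec.plate_extent
    zm = zt + az / 2

    features = np.array([
        [cx + ax / 2, cy, zm],          # medial  (+x)
        [cx - ax / 2, cy, zm],          # lateral (-x)
        [cx, cy - ay / 2, zm],          # anterior (-y)
        [cx, cy + ay / 2, zm],          # posterior (+y)
        [cx, cy + spec.stem_offset_mm, zt - spec.stem_length],  # tip
    ])

    pts: list[np.ndarray] = []
    nx = max(int(np.ceil(ax / step_mm)) + 1, 2)
    ny = max(int(np.ceil(ay / step_mm)) + 1, 2)
    gx = np.linspace(-ax / 2, ax / 2, nx)
    gy = np.linspace(-ay / 2, ay / 2, ny)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    for z in (zt, zt + az):  # plate bottom and top faces
        pts.append(np.column_stack([cx + GX.ravel(), cy + GY.ravel(), np.full(GX.size, z)]))
    gz = np.linspace(zt, zt + az, max(int(np.ceil(az / step_mm)) + 1, 2))
    for x in (-ax / 2, ax / 2):  # plate side faces
        GY2, GZ2 = np.meshgrid(gy, gz, indexing="ij")
        pts.append(np.column_stack([np.full(GY2.size, cx + x), cy + GY2.ravel(), GZ2.ravel()]))
    for y in (-ay / 2, ay / 2):
        GX2, GZ2 = np.meshgrid(gx, gz, indexing="ij")
        pts.append(np.column_stack([cx + GX2.ravel(), np.full(GX2.size, cy + y), GZ2.ravel()]))
    # stem: rings of points along the cylinder
    n_rings = max(int(np.ceil(spec.stem_length / step_mm)) + 1, 2)
    n_ang = max(int(np.ceil(2 * np.pi * spec.stem_radius / step_mm)), 6)
    theta = np.linspace(0, 2 * np.pi, n_ang, endpoint=False)
    for z in np.linspace(zt - spec.stem_length, zt, n_rings):
        pts.append(np.column_stack([
            cx + spec.stem_radius * np.cos(theta),
            cy + spec.stem_offset_mm + spec.stem_radius * np.sin(theta),
            np.full(n_ang, z),
        ]))
    surface = np.vstack(pts)
    points = np.vstack([features, surface])
    labels = list(FEATURE_LABELS) + ["surface"] * len(surface)
    return PointSet(points=points, labels=labels)
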