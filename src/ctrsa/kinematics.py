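"""Anatomical coordinate frames and migration outcome metrics.

Motions are expressed in an anatomical frame built from points marked on the
baseline scan (x medial, y proximal, z anterior for a right-sided knee) and
summarized by the standard radiostereometric outcome set: per-axis
translations (mm) and rotations (degrees), total translation TT and total
rotation TR (Euclidean norms), and maximum total point motion (MTPM) — the
displacement of the implant point that moved most, disregarding location.

Euler angles use the extrinsic x-y-z convention (R = Rz·Ry·Rx); per-axis
rotation values are convention dependent, whereas TT, TR and MTPM are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .register import PointSet
from .transforms import RigidTransform

BASEPLATE_LABELS = ("medial", "lateral", "anterior", "posterior")
FEATURE_LABELS = BASEPLATE_LABELS + ("tip",)


@dataclass(frozen=True)
class CoordinateFrame:
    """Right-handed orthonormal frame: origin plus unit axes (mm, world)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float).reshape(3))
        Q = self.rotation
        if not np.allclose(Q @ Q.T, np.eye(3), atol=1e-9):
            raise DataError("frame axes are not orthonormal")
        if np.linalg.det(Q) < 0:
            raise DataError("frame is left-handed")

    @property
    def rotation(self) -> np.ndarray:
        """World-from-frame rotation (axes as columns)."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def as_transform(self) -> RigidTransform:
        return RigidTransform(self.rotation, self.origin)


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise DataError(f"cannot normalize {what}: zero length")
    return v / n


def build_frame(marked_points: PointSet, side: str = "right") -> CoordinateFrame:
    """Anatomical frame from the labeled baseplate feature points.

    x = unit(medial - lateral) (medial positive; negated for left knees),
    provisional z points toward the anterior feature, y = z × x
    (proximal positive), z = x × y.  Origin is the centroid of the four
    baseplate feature points.
    """
    med = marked_points.select("medial").mean(axis=0)
    lat = marked_points.select("lateral").mean(axis=0)
    ant = marked_points.select("anterior").mean(axis=0)
    base = np.vstack([marked_points.select(l) for l in BASEPLATE_LABELS])
    origin = base.mean(axis=0)

    x = _unit(med - lat, "medial-lateral axis")
    if side == "left":
        x = -x
    elif side != "right":
        raise DataError("side must be 'right' or 'left'")
    z_prov = ant - origin
    y = np.cross(z_prov, x)
    if np.linalg.norm(y) < 1e-9:
        raise DataError("marked points are collinear; cannot build a frame")
    y = _unit(y, "proximal axis")
    z = np.cross(x, y)
    return CoordinateFrame(origin, x, y, z)


def express_in_frame(motion: RigidTransform, frame: CoordinateFrame) -> RigidTransform:
    """Conjugate a world-coordinate motion into frame coordinates:
    ``M' = F⁻¹ ∘ M ∘ F`` — translations are then reported at the frame
    origin, along the anatomical axes."""
    F = frame.as_transform()
    return F.inverse() @ motion @ F


def decompose(motion: RigidTransform) -> tuple[float, float, float, float, float, float]:
    """(Tx, Ty, Tz) in mm and extrinsic x-y-z Euler angles (Rx, Ry, Rz) in
    degrees.  Errors near gimbal lock (|Ry| > 89°), far outside the
    physiological migration range."""
    rx, ry, rz = motion.euler_deg()
    if abs(ry) > 89.0:
        raise DataError("rotation too close to gimbal lock (|Ry| > 89 deg)")
    tx, ty, tz = motion.translation
    return float(tx), float(ty), float(tz), float(rx), float(ry), float(rz)


def compose(tx, ty, tz, rx, ry, rz) -> RigidTransform:
    """Inverse of :func:`decompose` (useful for round-trip checks)."""
    return RigidTransform.from_euler((rx, ry, rz), (tx, ty, tz))


def total_translation(tx: float, ty: float, tz: float) -> float:
    """TT: Euclidean norm of the translation components (3-D Pythagoras)."""
    return float(np.sqrt(tx * tx + ty * ty + tz * tz))


def total_rotation(rx: float, ry: float, rz: float) -> float:
    """TR: Euclidean norm of the per-axis rotation components, degrees."""
    return float(np.sqrt(rx * rx + ry * ry + rz * rz))


def mtpm(points: PointSet, motion: RigidTransform) -> tuple[float, np.ndarray]:
    """Maximum total point motion over a point set.

    Returns ``(max displacement, location of the maximizing point)``; ties
    are broken by first index.
    """
    if len(points) == 0:
        raise DataError("empty point set")
    disp = np.linalg.norm(motion.apply(points.points) - points.points, axis=1)
    i = int(np.argmax(disp))
    return float(disp[i]), points.points[i].copy()


def feature_point_mtpm(feature_points: PointSet, motion: RigidTransform) -> float:
    """MTPM restricted to the five labeled implant feature points (the
    'maximum total translation' flavour used with selected points)."""
    pts = np.vstack([feature_points.select(l) for l in FEATURE_LABELS])
    disp = np.linalg.norm(motion.apply(pts) - pts, axis=1)
    return float(disp.max())


@dataclass
class MigrationResult:
    """Outcome metrics for one baseline/follow-up comparison."""

    pair_id: str
    Tx: float
    Ty: float
    Tz: float
    Rx: float
    Ry: float
    Rz: float
    TT: float
    TR: float
    MTPM_all: float
    MTPM_all_point: tuple[float, float, float]
    MTPM_feature: float
    align_object: str = ""
    mode: str = ""
    converged: bool = True
    qc: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "pair_id": self.pair_id,
            "Tx_mm": self.Tx, "Ty_mm": self.Ty, "Tz_mm": self.Tz,
            "Rx_deg": self.Rx, "Ry_deg": self.Ry, "Rz_deg": self.Rz,
            "TT_mm": self.TT, "TR_deg": self.TR,
            "MTPM_all_mm": self.MTPM_all,
            "MTPM_feature_mm": self.MTPM_feature,
            "align_object": self.align_object,
            "mode": self.mode,
            "converged": self.converged,
        }
        return row


def migration_result(
    pair_id: str,
    motion_world: RigidTransform,
    frame: CoordinateFrame,
    implant_points: PointSet,
    feature_points: PointSet,
    **meta,
) -> MigrationResult:
    """Assemble the full outcome set for one pair.

    MTPM is evaluated over the union of the implant model surface points and
    the feature points (so the feature subset can never exceed it); per-axis
    values are reported in the anatomical frame.
    """
    Mf = express_in_frame(motion_world, frame)
    tx, ty, tz, rx, ry, rz = decompose(Mf)
    allpts = PointSet(np.vstack([implant_points.points, feature_points.points]))
    m_all, m_pt = mtpm(allpts, motion_world)
    m_feat = feature_point_mtpm(feature_points, motion_world)
    return MigrationResult(
        pair_id=pair_id,
        Tx=tx, Ty=ty, Tz=tz, Rx=rx, Ry=ry, Rz=rz,
        TT=total_translation(tx, ty, tz),
        TR=total_rotation(rx, ry, rz),
        MTPM_all=m_all,
        MTPM_all_point=tuple(float(v) for v in m_pt),
        MTPM_feature=m_feat,
        **meta,
    )
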