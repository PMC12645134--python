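"""Two-step rigid registration of serial CT volumes.

Step one is a coarse initial alignment using the align object (centroid
matching plus a deterministic coarse search over Euler angles, refined by a
short masked gray-value optimization).  Step two registers the reference
(bone) and migrating (implant) objects independently, in one of two modes:

* gray-value mode — normalized cross-correlation over the voxels of the
  (dilated) object mask, sampled with cubic B-spline interpolation and
  optimized by L-BFGS with the analytic gradient (a smoothed coarse stage
  first, for capture range);
* surface mode — trimmed iterative-closest-point alignment of surface point
  sets extracted from the objects (point-to-plane where normals exist).

All transforms map baseline world coordinates to follow-up world coordinates,
i.e. they are the motion of the object between the two scans.  The implant's
motion relative to the bone is then the composition
``bone_motion⁻¹ ∘ implant_motion`` (:func:`relative_motion`), which cancels
any whole-scene repositioning exactly.

Because the internals of commercial CT-RSA systems are not published, the
metric, optimizer and stopping rules here are documented stand-ins, not
claimed identical to any product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter, map_coordinates, spline_filter
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .errors import DataError
from .segment import SegmentModel, largest_component
from .transforms import RigidTransform
from .volume import Volume, mask_bbox


@dataclass
class PointSet:
    """World-coordinate (mm) points with optional labels and unit normals."""

    points: np.ndarray
    labels: list | None = None
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        if self.labels is not None and len(self.labels) != len(self.points):
            raise DataError("labels must match points one-to-one")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, float).reshape(-1, 3)
            if len(self.normals) != len(self.points):
                raise DataError("normals must match points one-to-one")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, label: str) -> np.ndarray:
        if self.labels is None:
            raise DataError("point set has no labels")
        idx = [i for i, l in enumerate(self.labels) if l == label]
        if not idx:
            raise DataError(f"no point labeled {label!r}")
        return self.points[idx]

    def transformed(self, T: RigidTransform) -> "PointSet":
        n = None if self.normals is None else self.normals @ T.rotation.T
        return PointSet(T.apply(self.points), self.labels, n)


@dataclass
class RegistrationResult:
    transform: RigidTransform
    similarity_final: float
    n_iterations: int
    converged: bool
    mode: str = ""


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def _sample_volume(volume: Volume, world_pts: np.ndarray, cval: float = -2000.0) -> np.ndarray:
    idx = (world_pts - np.asarray(volume.origin)) / np.asarray(volume.spacing)
    return map_coordinates(volume.data, idx.T, order=1, mode="constant", cval=cval)


def _kabsch(src: np.ndarray, tgt: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit mapping src onto tgt (SVD, reflection-safe)."""
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - cs).T @ (tgt - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, ct - R @ cs)


# ---------------------------------------------------------------------------
# initial alignment
# ---------------------------------------------------------------------------

def initial_align(
    baseline: Volume,
    followup: Volume,
    align_obj: SegmentModel,
    *,
    threshold: float | None = None,
    followup_mask: np.ndarray | None = None,
    angle_range_deg: float = 12.0,
    angle_step_deg: float = 4.0,
    refine: bool = True,
    n_samples: int = 4000,
) -> RegistrationResult:
    """Coarse rigid alignment of baseline to follow-up via the align object.

    The align object's thresholded counterpart is found in the follow-up;
    centroids are matched, the three Euler angles are searched on a coarse
    deterministic grid (masked NCC score), and the best pose is refined by a
    short low-resolution gray-value optimization.  Intended accuracy is on
    the voxel scale — enough to put the final registrations in capture range.
    """
    if baseline.data.shape == followup.data.shape and np.array_equal(
        baseline.data, followup.data
    ):
        # degenerate but legitimate case (repeat analysis of one scan):
        # identical volumes are already aligned
        return RegistrationResult(
            RigidTransform.identity(), 1.0, 0, True, mode="initial"
        )
    if threshold is None:
        threshold = align_obj.threshold_from_provenance()
    if threshold is None:
        raise DataError("no threshold given and none recorded in the align object")
    if followup_mask is None:
        raw = followup.data >= threshold
        if not raw.any():
            raise DataError("follow-up has no voxels above the align threshold")
        followup_mask = largest_component(
            SegmentModel(raw, followup.spacing, followup.origin, "align"), 26
        ).mask

    c_b = align_obj.centroid_world()
    idx_f = np.argwhere(followup_mask)
    c_f = np.asarray(followup.origin) + idx_f.mean(axis=0) * np.asarray(followup.spacing)

    idx_b = np.argwhere(align_obj.mask)
    stride = max(1, len(idx_b) // n_samples)
    idx_b = idx_b[::stride]
    pts = np.asarray(align_obj.origin) + idx_b * np.asarray(align_obj.spacing)
    vals = baseline.data[tuple(idx_b.T)]

    half = int(round(angle_range_deg / angle_step_deg))
    grid = np.arange(-half, half + 1) * angle_step_deg
    best_score, best_T, n_evals = -np.inf, None, 0
    for ax_deg in grid:
        for ay_deg in grid:
            for az_deg in grid:
                R = RigidTransform.from_euler((ax_deg, ay_deg, az_deg)).rotation
                moved = (pts - c_b) @ R.T + c_f
                score = _ncc(vals, _sample_volume(followup, moved))
                n_evals += 1
                if score > best_score:
                    best_score = score
                    best_T = RigidTransform(R, c_f - R @ c_b)

    result = RegistrationResult(best_T, best_score, n_evals, True, mode="initial")
    if refine and best_score < 1.0 - 1e-9:
        refined = grayvalue_register(
            baseline, followup, align_obj, best_T,
            n_samples=8000, stages=("coarse",), max_iterations=60,
        )
        if refined.converged or refined.similarity_final < -abs(best_score):
            result = RegistrationResult(
                refined.transform, refined.similarity_final,
                n_evals + refined.n_iterations, True, mode="initial",
            )
    return result


# ---------------------------------------------------------------------------
# gray-value registration
# ---------------------------------------------------------------------------

def _rotation_and_derivs(angles_rad):
    """R = Rz@Ry@Rx (extrinsic x-y-z) and the three dR/dangle matrices."""
    ax, ay, az = angles_rad
    ca, sa = np.cos(ax), np.sin(ax)
    cb, sb = np.cos(ay), np.sin(ay)
    cc, sc = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    dRx = np.array([[0, 0, 0], [0, -sa, -ca], [0, ca, -sa]])
    dRy = np.array([[-sb, 0, cb], [0, 0, 0], [-cb, 0, -sb]])
    dRz = np.array([[-sc, -cc, 0], [cc, -sc, 0], [0, 0, 0]])
    return Rz @ Ry @ Rx, (Rz @ Ry @ dRx, Rz @ dRy @ Rx, dRz @ Ry @ Rx)


def _ncc_objective(fvals, pts, center, arr, grads, origin, spacing, lever, order):
    """Negative masked NCC and its analytic gradient in the 6 pose
    parameters (Euler angles about ``center``, scaled by ``lever`` so the
    optimizer sees comparable mm-like magnitudes, plus translation)."""
    fh = fvals - fvals.mean()
    fn = np.linalg.norm(fh)
    v = pts - center
    origin = np.asarray(origin)
    spacing = np.asarray(spacing)

    def objective(p):
        R, dRs = _rotation_and_derivs(p[:3] / lever)
        q = v @ R.T + center + p[3:]
        idx = ((q - origin) / spacing).T
        m = map_coordinates(arr, idx, order=order, prefilter=False, mode="nearest")
        mm = m - m.mean()
        mn = np.linalg.norm(mm)
        if fn == 0 or mn == 0:
            return 1.0, np.zeros(6)
        ncc = float(fh @ mm) / (fn * mn)
        dncc_dm = fh / (fn * mn) - mm * (ncc / mn**2)
        g = np.stack(
            [map_coordinates(grads[a], idx, order=1, mode="nearest") for a in range(3)],
            axis=1,
        )
        G = g * dncc_dm[:, None]
        grad = np.empty(6)
        for k in range(3):
            grad[k] = np.einsum("ab,na,nb->", dRs[k], G, v) / lever
        grad[3:] = G.sum(axis=0)
        return -ncc, -grad

    return objective


def grayvalue_register(
    baseline: Volume,
    followup: Volume,
    obj: SegmentModel,
    init: RigidTransform,
    *,
    n_samples: int = 30000,
    stages: tuple = ("coarse", "fine"),
    coarse_sigma_voxels: float = 2.0,
    max_iterations: int = 200,
    crop_margin_mm: float = 8.0,
) -> RegistrationResult:
    """Rigid transform maximizing normalized cross-correlation over the
    voxels of ``obj``'s mask.

    The metric samples the mask voxels of the baseline (uniformly strided to
    ``n_samples``) in the follow-up via cubic B-spline interpolation — linear
    interpolation of sharp edges biases the NCC optimum by a noticeable
    fraction of a voxel — and is optimized by L-BFGS with the analytic
    gradient, optionally preceded by the same optimization on
    Gaussian-smoothed copies (the ``coarse`` stage, which widens the capture
    range to several mm / degrees).  Deterministic given inputs; ``init``
    must be within the capture range (roughly 5 mm / 5 degrees).
    Non-convergence at the iteration cap is reported via ``converged=False``,
    not an exception.
    """
    if not obj.mask.any():
        raise DataError("object mask is empty")
    spacing = np.asarray(obj.spacing)
    idx_all = np.argwhere(obj.mask)
    stride = max(1, int(np.ceil(len(idx_all) / n_samples)))
    idx = idx_all[::stride]
    pts = np.asarray(obj.origin) + idx * spacing
    center = idx_all.mean(axis=0) * spacing + np.asarray(obj.origin)
    lever = float(np.linalg.norm(pts - center, axis=1).max())

    # follow-up region the samples can land in, with capture margin
    q0 = init.apply(pts)
    lo_w = q0.min(axis=0) - crop_margin_mm
    hi_w = q0.max(axis=0) + crop_margin_mm
    lo_i = np.floor((lo_w - followup.origin) / followup.spacing).astype(int)
    hi_i = np.ceil((hi_w - followup.origin) / followup.spacing).astype(int) + 1
    mov = followup.crop(np.maximum(lo_i, 0), np.minimum(hi_i, followup.shape))
    mov_data = mov.data.astype(np.float64)

    # initial parameters: rotation about the mask centroid
    angles0 = np.deg2rad(init.euler_deg())
    t0 = init.apply(center) - center
    p = np.concatenate([angles0 * lever, t0])

    total_iter = 0
    result = None
    for stage in stages:
        if stage == "coarse":
            fvol_lo, fvol_hi = mask_bbox(obj.mask)
            pad = int(np.ceil(4 * coarse_sigma_voxels))
            fixed_crop = baseline.crop(fvol_lo, fvol_hi, margin=pad)
            fixed_smooth = gaussian_filter(fixed_crop.data.astype(np.float64),
                                           coarse_sigma_voxels)
            rel = idx - np.maximum(fvol_lo - pad, 0)
            fvals = fixed_smooth[tuple(rel.T)]
            arr = gaussian_filter(mov_data, coarse_sigma_voxels)
            order = 1
        else:
            fvals = baseline.data[tuple(idx.T)].astype(np.float64)
            arr = spline_filter(mov_data, order=3)
            order = 3
        grads = np.gradient(arr, *mov.spacing)
        objective = _ncc_objective(
            fvals, pts, center, arr, grads, mov.origin, mov.spacing, lever, order
        )
        res = minimize(
            objective, p, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iterations, "ftol": 1e-13, "gtol": 1e-9},
        )
        p = res.x
        total_iter += int(res.nit)
        result = res

    R, _ = _rotation_and_derivs(p[:3] / lever)
    T = RigidTransform(R, center + p[3:] - R @ center).orthonormalized()
    # a line-search abort at a stationary point is still convergence
    converged = bool(result.success) or float(np.linalg.norm(result.jac)) < 1e-6
    return RegistrationResult(
        T,
        float(result.fun),  # negative NCC: lower is better
        total_iter,
        converged,
        mode="grayvalue",
    )


# ---------------------------------------------------------------------------
# surface extraction and ICP
# ---------------------------------------------------------------------------

def extract_surface_points(
    model: SegmentModel,
    max_points: int | None = 5000,
    *,
    volume: Volume | None = None,
    level: float | None = None,
) -> PointSet:
    """Surface point set of a segment, in world coordinates.

    Without ``volume``, vertices come from the 0.5-level marching-cubes
    isosurface of the binary mask (accurate to about half a voxel).  With
    ``volume``, vertices are taken from the HU isosurface at the segment's
    threshold (sub-voxel accurate thanks to partial-volume smoothing) and
    filtered to lie near the mask.  Points are uniformly subsampled to at
    most ``max_points``.
    """
    if not model.mask.any():
        raise DataError("segment mask is empty")
    lo, hi = mask_bbox(model.mask)
    pad = 2
    lo2 = np.maximum(lo - pad, 0)
    hi2 = np.minimum(hi + pad, model.mask.shape)
    sub_mask = model.mask[lo2[0]:hi2[0], lo2[1]:hi2[1], lo2[2]:hi2[2]]
    spacing = np.asarray(model.spacing)
    base = np.asarray(model.origin) + lo2 * spacing

    if volume is not None:
        if level is None:
            level = model.threshold_from_provenance()
        if level is None:
            raise DataError("no iso level given and none recorded in provenance")
        sub = volume.data[lo2[0]:hi2[0], lo2[1]:hi2[1], lo2[2]:hi2[2]].astype(np.float64)
        if not (sub.min() < level <= sub.max()):
            raise DataError("iso level is outside the sub-volume's value range")
        verts, _, normals, _ = marching_cubes(sub, level=float(level), spacing=tuple(spacing))
        # Newton refinement along the gradient: marching cubes interpolates
        # the crossing linearly between slices, which leaves phase-dependent
        # offsets of flat faces on the order of a tenth of a voxel
        coeff = spline_filter(sub, order=3)
        grads = np.gradient(sub, *spacing)
        for _ in range(2):
            idxv = (verts / spacing).T
            val = map_coordinates(coeff, idxv, order=3, prefilter=False, mode="nearest")
            g = np.stack(
                [map_coordinates(grads[a], idxv, order=1, mode="nearest") for a in range(3)],
                axis=1,
            )
            g2 = np.einsum("ij,ij->i", g, g)
            step = (float(level) - val) / np.maximum(g2, 1e-9)
            verts = verts + np.clip(step[:, None] * g, -0.6 * spacing, 0.6 * spacing)
        near = binary_dilation(sub_mask, np.ones((3, 3, 3), bool), iterations=2)
        keep = map_coordinates(
            near.astype(np.float32), (verts / spacing).T, order=1, mode="constant"
        ) > 0.25
        verts = verts[keep]
        normals = normals[keep]
        if len(verts) == 0:
            raise DataError("no isosurface vertices near the mask")
    else:
        padded = np.pad(sub_mask.astype(np.float32), 1)
        verts, _, normals, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
        verts = verts - spacing  # undo the one-voxel pad

    world = verts + base
    if max_points is not None and len(world) > max_points:
        sel = np.unique(np.linspace(0, len(world) - 1, max_points).astype(int))
        world = world[sel]
        normals = normals[sel]
    return PointSet(points=world, normals=normals)


def _check_nondegenerate(points: np.ndarray) -> None:
    if len(points) < 3:
        raise DataError("need at least 3 points for a rigid fit")
    s = np.linalg.svd(points - points.mean(axis=0), compute_uv=False)
    if s[2] <= 1e-8 * max(s[0], 1.0):
        raise DataError("degenerate point geometry (rank < 3 covariance)")


def surface_register(
    source: PointSet,
    target: PointSet,
    init: RigidTransform = RigidTransform.identity(),
    *,
    trim_fraction: float = 0.1,
    max_iterations: int = 200,
    tol: float = 1e-7,
    max_source_points: int = 6000,
) -> RegistrationResult:
    """Trimmed iterative-closest-point rigid fit of ``source`` onto ``target``.

    Each iteration matches every source point to its nearest target point
    and discards the worst ``trim_fraction`` of matches.  When the target
    carries surface normals the rigid update minimizes the point-to-plane
    residuals (a linearized 6-DOF solve); otherwise it is the classic
    point-to-point SVD fit.  Point-to-plane is strongly preferred for
    surfaces sampled on a grid: point-to-point correspondences inherit the
    target's discrete sampling pattern as a systematic bias, while distances
    along the local surface normal do not.  Stops when the update norm falls
    below ``tol`` or at the iteration cap.  The source is subsampled to
    ``max_source_points``; the target is used at full density.
    """
    src = source.points
    if len(src) > max_source_points:
        sel = np.unique(np.linspace(0, len(src) - 1, max_source_points).astype(int))
        src = src[sel]
    tgt = target.points
    _check_nondegenerate(src)
    _check_nondegenerate(tgt)
    use_planes = target.normals is not None
    tree = cKDTree(tgt)
    T = init
    n_keep = max(3, int(np.ceil(len(src) * (1.0 - trim_fraction))))
    converged = False
    rms = np.inf
    best_rms = np.inf
    stalled = 0
    it = 0
    for it in range(1, max_iterations + 1):
        moved = T.apply(src)
        dist, nn = tree.query(moved)
        if use_planes:
            n = target.normals[nn]
            r = np.einsum("ij,ij->i", moved - tgt[nn], n)
            keep = np.argsort(np.abs(r))[:n_keep]
            p, nk, rk = moved[keep], n[keep], r[keep]
            # solve A x = b for the twist x = (omega, v), linearized update
            A = np.hstack([np.cross(p, nk), nk])
            x, *_ = np.linalg.lstsq(A, -rk, rcond=None)
            from scipy.spatial.transform import Rotation as _Rot

            dR = _Rot.from_rotvec(x[:3]).as_matrix()
            T_new = RigidTransform(dR, x[3:]) @ T
            rms = float(np.sqrt(np.mean(rk**2)))
            delta = float(np.linalg.norm(x))
        else:
            keep = np.argsort(dist)[:n_keep]
            T_new = _kabsch(src[keep], tgt[nn[keep]])
            rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
            delta = np.linalg.norm(T_new.rotation - T.rotation) + np.linalg.norm(
                T_new.translation - T.translation
            )
        T = T_new.orthonormalized()
        if delta < tol:
            converged = True
            break
        # correspondence flips can keep the update norm oscillating at the
        # numerical floor; a stalled residual is convergence too
        if rms >= best_rms - 1e-10:
            stalled += 1
            if stalled >= 5:
                converged = True
                break
        else:
            best_rms = rms
            stalled = 0
    return RegistrationResult(T, rms, it, converged, mode="surface")


def fit_model_to_mask(
    model_points: PointSet,
    implant_mask: SegmentModel,
    *,
    volume: Volume | None = None,
) -> RigidTransform:
    """Register an implant point model onto a segmented implant mask.

    Initialization matches centroids and principal axes (testing the four
    proper sign combinations and keeping the best-scoring one), then a
    trimmed ICP onto the mask's surface points does the fine fit.
    """
    if not implant_mask.mask.any():
        raise DataError("implant mask is empty")
    surf = extract_surface_points(implant_mask, 4000, volume=volume)
    src = model_points.points
    _check_nondegenerate(src)
    tgt = surf.points
    c_s, c_t = src.mean(axis=0), tgt.mean(axis=0)

    def _axes(pts, c):
        cov = np.cov((pts - c).T)
        _, U = np.linalg.eigh(cov)
        U = U[:, ::-1]  # descending variance
        if np.linalg.det(U) < 0:
            U[:, 2] = -U[:, 2]
        return U

    U_m, U_t = _axes(src, c_s), _axes(tgt, c_t)
    tree = cKDTree(tgt)
    probe = src[:: max(1, len(src) // 400)]
    # Candidate initializations: centroid match combined with every proper
    # signed permutation of the principal axes (axis order and sign are both
    # ambiguous when eigenvalues are close, and surface vertex density can
    # reorder them relative to the model), plus the no-rotation hypothesis.
    # The best few by probe score are refined by ICP and the lowest-residual
    # fit wins — a rigid fit cannot escape a wrong quadrant on its own.
    from itertools import permutations

    candidates = [RigidTransform(np.eye(3), c_t - c_s)]
    for perm in permutations(range(3)):
        P = np.zeros((3, 3))
        P[range(3), perm] = 1.0
        for signs in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
            Q = P * np.asarray(signs)
            if np.linalg.det(Q) < 0:
                continue
            R = U_t @ Q @ U_m.T
            candidates.append(RigidTransform(R, c_t - R @ c_s))
    scores = [float(tree.query(c.apply(probe))[0].mean()) for c in candidates]
    best_res = None
    for k in np.argsort(scores)[:3]:
        res = surface_register(model_points, surf, candidates[k])
        if best_res is None or res.similarity_final < best_res.similarity_final:
            best_res = res
    return best_res.transform


# ---------------------------------------------------------------------------
# relative motion
# ---------------------------------------------------------------------------

def relative_motion(
    bone_reg: RegistrationResult, implant_reg: RegistrationResult
) -> RigidTransform:
    """Implant motion relative to the bone, in baseline world coordinates:
    ``(bone transform)⁻¹ ∘ (implant transform)``.  Any rigid repositioning of
    the whole follow-up scene cancels algebraically."""
    if not (bone_reg.converged and implant_reg.converged):
        warnings.warn("relative motion computed from an unconverged registration")
    return bone_reg.transform.inverse() @ implant_reg.transform
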