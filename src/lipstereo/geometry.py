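"""Camera models, DLT resectioning and stereo triangulation.

The toolkit measures lip kinematics in metric millimetres from two
synchronized video cameras.  This module supplies the geometric core:

* :class:`CameraModel` — a pinhole camera with radial/tangential distortion
  (k1, k2, p1, p2) and a rigid world→camera pose ``(R, t)``.
* :class:`StereoRig` — a calibrated pair of cameras.  The world frame is
  anchored to the left camera (``left.R = I``, ``left.t = 0``), so all 3D
  outputs are expressed in the left-camera frame in millimetres.  Lip
  aperture is a Euclidean distance and therefore invariant to this choice.
* :func:`resect_dlt` — normalized direct-linear-transformation estimation of
  a 3×4 projection matrix from 3D–2D correspondences (the calibration stage;
  corner detection itself is out of scope, the module consumes
  correspondences).
* :func:`triangulate` — two-view DLT triangulation of undistorted,
  normalized observations.

Pixel conventions: 0-based coordinates, origin at the top-left image corner,
x rightward, y downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import scipy.linalg

from .errors import (
    BehindCameraError,
    ConvergenceError,
    DegenerateGeometryError,
    InvalidModelError,
)

__all__ = [
    "CameraModel",
    "StereoRig",
    "Correspondence",
    "projection_matrix",
    "normalize_projection",
    "project",
    "project_homogeneous",
    "undistort_points",
    "resect_dlt",
    "decompose_projection",
    "triangulate",
    "reprojection_error",
    "projection_reprojection_error",
]

_ORTHONORMALITY_TOL = 1e-9


def _as_matrix(value, shape, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != shape:
        raise InvalidModelError(f"{name} must have shape {shape}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidModelError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera with a 4-parameter distortion model.

    Parameters
    ----------
    fx, fy : float
        Focal lengths in pixels; must be positive.
    cx, cy : float
        Principal point in pixels.
    dist : tuple of 4 floats
        Distortion coefficients ``(k1, k2, p1, p2)`` applied to normalized
        image coordinates: two radial and two tangential terms.  Higher-order
        terms are deliberately excluded — the intended regime is a
        low-distortion rectilinear ("linear") lens, where the 4-parameter
        model keeps the fixed-point inversion well conditioned.
    R : (3, 3) array
        World→camera rotation; orthonormal with determinant +1.
    t : (3,) array
        World→camera translation in millimetres.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    dist: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        for name in ("fx", "fy", "cx", "cy"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InvalidModelError(f"{name} is not finite")
        if self.fx <= 0 or self.fy <= 0:
            raise InvalidModelError("focal lengths must be positive")
        d = tuple(float(x) for x in self.dist)
        if len(d) != 4 or not all(np.isfinite(x) for x in d):
            raise InvalidModelError("dist must be 4 finite coefficients (k1,k2,p1,p2)")
        object.__setattr__(self, "dist", d)
        R = _as_matrix(self.R, (3, 3), "R")
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHONORMALITY_TOL):
            raise InvalidModelError("R is not orthonormal")
        if np.linalg.det(R) < 0:
            raise InvalidModelError("R must have determinant +1")
        t = _as_matrix(self.t, (3,), "t")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)

    @property
    def K(self) -> np.ndarray:
        """Upper-triangular intrinsic matrix."""
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates (mm): ``-R.T @ t``."""
        return -self.R.T @ self.t


@dataclass(frozen=True)
class StereoRig:
    """Calibrated stereo pair; the left camera defines the world frame.

    All triangulated coordinates are millimetres in the left-camera frame.
    A rig whose cameras share a center carries no depth information and is
    rejected as degenerate.
    """

    left: CameraModel
    right: CameraModel

    def __post_init__(self):
        if not np.allclose(self.left.R, np.eye(3), atol=1e-9) or not np.allclose(
            self.left.t, 0.0, atol=1e-9
        ):
            raise InvalidModelError(
                "the left camera anchors the world frame (left.R = I, left.t = 0)"
            )
        if self.baseline_mm <= 1e-9:
            raise DegenerateGeometryError(
                "zero-baseline rig: the two cameras coincide, rays are parallel"
            )

    @property
    def baseline_mm(self) -> float:
        return float(np.linalg.norm(self.right.center - self.left.center))


class Correspondence(NamedTuple):
    """A single 3D-world / 2D-image pairing used for resectioning."""

    world: tuple[float, float, float]
    image: tuple[float, float]
    camera_id: str = ""


def projection_matrix(cam: CameraModel) -> np.ndarray:
    """Return the 3×4 pinhole projection matrix ``K @ [R | t]``.

    Distortion is *not* folded in: the matrix describes the ideal pinhole
    part only, which is what the DLT triangulation consumes after
    observations have been undistorted.
    """
    return cam.K @ np.hstack([cam.R, cam.t[:, None]])


def normalize_projection(P: np.ndarray) -> np.ndarray:
    """Apply the package's projection-matrix scale convention.

    Projection matrices are homogeneous; for exact comparison we fix the
    scale to Frobenius norm 1 and the sign so that the determinant of the
    left 3×3 block is positive.
    """
    P = np.asarray(P, dtype=float)
    if P.shape != (3, 4):
        raise InvalidModelError(f"projection matrix must be 3x4, got {P.shape}")
    n = np.linalg.norm(P)
    if n == 0 or not np.isfinite(n):
        raise InvalidModelError("projection matrix is zero or non-finite")
    P = P / n
    d = np.linalg.det(P[:, :3])
    if d == 0:
        raise DegenerateGeometryError("left 3x3 block of projection matrix is singular")
    if d < 0:
        P = -P
    return P


def _apply_distortion(xy: np.ndarray, dist) -> np.ndarray:
    """Distort normalized image coordinates (vectorized over leading axes)."""
    k1, k2, p1, p2 = dist
    x = xy[..., 0]
    y = xy[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2 * r2
    xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
    yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
    return np.stack([xd, yd], axis=-1)


def project(cam: CameraModel, points) -> np.ndarray:
    """Project world points (mm) to pixel coordinates.

    Applies the rigid world→camera transform, checks positive depth,
    perspective-divides, applies the distortion polynomial on normalized
    coordinates, and maps through the intrinsics.

    Parameters
    ----------
    points : array-like, shape (..., 3)

    Returns
    -------
    ndarray, shape (..., 2) — pixel coordinates.
    """
    pts = np.asarray(points, dtype=float)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 3 or not np.all(np.isfinite(pts)):
        raise InvalidModelError("points must be finite with shape (..., 3)")
    pc = pts @ cam.R.T + cam.t
    z = pc[..., 2]
    if np.any(z <= 0):
        raise BehindCameraError(
            f"{int(np.count_nonzero(z <= 0))} point(s) have non-positive depth"
        )
    xy = pc[..., :2] / z[..., None]
    xyd = _apply_distortion(xy, cam.dist)
    px = np.empty_like(xyd)
    px[..., 0] = cam.fx * xyd[..., 0] + cam.cx
    px[..., 1] = cam.fy * xyd[..., 1] + cam.cy
    return px[0] if squeeze else px


def project_homogeneous(P: np.ndarray, points) -> np.ndarray:
    """Project points through a raw 3×4 matrix (no distortion).

    Used to evaluate reprojection error of a matrix estimated by
    :func:`resect_dlt` without decomposing it first.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    h = np.hstack([pts, np.ones((pts.shape[0], 1))]) @ np.asarray(P).T
    w = h[:, 2]
    if np.any(np.abs(w) < 1e-15):
        raise DegenerateGeometryError("point projects to infinity")
    out = h[:, :2] / w[:, None]
    return out[0] if np.asarray(points).ndim == 1 else out


def undistort_points(
    cam: CameraModel, pixels, *, tol: float = 1e-10, max_iter: int = 50
) -> np.ndarray:
    """Invert intrinsics and distortion: pixels → normalized coordinates.

    The distortion polynomial has no closed-form inverse; a fixed-point
    iteration is used (initialized at the distorted coordinates), which
    converges rapidly in the low-distortion regime this package targets.
    Re-applying the distortion and intrinsics to the result recovers the
    input pixel to well below 1e-6 px.

    Raises
    ------
    ConvergenceError
        If the iteration has not reached ``tol`` after ``max_iter`` steps;
        the exception carries the final residual.
    """
    px = np.asarray(pixels, dtype=float)
    squeeze = px.ndim == 1
    px = np.atleast_2d(px)
    if px.shape[-1] != 2 or not np.all(np.isfinite(px)):
        raise InvalidModelError("pixels must be finite with shape (..., 2)")
    xd = np.stack(
        [(px[..., 0] - cam.cx) / cam.fx, (px[..., 1] - cam.cy) / cam.fy], axis=-1
    )
    if all(abs(c) < 1e-300 for c in cam.dist):
        return xd[0] if squeeze else xd

    k1, k2, p1, p2 = cam.dist
    x = xd.copy()
    for _ in range(max_iter):
        xs = x[..., 0]
        ys = x[..., 1]
        r2 = xs * xs + ys * ys
        radial = 1.0 + k1 * r2 + k2 * r2 * r2
        dx = 2.0 * p1 * xs * ys + p2 * (r2 + 2.0 * xs * xs)
        dy = p1 * (r2 + 2.0 * ys * ys) + 2.0 * p2 * xs * ys
        x_new = (xd - np.stack([dx, dy], axis=-1)) / radial[..., None]
        step = np.max(np.abs(x_new - x))
        x = x_new
        if step < tol:
            break
    else:
        raise ConvergenceError(
            f"distortion inversion did not converge below {tol} in {max_iter} "
            f"iterations (residual {step:.3e})",
            residual=float(step),
        )
    return x[0] if squeeze else x


def _split_correspondences(correspondences) -> tuple[np.ndarray, np.ndarray]:
    """Accept a list of :class:`Correspondence` or an ``(world, image)`` pair."""
    if (
        isinstance(correspondences, tuple)
        and len(correspondences) == 2
        and not isinstance(correspondences[0], Correspondence)
    ):
        world, image = correspondences
    else:
        seq = list(correspondences)
        world = [c.world for c in seq]
        image = [c.image for c in seq]
    world = np.atleast_2d(np.asarray(world, dtype=float))
    image = np.atleast_2d(np.asarray(image, dtype=float))
    if world.shape[0] != image.shape[0]:
        raise InvalidModelError("world/image correspondence counts differ")
    if world.shape[1] != 3 or image.shape[1] != 2:
        raise InvalidModelError("correspondences must be (n,3) world / (n,2) image")
    if not (np.all(np.isfinite(world)) and np.all(np.isfinite(image))):
        raise InvalidModelError("correspondences contain non-finite values")
    return world, image


def resect_dlt(correspondences) -> np.ndarray:
    """Estimate a 3×4 projection matrix from ≥ 6 3D–2D correspondences.

    Normalized DLT: both point sets are isotropically normalized (centroid at
    the origin, mean distance √2 in 2D / √3 in 3D) before the homogeneous
    linear system is solved by SVD, and the similarity transforms are undone
    afterwards.  The result follows the package scale convention
    (:func:`normalize_projection`).

    Accepts either a sequence of :class:`Correspondence` or a tuple of
    arrays ``(world (n,3), image (n,2))``.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 6 correspondences, or a rank-deficient design matrix
        (e.g. all world points coplanar).
    """
    world, image = _split_correspondences(correspondences)
    n = world.shape[0]
    if n < 6:
        raise DegenerateGeometryError(
            f"resectioning needs at least 6 correspondences, got {n}"
        )

    # Isotropic (Hartley) normalization of both point sets.
    c3 = world.mean(axis=0)
    d3 = np.mean(np.linalg.norm(world - c3, axis=1))
    s3 = np.sqrt(3.0) / d3 if d3 > 0 else 1.0
    T3 = np.eye(4)
    T3[:3, :3] *= s3
    T3[:3, 3] = -s3 * c3

    c2 = image.mean(axis=0)
    d2 = np.mean(np.linalg.norm(image - c2, axis=1))
    s2 = np.sqrt(2.0) / d2 if d2 > 0 else 1.0
    T2 = np.array([[s2, 0, -s2 * c2[0]], [0, s2, -s2 * c2[1]], [0, 0, 1.0]])

    Xn = (world - c3) * s3
    xn = (image - c2) * s2

    Xh = np.hstack([Xn, np.ones((n, 1))])
    A = np.zeros((2 * n, 12))
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -xn[:, 0:1] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -xn[:, 1:2] * Xh

    _, s, Vt = np.linalg.svd(A, full_matrices=False)
    # A unique solution requires rank 11; coplanar/degenerate data leaves a
    # nullspace of dimension >= 2.
    if s[0] == 0 or s[10] / s[0] < 1e-9:
        raise DegenerateGeometryError(
            "degenerate correspondence configuration (rank-deficient design matrix)"
        )
    P_hat = Vt[-1].reshape(3, 4)
    P = np.linalg.inv(T2) @ P_hat @ T3
    return normalize_projection(P)


def decompose_projection(P: np.ndarray, *, skew_tol: float = 1e-6) -> CameraModel:
    """Factor a projection matrix into a zero-distortion :class:`CameraModel`.

    RQ decomposition of the left 3×3 block with sign fixing so the intrinsic
    diagonal is positive and the rotation proper.  Rejects matrices with a
    significant skew term, which this camera model does not represent.
    """
    P = normalize_projection(P)
    M = P[:, :3]
    if np.linalg.det(M) < 0:  # normalize_projection guarantees > 0
        P = -P
        M = P[:, :3]
    K, R = scipy.linalg.rq(M)
    S = np.diag(np.sign(np.diag(K)))
    K = K @ S
    R = S @ R
    scale = K[2, 2]  # overall homogeneous scale of P: M's third row is scale*R[2]
    K = K / scale
    if abs(K[0, 1]) / K[0, 0] > skew_tol:
        raise InvalidModelError(
            f"projection matrix has skew {K[0, 1]:.3e}, not representable"
        )
    t = np.linalg.solve(K, P[:, 3] / scale)
    return CameraModel(
        fx=float(K[0, 0]),
        fy=float(K[1, 1]),
        cx=float(K[0, 2]),
        cy=float(K[1, 2]),
        dist=(0.0, 0.0, 0.0, 0.0),
        R=R,
        t=t,
    )


def rig_from_projections(P_left: np.ndarray, P_right: np.ndarray) -> StereoRig:
    """Build a :class:`StereoRig` from two estimated projection matrices.

    Both matrices are decomposed into zero-distortion camera models and the
    pair is re-anchored so the left camera defines the world frame (the
    package convention).  Lip aperture is a distance, so re-anchoring by a
    rigid transform changes nothing downstream.
    """
    left = decompose_projection(P_left)
    right = decompose_projection(P_right)
    # world' = left-camera frame: X' = R_l X + t_l.
    R_rel = right.R @ left.R.T
    t_rel = right.t - R_rel @ left.t
    left2 = CameraModel(
        fx=left.fx, fy=left.fy, cx=left.cx, cy=left.cy, dist=left.dist
    )
    right2 = CameraModel(
        fx=right.fx, fy=right.fy, cx=right.cx, cy=right.cy, dist=right.dist,
        R=R_rel, t=t_rel,
    )
    return StereoRig(left=left2, right=right2)


def triangulate(rig: StereoRig, left_px, right_px) -> np.ndarray:
    """DLT triangulation of pixel observations to 3D points (mm, world frame).

    Both observations are first undistorted to normalized coordinates, so the
    DLT operates on the exact pinhole part: with normalized observations the
    effective projection matrices are ``[I | 0]`` and ``[R | t]``.  The 4×4
    homogeneous system per point is solved by the smallest right singular
    vector and dehomogenized.

    Vectorized: ``left_px``/``right_px`` may be shape (2,) or (n, 2).

    Raises
    ------
    DegenerateGeometryError
        If the homogeneous solution lies at infinity (|w| < 1e-12), meaning
        the rays are (numerically) parallel.
    """
    lp = np.asarray(left_px, dtype=float)
    squeeze = lp.ndim == 1
    xl = np.atleast_2d(undistort_points(rig.left, left_px))
    xr = np.atleast_2d(undistort_points(rig.right, right_px))
    if xl.shape != xr.shape:
        raise InvalidModelError("left/right observation counts differ")

    Pl = np.hstack([np.eye(3), np.zeros((3, 1))])
    Pr = np.hstack([rig.right.R, rig.right.t[:, None]])

    n = xl.shape[0]
    A = np.empty((n, 4, 4))
    A[:, 0, :] = xl[:, 0, None] * Pl[2] - Pl[0]
    A[:, 1, :] = xl[:, 1, None] * Pl[2] - Pl[1]
    A[:, 2, :] = xr[:, 0, None] * Pr[2] - Pr[0]
    A[:, 3, :] = xr[:, 1, None] * Pr[2] - Pr[1]

    _, _, Vt = np.linalg.svd(A)
    X = Vt[:, -1, :]
    w = X[:, 3]
    if np.any(np.abs(w) < 1e-12):
        raise DegenerateGeometryError(
            "triangulated point at infinity (parallel rays)"
        )
    out = X[:, :3] / w[:, None]
    return out[0] if squeeze else out


def reprojection_error(cam: CameraModel, correspondences) -> float:
    """RMS Euclidean pixel residual of :func:`project` against observations."""
    world, image = _split_correspondences(correspondences)
    if world.shape[0] == 0:
        raise InvalidModelError("reprojection error of an empty correspondence set")
    pred = project(cam, world)
    return float(np.sqrt(np.mean(np.sum((pred - image) ** 2, axis=1))))


def projection_reprojection_error(P: np.ndarray, correspondences) -> float:
    """RMS pixel residual of a raw 3×4 matrix against observations."""
    world, image = _split_correspondences(correspondences)
    if world.shape[0] == 0:
        raise InvalidModelError("reprojection error of an empty correspondence set")
    pred = np.atleast_2d(project_homogeneous(P, world))
    return float(np.sqrt(np.mean(np.sum((pred - image) ** 2, axis=1))))
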