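"""Head-pose recovery from 2D facial landmarks via perspective-n-point.

The driver-facing camera pipeline reduces, for this library, to rigid
correspondences between a canonical 3D landmark model (head-fixed frame:
x right, y down, z forward, millimetres) and per-frame 2D landmark
coordinates (pixels).  ``solve_pnp`` recovers the head->camera pose by
DLT initialisation followed by Levenberg-Marquardt refinement of the
reprojection error; ``yaw_series`` extracts the head-yaw angle
(horizontal rotation about the vertical axis) used by the coordination
analysis.

Euler convention: intrinsic yaw-pitch-roll about the camera-frame
vertical (y), lateral (x) and optical (z) axes, in that order, so yaw
spans the full (-180, 180] range and pitch is the +-90-degree-bounded
middle angle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .series import AngleSeries

_EULER_SEQ = "YXZ"  # intrinsic: yaw about vertical, pitch lateral, roll optical


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics, no lens distortion."""

    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.fx, 0.0, self.cx],
                         [0.0, self.fy, self.cy],
                         [0.0, 0.0, 1.0]])


def default_camera() -> CameraModel:
    """640x480 geometry with 600 px focal length (small CSI camera module)."""
    return CameraModel(fx=600.0, fy=600.0, cx=320.0, cy=240.0)


@dataclass(frozen=True)
class LandmarkModel:
    """Rigid 3D landmark set in the head-fixed frame, millimetres."""

    point_ids: tuple
    points: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "point_ids", tuple(self.point_ids))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be (N, 3)")
        if len(self.point_ids) != pts.shape[0]:
            raise ValueError("point_ids and points length mismatch")
        if pts.shape[0] < 6:
            raise ValueError("landmark model needs at least 6 points")
        centred = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centred, tol=1e-9) < 3:
            raise ValueError("landmark points must not be coplanar")


@dataclass(frozen=True)
class LandmarkFrame:
    """Observed 2D landmarks for one video frame, pixels."""

    frame: int
    point_ids: tuple
    uv: np.ndarray  # (N, 2)

    def __post_init__(self) -> None:
        uv = np.asarray(self.uv, dtype=float)
        object.__setattr__(self, "uv", uv)
        object.__setattr__(self, "point_ids", tuple(self.point_ids))
        if uv.ndim != 2 or uv.shape[1] != 2 or uv.shape[0] != len(self.point_ids):
            raise ValueError("uv must be (N, 2) matching point_ids")


@dataclass(frozen=True)
class HeadPose:
    """Rigid head->camera transform with Euler-angle accessors (degrees)."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,), mm
    rms_reproj_px: float | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def from_euler(cls, yaw: float, pitch: float = 0.0, roll: float = 0.0,
                   translation=(0.0, 0.0, 600.0)) -> "HeadPose":
        r = Rotation.from_euler(_EULER_SEQ, [yaw, pitch, roll], degrees=True)
        return cls(r.as_matrix(), np.asarray(translation, float))

    def _euler(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_euler(_EULER_SEQ, degrees=True)

    @property
    def yaw(self) -> float:
        return float(self._euler()[0])

    @property
    def pitch(self) -> float:
        return float(self._euler()[1])

    @property
    def roll(self) -> float:
        return float(self._euler()[2])


def project(model: LandmarkModel, pose: HeadPose, camera: CameraModel,
            frame: int = 0) -> LandmarkFrame:
    """Pinhole projection of the model under ``pose``.

    Raises ``ValueError`` naming the first point with non-positive depth.
    """
    xc = model.points @ pose.rotation.T + pose.translation
    z = xc[:, 2]
    bad = np.flatnonzero(z <= 0)
    if bad.size:
        raise ValueError(
            f"point {model.point_ids[bad[0]]!r} has non-positive depth "
            f"({z[bad[0]]:.3f} mm): behind the camera"
        )
    uv = np.column_stack((camera.fx * xc[:, 0] / z + camera.cx,
                          camera.fy * xc[:, 1] / z + camera.cy))
    return LandmarkFrame(frame, model.point_ids, uv)


def _match(frame: LandmarkFrame, model: LandmarkModel) -> tuple[np.ndarray, np.ndarray]:
    """Pair observed 2D points with model 3D points by point id."""
    idx3 = {pid: i for i, pid in enumerate(model.point_ids)}
    rows2, rows3 = [], []
    for j, pid in enumerate(frame.point_ids):
        if pid in idx3:
            rows2.append(j)
            rows3.append(idx3[pid])
    return frame.uv[rows2], model.points[rows3]


def _dlt_init(xy: np.ndarray, pts3: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Direct linear transform on normalised image coordinates.

    Returns an orthonormalised rotation and translation estimate.
    """
    n = pts3.shape[0]
    a = np.zeros((2 * n, 12))
    hom = np.column_stack((pts3, np.ones(n)))
    a[0::2, 0:4] = hom
    a[0::2, 8:12] = -xy[:, 0:1] * hom
    a[1::2, 4:8] = hom
    a[1::2, 8:12] = -xy[:, 1:2] * hom
    _, _, vt = np.linalg.svd(a)
    m = vt[-1].reshape(3, 4)
    # resolve the sign so projective depths come out positive
    if np.median(hom @ m[2]) < 0:
        m = -m
    u, s, vt3 = np.linalg.svd(m[:, :3])
    r0 = u @ vt3
    if np.linalg.det(r0) < 0:  # reflection; flip the weakest direction
        u[:, -1] *= -1
        r0 = u @ vt3
    t0 = m[:, 3] / s.mean()
    return r0, t0


def _reproject(rvec: np.ndarray, t: np.ndarray, pts3: np.ndarray,
               camera: CameraModel) -> np.ndarray:
    xc = pts3 @ Rotation.from_rotvec(rvec).as_matrix().T + t
    z = xc[:, 2]
    return np.column_stack((camera.fx * xc[:, 0] / z + camera.cx,
                            camera.fy * xc[:, 1] / z + camera.cy))


def _residual(params: np.ndarray, pts3: np.ndarray, uv: np.ndarray,
              camera: CameraModel) -> np.ndarray:
    return (_reproject(params[:3], params[3:], pts3, camera) - uv).ravel()


def _numeric_jacobian(params: np.ndarray, pts3: np.ndarray, uv: np.ndarray,
                      camera: CameraModel, h: float = 1e-6) -> np.ndarray:
    jac = np.empty((2 * pts3.shape[0], 6))
    for k in range(6):
        dp = np.zeros(6)
        dp[k] = h
        jac[:, k] = (_residual(params + dp, pts3, uv, camera)
                     - _residual(params - dp, pts3, uv, camera)) / (2 * h)
    return jac


def solve_pnp(frame: LandmarkFrame, model: LandmarkModel, camera: CameraModel,
              max_iter: int = 100, step_tol: float = 1e-10) -> HeadPose:
    """Estimate the head pose minimising mean squared reprojection error.

    DLT on normalised coordinates provides the initial estimate; damped
    Gauss-Newton (Levenberg-Marquardt) refines it until the accepted step
    norm falls below ``step_tol`` or ``max_iter`` iterations.  Raises on
    fewer than 6 correspondences or on divergence (ten consecutive
    rejected damped steps).
    """
    uv, pts3 = _match(frame, model)
    if uv.shape[0] < 6:
        raise ValueError(
            f"solve_pnp needs at least 6 correspondences, got {uv.shape[0]}"
        )
    xy = np.column_stack(((uv[:, 0] - camera.cx) / camera.fx,
                          (uv[:, 1] - camera.cy) / camera.fy))
    r0, t0 = _dlt_init(xy, pts3)
    params = np.concatenate((Rotation.from_matrix(r0).as_rotvec(), t0))

    res = _residual(params, pts3, uv, camera)
    cost = float(res @ res)
    lam = 1e-3
    rejects = 0
    for _ in range(max_iter):
        jac = _numeric_jacobian(params, pts3, uv, camera)
        jtj = jac.T @ jac
        g = jac.T @ res
        if np.linalg.norm(g) < 1e-10 * max(1.0, cost):
            break  # stationary point
        try:
            step = np.linalg.solve(jtj + lam * np.diag(np.diag(jtj)), -g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(jtj + lam * np.eye(6), -g, rcond=None)[0]
        new_params = params + step
        new_res = _residual(new_params, pts3, uv, camera)
        new_cost = float(new_res @ new_res)
        if new_cost <= cost * (1.0 + 1e-14):
            converged = (np.linalg.norm(step) < step_tol
                         or cost - new_cost <= 1e-14 * cost)
            if new_cost <= cost:
                params, res, cost = new_params, new_res, new_cost
            lam = max(lam / 10.0, 1e-12)
            rejects = 0
            if converged:
                break
        else:
            # rejected damped step: retry with stronger damping; a step
            # already below tolerance means we sit at a (noisy) optimum
            if np.linalg.norm(step) < step_tol:
                break
            lam *= 10.0
            rejects += 1
            if rejects >= 10:
                raise RuntimeError(
                    "solve_pnp diverged: reprojection error increased for 10 "
                    f"consecutive damped steps (cost {cost:.3e}, lambda {lam:.1e})"
                )
    rms = float(np.sqrt(cost / uv.shape[0]))
    rot = Rotation.from_rotvec(params[:3]).as_matrix()
    # re-orthonormalise against accumulated round-off
    u, _, vt = np.linalg.svd(rot)
    return HeadPose(u @ vt, params[3:], rms_reproj_px=rms)


def yaw_series(poses, rate: float, t0: float = 0.0) -> AngleSeries:
    """Extract head yaw per pose, unwrapped across the +-180-degree seam.

    Poses near gimbal lock (|pitch| > 85 deg) trigger a warning; their yaw
    values are retained.
    """
    poses = list(poses)
    if not poses:
        raise ValueError("empty pose sequence")
    eulers = np.array([p._euler() for p in poses])
    gimbal = np.flatnonzero(np.abs(eulers[:, 1]) > 85.0)
    if gimbal.size:
        warnings.warn(
            f"{gimbal.size} pose(s) near gimbal lock (|pitch| > 85 deg) at "
            f"indices {gimbal[:10].tolist()}; yaw retained",
            RuntimeWarning,
            stacklevel=2,
        )
    yaw = np.unwrap(eulers[:, 0], period=360.0)
    t = t0 + np.arange(len(poses)) / rate
    return AngleSeries(t, yaw, rate, channel="head_yaw")


def canonical_face_model() -> LandmarkModel:
    """Synthetic canonical 68-point facial landmark set (millimetres).

    A fixed, parametrically constructed stand-in for a person-specific
    reconstructed face mesh: jaw contour (17), eyebrows (2x5), nose
    bridge and base (4+5), eyes (2x6) and lips (12 outer + 8 inner).
    Head-fixed frame: x right, y down, z forward (out of the face); the
    set is deliberately non-coplanar (nose protrudes, jaw recedes).
    """
    pts: list[tuple[float, float, float]] = []
    # jaw: half-ellipse, ear to ear through the chin
    for k in range(17):
        ang = np.pi * k / 16.0  # 0 = right ear, pi = left ear
        x = -75.0 * np.cos(ang)
        y = 15.0 + 85.0 * np.sin(ang) ** 1.0
        z = -20.0 + 35.0 * np.sin(ang)  # chin forward of the ears
        pts.append((x, y, z))
    # eyebrows
    for side in (-1.0, 1.0):
        for k in range(5):
            x = side * (18.0 + 9.0 * k)
            y = -38.0 - 4.0 * np.sin(np.pi * k / 4.0)
            pts.append((x, y, 18.0 - 0.8 * k))
    # nose bridge
    for k in range(4):
        pts.append((0.0, -28.0 + 12.0 * k, 28.0 + 7.0 * k))
    # nose base
    for k in range(5):
        pts.append((-12.0 + 6.0 * k, 12.0, 38.0 - 3.0 * abs(k - 2)))
    # eyes
    for side in (-1.0, 1.0):
        cx0 = side * 32.0
        for k in range(6):
            ang = np.pi * k / 3.0
            pts.append((cx0 + 14.0 * np.cos(ang), -20.0 + 5.0 * np.sin(ang), 14.0))
    # outer lips
    for k in range(12):
        ang = 2.0 * np.pi * k / 12.0
        pts.append((26.0 * np.cos(ang), 42.0 + 10.0 * np.sin(ang), 24.0))
    # inner lips
    for k in range(8):
        ang = 2.0 * np.pi * k / 8.0
        pts.append((16.0 * np.cos(ang), 42.0 + 5.0 * np.sin(ang), 25.0))
    return LandmarkModel(tuple(range(68)), np.array(pts))
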