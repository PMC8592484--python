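"""Multi-camera pinhole geometry.

World frame convention: right-handed, X = direction of travel, Z = up,
ground plane at Z = 0.  Camera frame convention: x right, y down (image
origin top-left), z forward (optical axis).  All lengths in metres,
pixels for image coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


class GeometryError(ValueError):
    """Base class for geometric failure modes."""


class DegenerateProjectionError(GeometryError):
    """Point coincides with the camera centre."""


class BehindCameraError(GeometryError):
    """Point lies behind the camera (no valid projection)."""


class InsufficientViewsError(GeometryError):
    """Fewer than two distinct cameras supplied for triangulation."""


class DegenerateConfigurationError(GeometryError):
    """Point set too small or collinear for a rigid alignment."""


class CalibrationSchemaError(ValueError):
    """Calibration JSON does not match the expected schema."""


@dataclass(frozen=True)
class CameraModel:
    """A calibrated pinhole camera with optional radial-tangential distortion.

    ``rotation`` / ``translation`` map world points into the camera frame:
    ``x_cam = R @ x_world + t``.  ``distortion`` holds up to five Brown
    coefficients ``(k1, k2, p1, p2, k3)``; an empty sequence means an
    ideal lens.
    """

    camera_id: str
    intrinsic_matrix: np.ndarray
    rotation: np.ndarray
    translation: np.ndarray
    image_size: tuple[int, int]  # (width, height) pixels
    distortion: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        K = np.asarray(self.intrinsic_matrix, float).reshape(3, 3)
        R = np.asarray(self.rotation, float).reshape(3, 3)
        t = np.asarray(self.translation, float).reshape(3)
        d = np.asarray(self.distortion, float).reshape(-1)
        if d.size > 5:
            raise ValueError("at most 5 distortion coefficients supported")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError(f"camera {self.camera_id}: rotation not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError(f"camera {self.camera_id}: rotation determinant != +1")
        if K[0, 0] <= 0 or K[1, 1] <= 0:
            raise ValueError(f"camera {self.camera_id}: focal lengths must be positive")
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise ValueError(f"camera {self.camera_id}: image_size must be positive")
        object.__setattr__(self, "intrinsic_matrix", K)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "distortion", d)
        object.__setattr__(self, "image_size", (int(w), int(h)))

    @property
    def centre(self) -> np.ndarray:
        """Camera centre in world coordinates."""
        return -self.rotation.T @ self.translation

    @property
    def projection_matrix(self) -> np.ndarray:
        """3x4 homogeneous projection matrix K [R | t]."""
        return self.intrinsic_matrix @ np.hstack(
            [self.rotation, self.translation[:, None]]
        )

    def contains(self, uv: np.ndarray) -> np.ndarray:
        """Boolean mask of pixel coordinates falling inside the image."""
        uv = np.atleast_2d(uv)
        w, h = self.image_size
        return (
            (uv[..., 0] >= 0) & (uv[..., 0] <= w - 1)
            & (uv[..., 1] >= 0) & (uv[..., 1] <= h - 1)
        )


@dataclass(frozen=True)
class CalibrationSet:
    """An ordered collection of calibrated cameras sharing one world frame."""

    cameras: tuple[CameraModel, ...]

    def __post_init__(self):
        cams = tuple(self.cameras)
        ids = [c.camera_id for c in cams]
        if len(set(ids)) != len(ids):
            raise ValueError("camera_ids must be unique")
        object.__setattr__(self, "cameras", cams)

    def __iter__(self):
        return iter(self.cameras)

    def __len__(self):
        return len(self.cameras)

    def __getitem__(self, camera_id: str) -> CameraModel:
        for c in self.cameras:
            if c.camera_id == camera_id:
                return c
        raise KeyError(camera_id)

    @property
    def camera_ids(self) -> list[str]:
        return [c.camera_id for c in self.cameras]


@dataclass(frozen=True)
class RigidAlignment:
    """Rotation + translation mapping one metric frame onto another."""

    rotation: np.ndarray
    translation: np.ndarray
    rms_residual: float
    scale: float = 1.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return self.scale * pts @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# projection


def _distort(xn: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Apply Brown radial-tangential distortion to normalised coordinates."""
    k = np.zeros(5)
    k[: coeffs.size] = coeffs
    x, y = xn[..., 0], xn[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + k[0] * r2 + k[1] * r2 * r2 + k[4] * r2 * r2 * r2
    xd = x * radial + 2 * k[2] * x * y + k[3] * (r2 + 2 * x * x)
    yd = y * radial + k[2] * (r2 + 2 * y * y) + 2 * k[3] * x * y
    return np.stack([xd, yd], axis=-1)


def project_points(camera: CameraModel, points: np.ndarray):
    """Project world points; returns ``(uv, in_front)``.

    ``uv`` has shape (N, 2) with pixel origin top-left and y down; entries
    whose ray leaves through the back of the camera are still computed from
    the homogeneous division but flagged False in ``in_front``.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    x_cam = pts @ camera.rotation.T + camera.translation
    z = x_cam[:, 2]
    in_front = z > 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        xn = x_cam[:, :2] / z[:, None]
    if camera.distortion.size:
        xn = _distort(xn, camera.distortion)
    K = camera.intrinsic_matrix
    uv = xn @ K[:2, :2].T + K[:2, 2]
    return uv, in_front


def project_point(camera: CameraModel, point: np.ndarray) -> np.ndarray:
    """Project a single world point to pixel coordinates.

    Raises ``DegenerateProjectionError`` at the camera centre and
    ``BehindCameraError`` for points behind the image plane — points are
    never silently projected through the camera.
    """
    point = np.asarray(point, float).reshape(3)
    x_cam = camera.rotation @ point + camera.translation
    if np.linalg.norm(x_cam) < 1e-12:
        raise DegenerateProjectionError("point coincides with the camera centre")
    if x_cam[2] <= 1e-12:
        raise BehindCameraError("point lies behind the camera")
    uv, _ = project_points(camera, point[None, :])
    return uv[0]


def undistort_pixel(camera: CameraModel, uv: np.ndarray) -> np.ndarray:
    """Pixel -> ideal normalised image coordinates (inverts distortion)."""
    K = camera.intrinsic_matrix
    uv = np.atleast_2d(np.asarray(uv, float))
    xn = (uv - K[:2, 2]) @ np.linalg.inv(K[:2, :2]).T
    if not camera.distortion.size:
        return xn
    # fixed-point inversion of the Brown model
    xu = xn.copy()
    for _ in range(20):
        xd = _distort(xu, camera.distortion)
        xu = xu + (xn - xd)
    return xu


# ---------------------------------------------------------------------------
# triangulation


@dataclass(frozen=True)
class TriangulationResult:
    point: np.ndarray
    rms_residual_px: float
    ill_conditioned: bool = False


def triangulate_point(
    observations: list[tuple[CameraModel, np.ndarray]],
    refine: bool = True,
    condition_threshold: float = 1e6,
) -> TriangulationResult:
    """Least-squares intersection of back-projected rays.

    Linear DLT on normalised (undistorted) coordinates followed, by
    default, by a Levenberg–Marquardt refinement of the reprojection
    error.  The RMS pixel residual over all views is reported; a large
    DLT condition number attaches an ``ill_conditioned`` warning flag.
    """
    if len(observations) < 2:
        raise InsufficientViewsError("triangulation needs >= 2 cameras")
    ids = [cam.camera_id for cam, _ in observations]
    if len(set(ids)) < 2:
        raise InsufficientViewsError("observations must come from distinct cameras")

    rows = []
    for cam, uv in observations:
        xn = undistort_pixel(cam, uv)[0]
        P = np.hstack([cam.rotation, cam.translation[:, None]])  # normalised projection
        rows.append(xn[0] * P[2] - P[0])
        rows.append(xn[1] * P[2] - P[1])
    A = np.asarray(rows)
    _, s, Vt = np.linalg.svd(A)
    ill = bool(s[-1] < 1e-12 or s[0] / max(s[-2], 1e-300) > condition_threshold)
    X = Vt[-1]
    if abs(X[3]) < 1e-15:
        ill = True
        X = np.append(X[:3], 1.0)
    point = X[:3] / X[3]

    target = np.array([uv for _, uv in observations], float)

    def residual(p):
        err = []
        for (cam, _), obs in zip(observations, target):
            uv_hat, _ = project_points(cam, p[None, :])
            err.append(uv_hat[0] - obs)
        return np.concatenate(err)

    if refine:
        sol = least_squares(residual, point, method="lm", xtol=1e-12, ftol=1e-12)
        point = sol.x
    res = residual(point)
    rms = float(np.sqrt(np.mean(res**2)))
    return TriangulationResult(point=point, rms_residual_px=rms, ill_conditioned=ill)


# ---------------------------------------------------------------------------
# rigid alignment (Kabsch / orthogonal Procrustes, no scale by default)


def estimate_rigid_alignment(
    points_a: np.ndarray, points_b: np.ndarray, allow_scale: bool = False
) -> RigidAlignment:
    """Best-fit rotation + translation taking ``points_a`` onto ``points_b``.

    Minimises mean squared distance over proper rotations (Kabsch).  Both
    systems are metric so scale is excluded by default; ``allow_scale``
    enables a similarity fit for diagnostics only.
    """
    a = np.atleast_2d(np.asarray(points_a, float))
    b = np.atleast_2d(np.asarray(points_b, float))
    if a.shape != b.shape or a.shape[1] != 3:
        raise ValueError("point sets must be matching N x 3 arrays")
    n = a.shape[0]
    if n < 3:
        raise DegenerateConfigurationError("need >= 3 correspondences")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    sv = np.linalg.svd(a0, compute_uv=False)
    if sv[1] < 1e-12 * max(sv[0], 1.0):
        raise DegenerateConfigurationError("correspondences are collinear")
    H = a0.T @ b0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    scale = 1.0
    if allow_scale:
        scale = float(np.sum(S * np.diag(D)) / np.sum(a0**2))
    t = cb - scale * R @ ca
    resid = scale * a @ R.T + t - b
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidAlignment(rotation=R, translation=t, rms_residual=rms, scale=scale)


# ---------------------------------------------------------------------------
# wand-based reconstruction audit


def wand_accuracy(tracked_endpoints: np.ndarray, known_length: float | None = None):
    """Mean and sample SD of per-frame wand endpoint separations.

    ``tracked_endpoints`` is (N, 2, 3): N frames of two 3D endpoints.
    The comparison of the returned mean against ``known_length`` is the
    caller's audit; the known length is accepted only for documentation.
    """
    pts = np.asarray(tracked_endpoints, float)
    if pts.ndim != 3 or pts.shape[1:] != (2, 3) or pts.shape[0] == 0:
        raise ValueError("expected a non-empty (N, 2, 3) endpoint series")
    lengths = np.linalg.norm(pts[:, 0] - pts[:, 1], axis=1)
    mean = float(lengths.mean())
    sd = float(lengths.std(ddof=1)) if lengths.size > 1 else 0.0
    return mean, sd


# ---------------------------------------------------------------------------
# calibration I/O (JSON)

_CAMERA_FIELDS = {
    "camera_id": str,
    "intrinsic_matrix": list,
    "rotation": list,
    "translation": list,
    "image_size": list,
}


def _check(cond: bool, msg: str):
    if not cond:
        raise CalibrationSchemaError(msg)


def calibration_to_dict(calib: CalibrationSet) -> dict:
    return {
        "world_axes": "right-handed, X travel, Z up, ground Z=0",
        "cameras": [
            {
                "camera_id": c.camera_id,
                "intrinsic_matrix": c.intrinsic_matrix.tolist(),
                "distortion": c.distortion.tolist(),
                "rotation": c.rotation.tolist(),
                "translation": c.translation.tolist(),
                "image_size": list(c.image_size),
            }
            for c in calib
        ],
    }


def calibration_from_dict(doc: dict) -> CalibrationSet:
    _check(isinstance(doc, dict), "calibration document must be an object")
    _check("cameras" in doc, "missing field 'cameras'")
    _check(isinstance(doc["cameras"], list) and doc["cameras"],
           "'cameras' must be a non-empty list")
    cams = []
    for i, rec in enumerate(doc["cameras"]):
        _check(isinstance(rec, dict), f"cameras[{i}] must be an object")
        for name, typ in _CAMERA_FIELDS.items():
            _check(name in rec, f"cameras[{i}]: missing field '{name}'")
            _check(isinstance(rec[name], typ),
                   f"cameras[{i}].{name}: expected {typ.__name__}")
        try:
            cams.append(
                CameraModel(
                    camera_id=rec["camera_id"],
                    intrinsic_matrix=np.asarray(rec["intrinsic_matrix"], float),
                    distortion=np.asarray(rec.get("distortion", []), float),
                    rotation=np.asarray(rec["rotation"], float),
                    translation=np.asarray(rec["translation"], float),
                    image_size=tuple(rec["image_size"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise CalibrationSchemaError(f"cameras[{i}]: {exc}") from exc
    return CalibrationSet(cameras=tuple(cams))


def save_calibration(calib: CalibrationSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(calibration_to_dict(calib), fh, indent=1)


def load_calibration(path) -> CalibrationSet:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise CalibrationSchemaError(f"invalid JSON: {exc}") from exc
    return calibration_from_dict(doc)


def look_at_camera(
    camera_id: str,
    position: np.ndarray,
    target: np.ndarray,
    focal_px: float,
    image_size: tuple[int, int],
) -> CameraModel:
    """Construct a camera at ``position`` aimed at ``target`` (world up = +Z)."""
    position = np.asarray(position, float)
    target = np.asarray(target, float)
    f = target - position
    f = f / np.linalg.norm(f)
    up = np.array([0.0, 0.0, 1.0])
    if abs(f @ up) > 0.999:
        up = np.array([1.0, 0.0, 0.0])
    x_c = np.cross(f, up)
    x_c /= np.linalg.norm(x_c)
    y_c = np.cross(f, x_c)  # points image-down in world space
    R = np.stack([x_c, y_c, f])
    t = -R @ position
    w, h = image_size
    K = np.array(
        [[focal_px, 0.0, (w - 1) / 2.0],
         [0.0, focal_px, (h - 1) / 2.0],
         [0.0, 0.0, 1.0]]
    )
    return CameraModel(
        camera_id=camera_id,
        intrinsic_matrix=K,
        rotation=R,
        translation=t,
        image_size=(w, h),
    )
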