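"""Pinhole camera model, reprojection error, and joint calibration.

A camera is the classic projective map  s·(u,v,1)ᵀ = K·[R|T]·(X,Y,Z,1)ᵀ
with zero skew and no lens distortion.  ``calibrate`` jointly refines the
intrinsics and extrinsics of one or more cameras by minimizing the sum of
squared reprojection errors over manually measured world↔pixel
correspondences (Levenberg–Marquardt), starting from physically measured
initial extrinsics.

Calibration points in the intended workflow all lie on the floor plane
Z = 0.  Coplanar points cannot constrain a full free intrinsic matrix, so
the default mode fixes the principal point to the image centre and
enforces fx = fy, optimizing a single focal length together with the
extrinsics; ``fix_intrinsics`` freezes K entirely.  Full-intrinsics
optimization is allowed but requires non-coplanar points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import (
    BehindCameraError,
    DegenerateGeometryError,
    InvalidArgumentError,
)

_MIN_DEPTH = 1e-12


@dataclass(frozen=True)
class CameraModel:
    """One calibrated view: intrinsics K, world-to-camera rotation R and
    translation T (meters), and the image size in pixels (width, height)."""

    K: np.ndarray
    R: np.ndarray
    T: np.ndarray
    image_size: tuple[int, int]

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float).reshape(3, 3)
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        T = np.asarray(self.T, dtype=float).reshape(3)
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "T", T)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise InvalidArgumentError("R is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise InvalidArgumentError("det(R) must be +1")
        if K[0, 0] <= 0 or K[1, 1] <= 0:
            raise InvalidArgumentError("focal lengths must be positive")
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise InvalidArgumentError("image_size must be positive")

    @property
    def fx(self) -> float:
        return float(self.K[0, 0])

    @property
    def fy(self) -> float:
        return float(self.K[1, 1])

    @property
    def principal_point(self) -> tuple[float, float]:
        return float(self.K[0, 2]), float(self.K[1, 2])

    @property
    def center(self) -> np.ndarray:
        """Camera centre in world coordinates, C = −Rᵀ·T."""
        return -self.R.T @ self.T

    @property
    def diagonal(self) -> float:
        w, h = self.image_size
        return float(np.hypot(w, h))

    def contains(self, pixel) -> bool:
        u, v = pixel
        w, h = self.image_size
        return 0.0 <= u < w and 0.0 <= v < h

    def to_dict(self) -> dict:
        return {
            "K": self.K.tolist(),
            "R": self.R.tolist(),
            "T": self.T.tolist(),
            "image_size": list(self.image_size),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            K=np.array(d["K"], dtype=float),
            R=np.array(d["R"], dtype=float),
            T=np.array(d["T"], dtype=float),
            image_size=tuple(int(x) for x in d["image_size"]),
        )

    @classmethod
    def from_intrinsics(cls, fx, fy, cx, cy, R, T, image_size) -> "CameraModel":
        K = np.array([[fx, 0.0, cx], [0.0, fy, cy], [0.0, 0.0, 1.0]])
        return cls(K=K, R=np.asarray(R, float), T=np.asarray(T, float),
                   image_size=image_size)

    @classmethod
    def look_at(cls, position, target, fx, fy, cx, cy, image_size,
                up=(0.0, 0.0, 1.0)) -> "CameraModel":
        """Build a camera at ``position`` whose optical axis points at
        ``target``; ``up`` resolves the roll (world +Z by default)."""
        position = np.asarray(position, float)
        z_cam = np.asarray(target, float) - position
        nz = np.linalg.norm(z_cam)
        if nz < 1e-12:
            raise InvalidArgumentError("camera position equals target")
        z_cam = z_cam / nz
        up = np.asarray(up, float)
        x_cam = np.cross(-up, z_cam)  # image x to the right, y down
        nx = np.linalg.norm(x_cam)
        if nx < 1e-9:  # looking straight along ±up: pick world +X as right
            x_cam = np.array([1.0, 0.0, 0.0])
            x_cam = x_cam - z_cam * (x_cam @ z_cam)
            x_cam /= np.linalg.norm(x_cam)
        else:
            x_cam /= nx
        y_cam = np.cross(z_cam, x_cam)
        R = np.vstack([x_cam, y_cam, z_cam])
        T = -R @ position
        return cls.from_intrinsics(fx, fy, cx, cy, R, T, image_size)


@dataclass(frozen=True)
class Correspondence:
    """One measured world point and its annotated pixel in one camera."""

    world: tuple[float, float, float]
    pixel: tuple[float, float]
    camera_id: str

    def __post_init__(self):
        if not (np.all(np.isfinite(self.world)) and np.all(np.isfinite(self.pixel))):
            raise InvalidArgumentError("non-finite correspondence coordinates")


@dataclass
class CalibrationOptions:
    fix_intrinsics: bool = False
    enforce_fx_eq_fy: bool = True
    fix_principal_point: bool = True


@dataclass
class CalibrationProblem:
    correspondences: list[Correspondence]
    cameras: dict[str, CameraModel]
    options: CalibrationOptions = field(default_factory=CalibrationOptions)


@dataclass
class CalibrationResult:
    cameras: dict[str, CameraModel]
    final_error: float
    initial_error: float
    rms_px: float
    n_iterations: int
    converged: bool


def project(world_point, camera: CameraModel) -> tuple[tuple[float, float], float]:
    """Project a world point; returns ((u, v), s) with s the depth along
    the optical axis so that callers can test cheirality.

    Raises :class:`BehindCameraError` when s ≤ 1e−12.
    """
    X = np.asarray(world_point, dtype=float).reshape(3)
    x_cam = camera.R @ X + camera.T
    s = float(x_cam[2])
    if s <= _MIN_DEPTH:
        raise BehindCameraError(f"point {tuple(X)} has depth s={s:.3g}")
    uvw = camera.K @ x_cam
    return (float(uvw[0] / s), float(uvw[1] / s)), s


def project_points(points: np.ndarray, camera: CameraModel):
    """Vectorized projection of an (N, 3) array.

    Returns (pixels (N, 2), depths (N,)); rows with depth ≤ 1e−12 get NaN
    pixels instead of raising, so bulk rendering can skip them.
    """
    P = np.asarray(points, dtype=float).reshape(-1, 3)
    x_cam = P @ camera.R.T + camera.T
    s = x_cam[:, 2].copy()
    ok = s > _MIN_DEPTH
    uvw = x_cam @ camera.K.T
    pix = np.full((len(P), 2), np.nan)
    pix[ok] = uvw[ok, :2] / s[ok, None]
    return pix, s


def reprojection_error(problem: CalibrationProblem,
                       cameras: dict[str, CameraModel] | None = None) -> float:
    """Sum over all correspondences of the squared pixel distance between
    the annotated pixel and the model prediction (px²).

    A correspondence behind its camera contributes +inf.
    """
    cams = cameras if cameras is not None else problem.cameras
    total = 0.0
    for c in problem.correspondences:
        if c.camera_id not in cams:
            raise InvalidArgumentError(f"no camera for id '{c.camera_id}'")
        try:
            (u, v), _ = project(c.world, cams[c.camera_id])
        except BehindCameraError:
            return float("inf")
        total += (u - c.pixel[0]) ** 2 + (v - c.pixel[1]) ** 2
    return total


def _check_degeneracy(problem: CalibrationProblem) -> None:
    opts = problem.options
    min_pts = 4 if opts.fix_intrinsics else 6
    by_cam: dict[str, list[Correspondence]] = {}
    for c in problem.correspondences:
        by_cam.setdefault(c.camera_id, []).append(c)
    for cam_id, cs in by_cam.items():
        if len(cs) < min_pts:
            raise DegenerateGeometryError(
                f"camera '{cam_id}' has {len(cs)} correspondences; "
                f"≥ {min_pts} required")
        W = np.array([c.world for c in cs])
        # collinear world points leave rotation about the line unconstrained
        centred = W - W.mean(axis=0)
        svals = np.linalg.svd(centred, compute_uv=False)
        if svals[1] < 1e-9 * max(svals[0], 1.0):
            raise DegenerateGeometryError(
                f"camera '{cam_id}': calibration points are collinear")


def _pack(cameras, order, opts):
    x = []
    for cam_id in order:
        cam = cameras[cam_id]
        x.extend(Rotation.from_matrix(cam.R).as_rotvec())
        x.extend(cam.T)
        if not opts.fix_intrinsics:
            if opts.enforce_fx_eq_fy:
                x.append(cam.fx)
            else:
                x.extend([cam.fx, cam.fy])
            if not opts.fix_principal_point:
                x.extend(cam.principal_point)
    return np.array(x, dtype=float)


def _unpack(x, cameras, order, opts):
    out = {}
    i = 0
    for cam_id in order:
        cam = cameras[cam_id]
        rvec, T = x[i:i + 3], x[i + 3:i + 6]
        i += 6
        K = cam.K.copy()
        if not opts.fix_intrinsics:
            if opts.enforce_fx_eq_fy:
                K[0, 0] = K[1, 1] = x[i]
                i += 1
            else:
                K[0, 0], K[1, 1] = x[i], x[i + 1]
                i += 2
            if not opts.fix_principal_point:
                K[0, 2], K[1, 2] = x[i], x[i + 1]
                i += 2
        out[cam_id] = CameraModel(
            K=K, R=Rotation.from_rotvec(rvec).as_matrix(), T=np.asarray(T),
            image_size=cam.image_size)
    return out


def calibrate(problem: CalibrationProblem,
              max_iterations: int = 200,
              tol: float = 1e-10) -> CalibrationResult:
    """Refine camera parameters by LM minimization of the reprojection
    error, starting from ``problem.cameras``.

    Rotations are parameterized internally as axis-angle vectors.  Stops
    when the decrease in E falls below ``tol`` or after
    ``max_iterations``; the result never has a larger E than the
    initialization.
    """
    _check_degeneracy(problem)
    opts = problem.options
    order = sorted(problem.cameras)
    if opts.fix_intrinsics and not any(True for _ in problem.correspondences):
        raise InvalidArgumentError("no correspondences")

    world = {cid: np.array([c.world for c in problem.correspondences
                            if c.camera_id == cid]) for cid in order}
    pixels = {cid: np.array([c.pixel for c in problem.correspondences
                             if c.camera_id == cid]) for cid in order}

    def residuals(x):
        cams = _unpack(x, problem.cameras, order, opts)
        res = []
        for cid in order:
            cam = cams[cid]
            x_cam = world[cid] @ cam.R.T + cam.T
            s = x_cam[:, 2]
            bad = s <= _MIN_DEPTH
            s = np.where(bad, 1.0, s)
            uv = (x_cam @ cam.K.T)[:, :2] / s[:, None]
            r = uv - pixels[cid]
            # huge-but-finite penalty keeps LM usable near cheirality violations
            r[bad] = 1e6
            res.append(r.ravel())
        return np.concatenate(res)

    x0 = _pack(problem.cameras, order, opts)
    initial_error = reprojection_error(problem, problem.cameras)
    sol = least_squares(residuals, x0, method="lm",
                        ftol=tol, xtol=1e-14, gtol=1e-14,
                        max_nfev=max_iterations * max(len(x0), 10))
    cams_opt = _unpack(sol.x, problem.cameras, order, opts)
    final_error = reprojection_error(problem, cams_opt)
    converged = bool(sol.status > 0)
    if final_error > initial_error:  # LM safeguard: never worsen the start
        cams_opt, final_error, converged = dict(problem.cameras), initial_error, False
    n_res = max(len(problem.correspondences), 1)
    return CalibrationResult(
        cameras=cams_opt,
        final_error=float(final_error),
        initial_error=float(initial_error),
        rms_px=float(np.sqrt(final_error / n_res)),
        n_iterations=int(sol.nfev),
        converged=converged,
    )


def perturb_camera(camera: CameraModel, rotation_deg: float,
                   translation_m: float, seed: int = 0) -> CameraModel:
    """Return a copy with extrinsics perturbed by a random rotation of the
    given magnitude (degrees) and a random translation (meters) — the
    standard way to build a misinitialized calibration test problem."""
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    dR = Rotation.from_rotvec(np.deg2rad(rotation_deg) * axis).as_matrix()
    dT = rng.normal(size=3)
    dT *= translation_m / np.linalg.norm(dT)
    return replace(camera, R=dR @ camera.R, T=camera.T + dT)


# --- correspondence / camera file I/O -------------------------------------

def read_correspondences(path) -> list[Correspondence]:
    """CSV 'camera_id,X,Y,Z,u,v' (header optional)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.lower().startswith("camera_id"):
                continue
            parts = line.split(",")
            if len(parts) != 6:
                from .errors import ParseError
                raise ParseError(f"expected 6 fields, got {len(parts)}", ln)
            cid = parts[0].strip()
            X, Y, Z, u, v = map(float, parts[1:])
            out.append(Correspondence(world=(X, Y, Z), pixel=(u, v), camera_id=cid))
    return out


def write_cameras_yaml(cameras: dict[str, CameraModel], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({cid: cam.to_dict() for cid, cam in cameras.items()}, fh)


def read_cameras_yaml(path) -> dict[str, CameraModel]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {cid: CameraModel.from_dict(d) for cid, d in raw.items()}
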