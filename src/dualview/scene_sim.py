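"""Synthetic pen simulator.

Emulates the statistical structure of a dual-camera gilt-pen recording
setup — a 5.3 × 6.0 m pen holding ~35 animals of which ~5 carry no ear
tag, a ceiling camera 3.4 m above the feeding area (covering only part
of the pen) and an elevated oblique camera covering the whole pen — so
that the geometry, mapping and evaluation modules are testable without
farm video.  Agents move by waypoint seeking; day/night noise regimes
differ in pixel jitter and detection dropout.

The simulator is deliberately not photorealistic: detections are
projected world rectangles plus Gaussian pixel noise, not renderings.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .camera_geometry import CameraModel, project_points
from .errors import InvalidArgumentError
from .records import DetectionRecord, TagClass, read_mot, write_mot  # noqa: F401

__all__ = [
    "PenConfig", "MotionState", "Trajectory", "NoiseModel",
    "simulate_trajectories", "render_views", "RenderResult",
    "default_cameras", "filter_redundant_frames",
    "write_mot", "read_mot",
]


class MotionState(enum.Enum):
    stationary = "stationary"
    active = "active"
    mixed = "mixed"


@dataclass(frozen=True)
class PenConfig:
    """Pen geometry and population.

    The world frame is right-handed with Z up; Z = 0 is the slatted
    floor; the pen occupies [0, width_m] × [0, depth_m].  The feeding
    area is an axis-aligned sub-rectangle (x, y, w, h) in meters over
    which the top-down camera is mounted.  ``agent_height_m`` is the
    body-centre height above the floor used for projection and as the
    default cross-view mapping plane.
    """

    width_m: float = 5.3
    depth_m: float = 6.0
    n_pigs: int = 35
    n_untagged: int = 5
    feeding_area: tuple[float, float, float, float] = (0.9, 0.4, 3.5, 2.0)
    agent_height_m: float = 0.35

    def __post_init__(self):
        if self.width_m <= 0 or self.depth_m <= 0 or self.agent_height_m <= 0:
            raise InvalidArgumentError("pen dimensions must be positive")
        if self.n_pigs < 1:
            raise InvalidArgumentError("n_pigs must be ≥ 1")
        if not 0 <= self.n_untagged <= self.n_pigs:
            raise InvalidArgumentError("need 0 ≤ n_untagged ≤ n_pigs")
        fx, fy, fw, fh = self.feeding_area
        if fw <= 0 or fh <= 0 or fx < 0 or fy < 0 \
                or fx + fw > self.width_m or fy + fh > self.depth_m:
            raise InvalidArgumentError("feeding_area must lie inside the pen")

    @property
    def feeding_center(self) -> tuple[float, float]:
        fx, fy, fw, fh = self.feeding_area
        return (fx + fw / 2.0, fy + fh / 2.0)


@dataclass(frozen=True)
class Trajectory:
    """One agent's path: an (n_frames, 3) array of (t, x, y) rows with t
    the integer frame index and x, y in meters."""

    agent_id: int
    tagged: bool
    positions: np.ndarray
    motion_state: MotionState

    def __post_init__(self):
        P = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", P)
        t = P[:, 0]
        if len(t) and (np.any(np.diff(t) <= 0)):
            raise InvalidArgumentError("frame indices must be strictly increasing")

    @property
    def xy(self) -> np.ndarray:
        return self.positions[:, 1:3]


@dataclass(frozen=True)
class NoiseModel:
    """Detection noise regime.  Night defaults double the day pixel
    jitter and dropout, reproducing the qualitative day/night
    degradation of overhead livestock footage without claiming measured
    numbers."""

    pixel_sigma: float = 2.0
    dropout_prob: float = 0.03
    regime: str = "day"

    def __post_init__(self):
        if self.pixel_sigma < 0:
            raise InvalidArgumentError("pixel_sigma must be ≥ 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise InvalidArgumentError("dropout_prob must be in [0, 1]")
        if self.regime not in ("day", "night"):
            raise InvalidArgumentError("regime must be 'day' or 'night'")

    @classmethod
    def day(cls, pixel_sigma: float = 2.0, dropout_prob: float = 0.03):
        return cls(pixel_sigma, dropout_prob, "day")

    @classmethod
    def night(cls, pixel_sigma: float = 4.0, dropout_prob: float = 0.06):
        return cls(pixel_sigma, dropout_prob, "night")

    @classmethod
    def none(cls):
        return cls(0.0, 0.0, "day")


V_MAX = 1.0  # m/s — upper bound on agent speed


def simulate_trajectories(pen: PenConfig, n_frames: int, fps: float,
                          seed: int,
                          motion_state: MotionState | str = MotionState.mixed,
                          v_max: float = V_MAX) -> list[Trajectory]:
    """Simulate ``pen.n_pigs`` waypoint-seeking trajectories of
    ``n_frames`` frames at ``fps``.

    Exactly ``pen.n_untagged`` agents are untagged (the first ids).
    Stationary agents have zero speed; active agents draw a per-agent
    cruise speed from (0.15·v_max, v_max]; mixed agents alternate
    stationary and active bouts.  Deterministic given ``seed``.
    """
    if n_frames < 1:
        raise InvalidArgumentError("n_frames must be ≥ 1")
    if fps <= 0:
        raise InvalidArgumentError("fps must be > 0")
    motion_state = MotionState(motion_state)
    rng = np.random.default_rng(seed)
    dt = 1.0 / fps
    margin = 0.25  # keep body centres away from walls
    lo = np.array([margin, margin])
    hi = np.array([pen.width_m - margin, pen.depth_m - margin])

    trajectories = []
    for agent_id in range(pen.n_pigs):
        tagged = agent_id >= pen.n_untagged
        if motion_state is MotionState.mixed:
            state = rng.choice([MotionState.stationary, MotionState.active,
                                MotionState.mixed], p=[0.35, 0.35, 0.30])
        else:
            state = motion_state
        speed = 0.0 if state is MotionState.stationary \
            else float(rng.uniform(0.15 * v_max, v_max))
        pos = rng.uniform(lo, hi)
        waypoint = rng.uniform(lo, hi)
        moving = state is MotionState.active
        bout_left = int(rng.integers(int(2 * fps), int(8 * fps) + 1))
        rows = np.empty((n_frames, 3))
        for t in range(n_frames):
            rows[t] = (t, pos[0], pos[1])
            if state is MotionState.mixed:
                bout_left -= 1
                if bout_left <= 0:
                    moving = not moving
                    bout_left = int(rng.integers(int(2 * fps), int(8 * fps) + 1))
            v = speed if (state is MotionState.active or
                          (state is MotionState.mixed and moving)) else 0.0
            if v > 0:
                delta = waypoint - pos
                dist = float(np.hypot(*delta))
                step = min(v * dt, dist)
                if dist < 1e-9 or step >= dist:
                    pos = waypoint.copy()
                    waypoint = rng.uniform(lo, hi)
                else:
                    pos = pos + delta / dist * step
                pos = np.clip(pos, lo, hi)
        trajectories.append(Trajectory(agent_id=agent_id, tagged=tagged,
                                       positions=rows, motion_state=state))
    return trajectories


def default_cameras(pen: PenConfig,
                    image_size: tuple[int, int] = (1920, 1080),
                    top_height_m: float = 3.4,
                    top_focal_px: float = 1500.0,
                    pan_focal_px: float = 900.0) -> tuple[CameraModel, CameraModel]:
    """Construct the two study cameras: a ceiling camera ``top_height_m``
    above the feeding-area centre looking straight down (covering only
    part of the pen at the default focal), and an oblique panoramic
    camera suspended at the midpoint above one side of the pen, aimed at
    the pen centre so its frustum covers the whole pen."""
    w, h = image_size
    cx, cy = w / 2.0, h / 2.0
    fcx, fcy = pen.feeding_center
    cam_top = CameraModel.look_at(
        position=(fcx, fcy, top_height_m), target=(fcx, fcy, 0.0),
        fx=top_focal_px, fy=top_focal_px, cx=cx, cy=cy,
        image_size=image_size, up=(0.0, 1.0, 0.0))
    cam_pan = CameraModel.look_at(
        position=(pen.width_m / 2.0, -0.4, 2.6),
        target=(pen.width_m / 2.0, pen.depth_m / 2.0, pen.agent_height_m),
        fx=pan_focal_px, fy=pan_focal_px, cx=cx, cy=cy,
        image_size=image_size)
    return cam_top, cam_pan


@dataclass
class RenderResult:
    top: list[DetectionRecord]
    pan: list[DetectionRecord]
    diagnostics: dict = field(default_factory=dict)

    def __iter__(self):
        return iter((self.top, self.pan))


def _heading_series(xy: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-frame unit heading; stationary stretches reuse the last known
    (or a random initial) heading so body boxes stay oriented."""
    n = len(xy)
    headings = np.empty((n, 2))
    theta0 = rng.uniform(0.0, 2 * np.pi)
    current = np.array([np.cos(theta0), np.sin(theta0)])
    for t in range(n):
        if t + 1 < n:
            d = xy[t + 1] - xy[t]
            nd = np.hypot(*d)
            if nd > 1e-9:
                current = d / nd
        headings[t] = current
    return headings


def render_views(trajectories: list[Trajectory],
                 cam_top: CameraModel, cam_pan: CameraModel,
                 noise: NoiseModel, seed: int,
                 agent_height_m: float = 0.35,
                 body_size_m: tuple[float, float] = (0.9, 0.35),
                 tag_occluded_prob: float = 0.08) -> RenderResult:
    """Project every agent at every frame into both cameras and emit
    noisy detection records.

    The body is a fixed ``body_size_m`` (length × width) world rectangle
    at ``agent_height_m`` above the floor, oriented along the travel
    heading; its projected corner hull's axis-aligned bounding box is
    the detection.  i.i.d. N(0, pixel_sigma²) noise is added to each box
    edge; records are dropped with ``dropout_prob``.  A view keeps only
    detections whose (noiseless) centre projects inside its image
    bounds.  Untagged agents are always ``tag_not_visible``; tagged
    agents are mislabelled ``tag_not_visible`` with
    ``tag_occluded_prob`` (an occluded ear tag).  Agents projecting
    behind a camera are skipped and counted in ``diagnostics``.
    """
    if not trajectories:
        raise InvalidArgumentError("trajectories must be non-empty")
    rng = np.random.default_rng(seed)
    half_l, half_w = body_size_m[0] / 2.0, body_size_m[1] / 2.0
    diagnostics = {"behind_camera": {"top": 0, "pan": 0},
                   "out_of_frame": {"top": 0, "pan": 0},
                   "dropped": {"top": 0, "pan": 0}}
    views = {"top": (cam_top, []), "pan": (cam_pan, [])}

    for traj in trajectories:
        xy = traj.xy
        n = len(xy)
        headings = _heading_series(xy, rng)
        perp = headings[:, ::-1] * np.array([-1.0, 1.0])
        # 4 body-rectangle corners per frame, at body-centre height
        offsets = np.stack([
            half_l * headings + half_w * perp,
            half_l * headings - half_w * perp,
            -half_l * headings + half_w * perp,
            -half_l * headings - half_w * perp,
        ], axis=1)                                   # (n, 4, 2)
        corners = np.empty((n, 4, 3))
        corners[:, :, :2] = xy[:, None, :] + offsets
        corners[:, :, 2] = agent_height_m
        centers = np.column_stack([xy, np.full(n, agent_height_m)])

        # occlusion labels for tagged agents, one draw per frame
        occluded = rng.random(n) < tag_occluded_prob if traj.tagged else None

        for name, (cam, records) in views.items():
            pix, s = project_points(corners.reshape(-1, 3), cam)
            pix = pix.reshape(n, 4, 2)
            s = s.reshape(n, 4)
            cpix, cs = project_points(centers, cam)
            edge_noise = rng.normal(0.0, noise.pixel_sigma, size=(n, 4))
            drop = rng.random(n) < noise.dropout_prob
            for t in range(n):
                if cs[t] <= 1e-12 or np.any(s[t] <= 1e-12):
                    diagnostics["behind_camera"][name] += 1
                    continue
                if not cam.contains(cpix[t]):
                    diagnostics["out_of_frame"][name] += 1
                    continue
                if drop[t]:
                    diagnostics["dropped"][name] += 1
                    continue
                x1, y1 = pix[t].min(axis=0)
                x2, y2 = pix[t].max(axis=0)
                x1 += edge_noise[t, 0]
                y1 += edge_noise[t, 1]
                x2 += edge_noise[t, 2]
                y2 += edge_noise[t, 3]
                w = max(x2 - x1, 1.0)
                h = max(y2 - y1, 1.0)
                if traj.tagged:
                    cls = TagClass.tag_not_visible if occluded[t] \
                        else TagClass.tag_visible
                else:
                    cls = TagClass.tag_not_visible
                records.append(DetectionRecord(
                    frame=int(traj.positions[t, 0]), id=traj.agent_id,
                    box=(float(x1), float(y1), float(w), float(h)),
                    cls=cls, conf=1.0))
    return RenderResult(top=views["top"][1], pan=views["pan"][1],
                        diagnostics=diagnostics)


def filter_redundant_frames(frames, threshold: float = 0.78) -> list[int]:
    """Greedy SSIM de-duplication of a frame sequence.

    The first frame is always kept; each subsequent frame is kept iff
    its SSIM against the *last kept* frame is below ``threshold`` (0.78
    by default).  Returns the retained indices.  An empty input yields
    an empty list.
    """
    frames = list(frames)
    if not frames:
        return []
    if not 0.0 < threshold < 1.0:
        raise InvalidArgumentError("threshold must be in (0, 1)")
    shape = np.asarray(frames[0]).shape
    retained = [0]
    last = np.asarray(frames[0], dtype=float)
    for i, frame in enumerate(frames[1:], start=1):
        f = np.asarray(frame, dtype=float)
        if f.shape != shape:
            raise InvalidArgumentError(
                f"frame {i} shape {f.shape} differs from {shape}")
        rng_val = max(last.max() - last.min(), f.max() - f.min(), 1e-9)
        score = structural_similarity(last, f, data_range=rng_val)
        if score < threshold:
            retained.append(i)
            last = f
    return retained
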