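"""Cross-view position mapping and target matching.

A tag-loss detection in the top-down view is carried into the panoramic
oblique view by intersecting its viewing ray with a horizontal reference
plane (the shared floor frame) and re-projecting the world point through
the panoramic camera.  For points on that plane this chain is exact and
realizes the rigid world-frame transform between the two views.  The
mapped point is then matched to panoramic detections by nearest
neighbour on the normalized Euclidean distance (pixel distance divided
by the panoramic image diagonal), with a rejection threshold: if even
the nearest candidate is farther than the threshold, no match is output.

The module also houses the tag-loss decision rule (a tag-not-visible
animal counts as a tag-loss candidate only when its box keeps at least a
one-pixel margin from every image border, since an animal cut off by the
frame edge may simply have its tag outside the view) and the mapping
evaluation statistics: matching accuracy, coverage, mapping accuracy and
rejection rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .camera_geometry import CameraModel, project
from .errors import (
    BehindCameraError,
    DegenerateRayError,
    InvalidArgumentError,
    UndefinedMetricError,
)
from .records import DetectionRecord, TagClass
from .tracking_eval import iou

__all__ = [
    "DetectionRecord", "TagClass", "MatchOutcome", "MappingEvalResult",
    "is_tag_loss", "backproject_to_plane", "map_topdown_to_panoramic",
    "match_target", "evaluate_mapping", "fit_rigid_2d", "apply_rigid_2d",
]


@dataclass(frozen=True)
class MatchOutcome:
    """Result of one cross-view matching attempt."""

    query: DetectionRecord
    mapped_pixel: tuple[float, float]
    matched: DetectionRecord | None
    norm_distance: float
    rejected: bool

    def __post_init__(self):
        if self.rejected != (self.matched is None):
            raise InvalidArgumentError("rejected ⇔ matched is None")


@dataclass(frozen=True)
class MappingEvalResult:
    """Mapping statistics over a set of matching attempts.

    mapping_accuracy  = n_correct / n_total
    coverage          = n_covered / n_total   (matched, i.e. not rejected)
    rejection_rate    = n_rejected / n_total
    matching_accuracy = n_correct / (n_total − n_rejected); NaN (with
    ``matching_accuracy_defined=False``) when everything was rejected.
    """

    matching_accuracy: float
    coverage: float
    mapping_accuracy: float
    rejection_rate: float
    n_total: int
    n_attempted: int
    n_covered: int
    n_correct: int
    n_rejected: int
    matching_accuracy_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "matching_accuracy": self.matching_accuracy,
            "coverage": self.coverage,
            "mapping_accuracy": self.mapping_accuracy,
            "rejection_rate": self.rejection_rate,
            "counts": {
                "n_total": self.n_total, "n_attempted": self.n_attempted,
                "n_covered": self.n_covered, "n_correct": self.n_correct,
                "n_rejected": self.n_rejected,
            },
        }


def is_tag_loss(det: DetectionRecord, image_size: tuple[int, int]) -> bool:
    """True iff the detection is tag-not-visible AND its box keeps a
    ≥ 1 px margin from all four image borders (fully inside the view, so
    the missing tag cannot be explained by frame truncation)."""
    if det.cls is not TagClass.tag_not_visible:
        return False
    x, y, w, h = det.box
    width, height = image_size
    return x >= 1.0 and y >= 1.0 and x + w <= width - 1.0 and y + h <= height - 1.0


def backproject_to_plane(pixel, camera: CameraModel,
                         plane_height: float) -> tuple[float, float, float]:
    """Intersect the viewing ray through ``pixel`` with the horizontal
    plane Z = ``plane_height``; returns the world point (X, Y, plane_height).

    Raises :class:`DegenerateRayError` when the ray is parallel to the
    plane and :class:`BehindCameraError` when the intersection lies
    behind the camera.
    """
    u, v = float(pixel[0]), float(pixel[1])
    direction = camera.R.T @ np.linalg.solve(camera.K, np.array([u, v, 1.0]))
    center = camera.center
    if abs(direction[2]) < 1e-12:
        raise DegenerateRayError(f"ray through {(u, v)} is parallel to the plane")
    t = (plane_height - center[2]) / direction[2]
    if t <= 0:
        raise BehindCameraError(
            f"plane Z={plane_height} intersection lies behind the camera")
    X = center + t * direction
    return (float(X[0]), float(X[1]), float(plane_height))


def map_topdown_to_panoramic(det: DetectionRecord, cam_top: CameraModel,
                             cam_pan: CameraModel,
                             plane_height: float = 0.35) -> tuple[float, float]:
    """Map a top-down detection's box centre into the panoramic view via
    the shared reference plane: back-project onto Z = ``plane_height``,
    then project the world point through the panoramic camera.

    ``plane_height`` defaults to the body-centre height (box centres sit
    above the floor); a value of 0 uses the floor plane itself.
    """
    world = backproject_to_plane(det.center, cam_top, plane_height)
    (u, v), _ = project(world, cam_pan)
    return (u, v)


def match_target(P2, candidates, threshold: float,
                 image_size: tuple[int, int],
                 query: DetectionRecord | None = None) -> MatchOutcome:
    """Nearest-neighbour matching of a mapped point against panoramic
    detections, with threshold rejection.

    The distance to each candidate's box centre is normalized by the
    image diagonal; the minimum-distance candidate is accepted iff its
    normalized distance is strictly below ``threshold`` (ties broken by
    lowest candidate index).  With no candidates the outcome is a
    rejection at distance +inf.
    """
    if threshold <= 0:
        raise InvalidArgumentError("threshold must be > 0")
    if query is None:
        query = DetectionRecord(frame=-1, id=-1, box=(0.0, 0.0, 0.0, 0.0),
                                cls=TagClass.tag_not_visible)
    candidates = list(candidates)
    P2 = (float(P2[0]), float(P2[1]))
    if not candidates:
        return MatchOutcome(query=query, mapped_pixel=P2, matched=None,
                            norm_distance=math.inf, rejected=True)
    diag = math.hypot(*image_size)
    centers = np.array([c.center for c in candidates])
    dists = np.hypot(centers[:, 0] - P2[0], centers[:, 1] - P2[1]) / diag
    best = int(np.argmin(dists))  # argmin returns the first minimum: lowest index
    d = float(dists[best])
    if d < threshold:
        return MatchOutcome(query=query, mapped_pixel=P2,
                            matched=candidates[best], norm_distance=d,
                            rejected=False)
    return MatchOutcome(query=query, mapped_pixel=P2, matched=None,
                        norm_distance=d, rejected=True)


def evaluate_mapping(outcomes, truth, iou_threshold: float = 0.5) -> MappingEvalResult:
    """Score matching attempts against ground truth.

    ``truth`` maps (query.frame, query.id) — or the query record itself —
    to the true panoramic box (x, y, w, h).  A non-rejected outcome is
    *correct* iff the IoU between the matched box and the truth box is
    ≥ ``iou_threshold``.
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise UndefinedMetricError("no matching outcomes to evaluate")
    n_total = len(outcomes)
    n_rejected = sum(o.rejected for o in outcomes)
    n_covered = n_total - n_rejected
    n_correct = 0
    for o in outcomes:
        key = (o.query.frame, o.query.id)
        if key in truth:
            true_box = truth[key]
        elif o.query in truth:
            true_box = truth[o.query]
        else:
            raise InvalidArgumentError(f"no truth entry for query {key}")
        if not o.rejected and iou(o.matched.box, true_box) >= iou_threshold:
            n_correct += 1
    defined = n_covered > 0
    return MappingEvalResult(
        matching_accuracy=n_correct / n_covered if defined else math.nan,
        coverage=n_covered / n_total,
        mapping_accuracy=n_correct / n_total,
        rejection_rate=n_rejected / n_total,
        n_total=n_total, n_attempted=n_total, n_covered=n_covered,
        n_correct=n_correct, n_rejected=n_rejected,
        matching_accuracy_defined=defined,
    )


# --- literal 2D rigid-transform mode --------------------------------------
#
# The cross-view transform written directly on 2D detection coordinates,
# P2 = R·P1 + T with R a 2×2 rotation (optionally scaled) — geometrically
# only an approximation between oblique views, provided for comparison
# with the plane-chain mapping.

def fit_rigid_2d(src: np.ndarray, dst: np.ndarray,
                 allow_scale: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares similarity/rigid transform between matched 2D point
    sets (Umeyama alignment).  Returns (A 2×2, t 2-vector)."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise InvalidArgumentError("src/dst must be matching (N, 2) arrays")
    if len(src) < 2:
        raise InvalidArgumentError("need ≥ 2 point pairs")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    S, D = src - mu_s, dst - mu_d
    H = D.T @ S / len(src)
    U, sig, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(U @ Vt))
    C = np.diag([1.0, sign])
    R = U @ C @ Vt
    if allow_scale:
        var_s = (S ** 2).sum() / len(src)
        scale = float((sig * np.diag(C)).sum() / var_s)
        R = scale * R
    t = mu_d - R @ mu_s
    return R, t


def apply_rigid_2d(P1, A: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    p = np.asarray(A, float) @ np.asarray(P1, float) + np.asarray(t, float)
    return (float(p[0]), float(p[1]))
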