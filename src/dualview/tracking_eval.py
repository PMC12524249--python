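"""Single-object-tracking evaluation metrics.

Three standard metrics over per-frame (predicted, ground-truth) box
pairs:

* Success(θ): fraction of frames whose IoU reaches the threshold θ
  (default 0.5).
* Norm-Precision: mean Euclidean centre distance divided by the frame
  area A (the literal convention of the source formulation; a √A
  variant, dimensionally a length, is available via ``mode="sqrt"``).
* Precision: mean Euclidean centre distance in pixels.

``evaluate_tracks`` aggregates these per lighting/activity condition
from MOT-style CSV or LaSOT-style one-box-per-line files.  Frames
present in the truth but missing from the predictions are scored as
failures (IoU 0) and excluded from the distance means, with the count
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, InvalidArgumentError, UndefinedMetricError
from .records import read_mot

Box = tuple[float, float, float, float]


@dataclass(frozen=True)
class BoxPair:
    frame: int
    predicted: Box
    truth: Box

    def __post_init__(self):
        for b in (self.predicted, self.truth):
            if b[2] < 0 or b[3] < 0:
                raise InvalidArgumentError(f"negative box size in {b}")


@dataclass(frozen=True)
class TrackEvalConfig:
    iou_threshold: float = 0.5
    frame_area: float = 1920.0 * 1080.0
    norm_mode: str = "area"  # "area": divide by A (literal); "sqrt": by √A

    def __post_init__(self):
        if not 0.0 < self.iou_threshold <= 1.0:
            raise InvalidArgumentError("iou_threshold must be in (0, 1]")
        if self.frame_area <= 0:
            raise InvalidArgumentError("frame_area must be > 0")
        if self.norm_mode not in ("area", "sqrt"):
            raise InvalidArgumentError("norm_mode must be 'area' or 'sqrt'")


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection over union of two (x_left, y_top, w, h) boxes;
    0 when the union is empty."""
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    if aw < 0 or ah < 0 or bw < 0 or bh < 0:
        raise InvalidArgumentError("box sizes must be non-negative")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    # rounding of (x+w)−x can overshoot w; the overlap never exceeds
    # either box's area
    inter = min(ix * iy, aw * ah, bw * bh)
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def _center(box: Box) -> tuple[float, float]:
    return (box[0] + box[2] / 2.0, box[1] + box[3] / 2.0)


def _center_distances(pairs) -> np.ndarray:
    return np.array([math.dist(_center(p.predicted), _center(p.truth))
                     for p in pairs])


def success(pairs, config: TrackEvalConfig) -> float:
    """(1/N) Σ 1[IoU(bᵢ, gᵢ) ≥ θ]."""
    pairs = list(pairs)
    if not pairs:
        raise UndefinedMetricError("success over empty pair set")
    hits = sum(iou(p.predicted, p.truth) >= config.iou_threshold for p in pairs)
    return hits / len(pairs)


def norm_precision(pairs, config: TrackEvalConfig) -> float:
    """Mean centre distance normalized by the frame area A (literal
    mode) or by √A (``norm_mode='sqrt'``)."""
    pairs = list(pairs)
    if not pairs:
        raise UndefinedMetricError("norm_precision over empty pair set")
    denom = config.frame_area if config.norm_mode == "area" \
        else math.sqrt(config.frame_area)
    return float(_center_distances(pairs).mean() / denom)


def precision(pairs) -> float:
    """Mean Euclidean centre distance in pixels."""
    pairs = list(pairs)
    if not pairs:
        raise UndefinedMetricError("precision over empty pair set")
    return float(_center_distances(pairs).mean())


@dataclass
class TrackEvalReport:
    overall: dict
    per_condition: dict[str, dict]
    n_missing_frames: int
    n_frames: int

    def to_dict(self) -> dict:
        return {"overall": self.overall, "per_condition": self.per_condition,
                "n_missing_frames": self.n_missing_frames,
                "n_frames": self.n_frames}


def read_lasot(path) -> dict[int, Box]:
    """LaSOT-style ground truth: one 'x,y,w,h' line per frame, frames
    numbered from 1."""
    out: dict[int, Box] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            x, y, w, h = (float(v) for v in line.split(","))
            out[i] = (x, y, w, h)
    return out


def _boxes_by_frame(path) -> dict[int, Box]:
    """Load a single-target track from MOT CSV or LaSOT text; with
    multiple detections per frame the highest-confidence one wins."""
    try:
        records = read_mot(path)
    except Exception:
        return read_lasot(path)
    out: dict[int, Box] = {}
    best: dict[int, float] = {}
    for r in records:
        if r.frame not in out or r.conf > best[r.frame]:
            out[r.frame] = r.box
            best[r.frame] = r.conf
    return out


def _metrics(pairs, config) -> dict:
    return {"success": success(pairs, config),
            "norm_precision": norm_precision(pairs, config),
            "precision": precision(pairs),
            "n_frames": len(pairs)}


def evaluate_tracks(pred_file, truth_file, config: TrackEvalConfig,
                    condition_labels: dict[int, str] | None = None) -> TrackEvalReport:
    """Align a predicted track with ground truth frame-by-frame and
    report Success / Norm-Precision / Precision overall and per
    condition label (e.g. day/night).

    Truth frames with no prediction count as Success failures and are
    excluded from the two distance means (their count is reported).
    """
    pred = _boxes_by_frame(pred_file)
    truth = _boxes_by_frame(truth_file)
    if not truth or not (set(truth) & set(pred)):
        raise AlignmentError("prediction and truth share no frames")

    matched: list[BoxPair] = []
    n_missing = 0
    missing_frames: list[int] = []
    for frame in sorted(truth):
        if frame in pred:
            matched.append(BoxPair(frame, pred[frame], truth[frame]))
        else:
            n_missing += 1
            missing_frames.append(frame)

    n_truth = len(truth)
    overall = _metrics(matched, config)
    # missing frames fail the IoU test but cannot contribute a distance
    overall["success"] = overall["success"] * len(matched) / n_truth
    overall["n_frames"] = n_truth

    per_condition: dict[str, dict] = {}
    if condition_labels:
        by_label: dict[str, list[BoxPair]] = {}
        miss_by_label: dict[str, int] = {}
        for p in matched:
            by_label.setdefault(condition_labels.get(p.frame, "unlabelled"),
                                []).append(p)
        for frame in missing_frames:
            lbl = condition_labels.get(frame, "unlabelled")
            miss_by_label[lbl] = miss_by_label.get(lbl, 0) + 1
        for label, ps in by_label.items():
            m = _metrics(ps, config)
            n_lbl = len(ps) + miss_by_label.get(label, 0)
            m["success"] = m["success"] * len(ps) / n_lbl
            m["n_frames"] = n_lbl
            per_condition[label] = m
    return TrackEvalReport(overall=overall, per_condition=per_condition,
                           n_missing_frames=n_missing, n_frames=n_truth)
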