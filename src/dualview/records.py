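"""Detection records and MOT-style CSV I/O shared by the simulator, the
cross-view mapper and the tracking evaluator."""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .errors import InvalidArgumentError, ParseError


class TagClass(enum.Enum):
    """Ear-tag visibility class of a detection."""

    tag_visible = 1
    tag_not_visible = 2


@dataclass(frozen=True)
class DetectionRecord:
    """One bounding box: frame index, identity (−1 when unknown), box as
    (x_left, y_top, w, h) in pixels, tag-visibility class, confidence."""

    frame: int
    id: int
    box: tuple[float, float, float, float]
    cls: TagClass = TagClass.tag_visible
    conf: float = 1.0

    def __post_init__(self):
        x, y, w, h = self.box
        if w < 0 or h < 0:
            raise InvalidArgumentError(f"negative box size {(w, h)}")
        if not 0.0 <= self.conf <= 1.0:
            raise InvalidArgumentError(f"confidence {self.conf} outside [0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        x, y, w, h = self.box
        return (x + w / 2.0, y + h / 2.0)


MOT_COLUMNS = ["frame", "id", "x", "y", "w", "h", "conf", "class", "vis"]


def write_mot(records, path) -> None:
    """Write detections as MOT-17-style CSV lines
    ``frame,id,x,y,w,h,conf,class,vis`` (no header)."""
    rows = [(r.frame, r.id, *r.box, r.conf, r.cls.value, 1.0) for r in records]
    df = pd.DataFrame(rows, columns=MOT_COLUMNS)
    df.to_csv(path, header=False, index=False)


def read_mot(path) -> list[DetectionRecord]:
    """Read a MOT-17-style CSV; raises :class:`ParseError` with the line
    number on malformed input."""
    out: list[DetectionRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 8:
                raise ParseError(f"expected ≥ 8 fields, got {len(parts)}", ln)
            try:
                frame, ident = int(parts[0]), int(parts[1])
                x, y, w, h, conf = map(float, parts[2:7])
                cls = TagClass(int(parts[7]))
            except (ValueError, KeyError) as exc:
                raise ParseError(str(exc), ln) from exc
            out.append(DetectionRecord(frame=frame, id=ident, box=(x, y, w, h),
                                       cls=cls, conf=conf))
    return out
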