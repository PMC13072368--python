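"""Domain types and file I/O for mouth bounding boxes and tracks.

Boxes are stored in corner form ``(x1, y1)``–``(x2, y2)`` in pixel units,
x rightward, y downward, frames 1-based. On disk the package speaks the
MOT-challenge plain-text dialect (one box per line:
``frame,id,bb_left,bb_top,bb_width,bb_height,conf,x,y,z``), with optional
JSON-lines sidecars for per-detection appearance vectors and per-frame
affine camera transforms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "BoxRecord",
    "AffineTransform",
    "SceneBundle",
    "read_mot",
    "write_mot",
    "read_appearance_sidecar",
    "write_appearance_sidecar",
    "read_transform_sidecar",
    "write_transform_sidecar",
    "box_iou",
    "box_dims",
]


class MOTParseError(ValueError):
    """Raised when a MOT-dialect line cannot be parsed."""


@dataclass(frozen=True)
class BoxRecord:
    """One time-stamped axis-aligned bounding box.

    Either a raw detection (``identity`` is None) or one frame of a track
    (``identity`` set). ``appearance`` is an optional re-identification
    feature vector describing the target's visual appearance.
    """

    frame_index: int
    x1: float
    y1: float
    x2: float
    y2: float
    identity: int | None = None
    confidence: float | None = None
    appearance: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.frame_index < 1:
            raise ValueError(f"frame_index must be >= 1, got {self.frame_index}")
        for name in ("x1", "y1", "x2", "y2"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite coordinate {name}={v}")
        if self.x2 < self.x1 or self.y2 < self.y1:
            raise ValueError(
                f"degenerate box: ({self.x1},{self.y1})-({self.x2},{self.y2})"
            )
        if self.identity is not None and self.identity < 0:
            raise ValueError(f"identity must be non-negative, got {self.identity}")
        if self.confidence is not None and not math.isfinite(self.confidence):
            raise ValueError("non-finite confidence")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    def with_identity(self, identity: int) -> "BoxRecord":
        return replace(self, identity=identity)


@dataclass(frozen=True)
class AffineTransform:
    """2x3 affine map from the previous frame's pixel coordinates to this frame's.

    Used for camera motion compensation: a tracker's state predicted in
    frame ``t-1`` coordinates is mapped through the frame-``t`` transform
    before association.
    """

    frame_index: int
    matrix: tuple[tuple[float, float, float], tuple[float, float, float]]

    def __post_init__(self) -> None:
        if self.frame_index < 1:
            raise ValueError("frame_index must be >= 1")
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3) or not np.all(np.isfinite(m)):
            raise ValueError("matrix must be a finite 2x3 array")

    @classmethod
    def identity(cls, frame_index: int) -> "AffineTransform":
        return cls(frame_index, ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)))

    @classmethod
    def translation(cls, frame_index: int, dx: float, dy: float) -> "AffineTransform":
        return cls(frame_index, ((1.0, 0.0, dx), (0.0, 1.0, dy)))

    @property
    def linear(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)[:, :2]

    @property
    def offset(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)[:, 2]

    def apply_point(self, x: float, y: float) -> tuple[float, float]:
        p = self.linear @ np.array([x, y]) + self.offset
        return (float(p[0]), float(p[1]))

    def apply_box(self, rec: BoxRecord) -> BoxRecord:
        x1, y1 = self.apply_point(rec.x1, rec.y1)
        x2, y2 = self.apply_point(rec.x2, rec.y2)
        return replace(
            rec,
            x1=min(x1, x2),
            y1=min(y1, y2),
            x2=max(x1, x2),
            y2=max(y1, y2),
        )


@dataclass
class SceneBundle:
    """Everything one scene needs: detections, optional ground truth, transforms."""

    detections: list[BoxRecord] = field(default_factory=list)
    gt_tracks: list[BoxRecord] | None = None
    transforms: list[AffineTransform] | None = None
    fps: float = 25.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        self.detections = sorted(self.detections, key=_sort_key)
        if self.gt_tracks is not None:
            self.gt_tracks = sorted(self.gt_tracks, key=_sort_key)
        if self.transforms is not None:
            self.transforms = sorted(self.transforms, key=lambda t: t.frame_index)

    def transform_for(self, frame_index: int) -> AffineTransform | None:
        if self.transforms is None:
            return None
        for t in self.transforms:
            if t.frame_index == frame_index:
                return t
        return None


def _sort_key(r: BoxRecord) -> tuple[int, int]:
    return (r.frame_index, -1 if r.identity is None else r.identity)


# ---------------------------------------------------------------------------
# MOT-challenge dialect
# ---------------------------------------------------------------------------

def read_mot(path: str | Path, kind: Literal["detection", "track"] = "detection") -> list[BoxRecord]:
    """Read a MOT-challenge text file into :class:`BoxRecord` objects.

    ``kind='detection'`` drops the id column (conventionally -1);
    ``kind='track'`` requires a non-negative id on every line. World
    coordinate columns (x, y, z), if present, are ignored.
    """
    if kind not in ("detection", "track"):
        raise ValueError(f"kind must be 'detection' or 'track', got {kind!r}")
    records: list[BoxRecord] = []
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 7:
                raise MOTParseError(
                    f"{path}:{lineno}: expected >=7 comma-separated fields, got {len(parts)}"
                )
            try:
                frame = int(float(parts[0]))
                ident = int(float(parts[1]))
                left, top, w, h, conf = (float(p) for p in parts[2:7])
            except ValueError as exc:
                raise MOTParseError(f"{path}:{lineno}: {exc}") from None
            if w < 0 or h < 0:
                raise MOTParseError(
                    f"{path}:{lineno}: negative box dimensions ({w}, {h})"
                )
            if kind == "track" and ident < 0:
                raise MOTParseError(f"{path}:{lineno}: track line with id {ident}")
            records.append(
                BoxRecord(
                    frame_index=frame,
                    x1=left,
                    y1=top,
                    x2=left + w,
                    y2=top + h,
                    identity=None if (kind == "detection" or ident < 0) else ident,
                    confidence=conf,
                )
            )
    return sorted(records, key=_sort_key)


def write_mot(records: Iterable[BoxRecord], path: str | Path) -> None:
    """Write records in the MOT-challenge dialect (sorted by frame, id).

    Missing identities are written as -1, missing confidences as 1; the
    world-coordinate columns are written as -1.
    """
    recs = sorted(records, key=_sort_key)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for r in recs:
            ident = -1 if r.identity is None else r.identity
            conf = 1 if r.confidence is None else r.confidence
            fh.write(
                f"{r.frame_index},{ident},{_fmt(r.x1)},{_fmt(r.y1)},"
                f"{_fmt(r.width)},{_fmt(r.height)},{_fmt(conf)},-1,-1,-1\n"
            )


def _fmt(v: float) -> str:
    # integers print without a trailing .0 so files stay diff-friendly
    if float(v) == int(v):
        return str(int(v))
    return repr(float(v))


def write_appearance_sidecar(records: Sequence[BoxRecord], path: str | Path) -> None:
    """JSON-lines sidecar of appearance vectors keyed by (frame, within-frame index)."""
    by_frame: dict[int, int] = {}
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in sorted(records, key=_sort_key):
            idx = by_frame.get(r.frame_index, 0)
            by_frame[r.frame_index] = idx + 1
            if r.appearance is None:
                continue
            fh.write(
                json.dumps(
                    {"frame": r.frame_index, "index": idx, "vector": list(r.appearance)}
                )
                + "\n"
            )


def read_appearance_sidecar(
    records: Sequence[BoxRecord], path: str | Path
) -> list[BoxRecord]:
    """Attach sidecar appearance vectors to records by (frame, within-frame index)."""
    table: dict[tuple[int, int], tuple[float, ...]] = {}
    dim: int | None = None
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            obj = json.loads(line)
            vec = tuple(float(v) for v in obj["vector"])
            if dim is None:
                dim = len(vec)
            elif len(vec) != dim:
                raise ValueError(
                    f"{path}:{lineno}: appearance vector length {len(vec)} != {dim}"
                )
            table[(int(obj["frame"]), int(obj["index"]))] = vec
    out: list[BoxRecord] = []
    by_frame: dict[int, int] = {}
    for r in sorted(records, key=_sort_key):
        idx = by_frame.get(r.frame_index, 0)
        by_frame[r.frame_index] = idx + 1
        vec = table.get((r.frame_index, idx))
        out.append(replace(r, appearance=vec) if vec is not None else r)
    return out


def write_transform_sidecar(
    transforms: Sequence[AffineTransform], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for t in sorted(transforms, key=lambda t: t.frame_index):
            fh.write(
                json.dumps(
                    {"frame": t.frame_index, "matrix": [list(row) for row in t.matrix]}
                )
                + "\n"
            )


def read_transform_sidecar(path: str | Path) -> list[AffineTransform]:
    out: list[AffineTransform] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            obj = json.loads(line)
            m = obj["matrix"]
            out.append(
                AffineTransform(
                    int(obj["frame"]),
                    (tuple(float(v) for v in m[0]), tuple(float(v) for v in m[1])),
                )
            )
    return sorted(out, key=lambda t: t.frame_index)


# ---------------------------------------------------------------------------
# Box geometry
# ---------------------------------------------------------------------------

def box_iou(a: BoxRecord, b: BoxRecord) -> float:
    """Intersection-over-union of two axis-aligned boxes, in [0, 1].

    Zero-area boxes have IoU 0 with everything (including themselves).
    """
    iw = min(a.x2, b.x2) - max(a.x1, b.x1)
    ih = min(a.y2, b.y2) - max(a.y1, b.y1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.width * a.height + b.width * b.height - inter
    if union <= 0:
        return 0.0
    return float(inter / union)


def box_dims(b: BoxRecord) -> tuple[float, float]:
    """Width X = x2 - x1 and height Y = y2 - y1 of a box, in pixels."""
    return (b.x2 - b.x1, b.y2 - b.y1)
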