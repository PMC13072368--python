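"""BoT-SORT-style multi-object tracking of mouth bounding boxes.

Per frame the tracker (1) advances every live track one step with a
constant-velocity Kalman filter, (2) optionally maps the prediction through
a supplied affine camera-motion transform, (3) associates predictions with
detections in two stages — IoU assignment over high-confidence detections,
then appearance (cosine-distance) matching of the leftovers, falling back
to IoU over low-confidence detections when no appearance vectors are
available — and (4) manages the tracklet lifecycle (birth, confirmation,
coasting, removal).

The Kalman state is (cx, cy, w, h) plus per-frame velocities, with SORT
lineage noise scales proportional to box height. Association is solved
optimally with the Hungarian algorithm. The tracker is fully deterministic:
identical input yields bit-identical output, and identities are positive
integers assigned in creation order, never reused.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import AffineTransform, BoxRecord, SceneBundle, box_iou

__all__ = [
    "TrackStatus",
    "TrackState",
    "TrackerConfig",
    "predict",
    "associate",
    "step",
    "run_tracker",
    "MouthTracker",
]

# SORT-lineage measurement/process noise weights (relative to box height)
_STD_WEIGHT_POS = 1.0 / 20.0
_STD_WEIGHT_VEL = 1.0 / 160.0

_F = np.eye(8)
_F[:4, 4:] = np.eye(4)  # constant-velocity transition
_H = np.eye(4, 8)


class TrackStatus(enum.Enum):
    TENTATIVE = "tentative"
    ACTIVE = "active"
    REMOVED = "removed"


@dataclass
class TrackState:
    """One tracklet: Kalman state, identity and lifecycle counters."""

    identity: int
    mean: np.ndarray  # (cx, cy, w, h, vcx, vcy, vw, vh)
    covariance: np.ndarray  # 8x8
    age: int = 0  # frames since last update
    hits: int = 1  # total updates
    status: TrackStatus = TrackStatus.TENTATIVE
    appearance: np.ndarray | None = None
    last_confidence: float | None = None

    @classmethod
    def from_detection(cls, identity: int, det: BoxRecord) -> "TrackState":
        cx, cy = det.center
        w, h = det.width, det.height
        mean = np.array([cx, cy, w, h, 0.0, 0.0, 0.0, 0.0])
        scale = max(h, 1.0)
        std = np.array(
            [2 * _STD_WEIGHT_POS * scale] * 4 + [10 * _STD_WEIGHT_VEL * scale] * 4
        )
        app = None
        if det.appearance is not None:
            app = _unit(np.asarray(det.appearance, dtype=float))
        return cls(
            identity=identity,
            mean=mean,
            covariance=np.diag(std**2),
            appearance=app,
            last_confidence=det.confidence,
        )

    def to_box(self, frame_index: int) -> BoxRecord:
        cx, cy, w, h = self.mean[:4]
        w = max(w, 0.0)
        h = max(h, 0.0)
        return BoxRecord(
            frame_index=frame_index,
            x1=cx - w / 2,
            y1=cy - h / 2,
            x2=cx + w / 2,
            y2=cy + h / 2,
            identity=self.identity,
            confidence=self.last_confidence,
        )

    def kalman_predict(self) -> None:
        scale = max(self.mean[3], 1.0)
        q = np.array(
            [_STD_WEIGHT_POS * scale] * 4 + [_STD_WEIGHT_VEL * scale] * 4
        )
        self.mean = _F @ self.mean
        self.covariance = _F @ self.covariance @ _F.T + np.diag(q**2)
        self.mean[2] = max(self.mean[2], 0.0)
        self.mean[3] = max(self.mean[3], 0.0)
        self.age += 1

    def apply_transform(self, t: AffineTransform) -> None:
        R = t.linear
        # positions map affinely, velocities through the linear part only
        self.mean[:2] = R @ self.mean[:2] + t.offset
        self.mean[4:6] = R @ self.mean[4:6]
        # width/height pick up the axis scales of the linear part
        sx = float(np.hypot(R[0, 0], R[1, 0]))
        sy = float(np.hypot(R[0, 1], R[1, 1]))
        self.mean[2] *= sx
        self.mean[3] *= sy
        self.mean[6] *= sx
        self.mean[7] *= sy
        R8 = np.eye(8)
        R8[0:2, 0:2] = R
        R8[4:6, 4:6] = R
        self.covariance = R8 @ self.covariance @ R8.T

    def kalman_update(self, det: BoxRecord) -> None:
        cx, cy = det.center
        z = np.array([cx, cy, det.width, det.height])
        scale = max(self.mean[3], 1.0)
        r = np.diag(np.full(4, (_STD_WEIGHT_POS * scale) ** 2))
        S = _H @ self.covariance @ _H.T + r
        K = self.covariance @ _H.T @ np.linalg.solve(S, np.eye(4))
        self.mean = self.mean + K @ (z - _H @ self.mean)
        self.covariance = (np.eye(8) - K @ _H) @ self.covariance
        self.mean[2] = max(self.mean[2], 0.0)
        self.mean[3] = max(self.mean[3], 0.0)
        self.age = 0
        self.hits += 1
        self.last_confidence = det.confidence


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


@dataclass(frozen=True)
class TrackerConfig:
    """Tunable tracker thresholds (none are dictated by the method itself)."""

    iou_match_threshold: float = 0.3
    high_conf_threshold: float = 0.5
    appearance_distance_threshold: float = 0.4
    max_age: int = 30
    min_hits: int = 3
    appearance_momentum: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.iou_match_threshold <= 1):
            raise ValueError("iou_match_threshold must be in (0, 1]")
        if not (0 <= self.appearance_momentum <= 1):
            raise ValueError("appearance_momentum must be in [0, 1]")
        if self.max_age < 1 or self.min_hits < 1:
            raise ValueError("max_age and min_hits must be >= 1")


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def predict(
    states: Sequence[TrackState], transform: AffineTransform | None = None
) -> list[TrackState]:
    """Advance every track one frame; map through the camera transform if given."""
    for s in states:
        s.kalman_predict()
        if transform is not None:
            s.apply_transform(transform)
    return list(states)


def _solve_iou(
    tracks: Sequence[TrackState],
    track_boxes: Sequence[BoxRecord],
    detections: Sequence[BoxRecord],
    iou_threshold: float,
) -> list[tuple[int, int]]:
    if not tracks or not detections:
        return []
    iou = np.zeros((len(tracks), len(detections)))
    for i, tb in enumerate(track_boxes):
        for j, d in enumerate(detections):
            iou[i, j] = box_iou(tb, d)
    rows, cols = linear_sum_assignment(-iou)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if iou[i, j] >= iou_threshold]


def associate(
    tracks: Sequence[TrackState],
    detections: Sequence[BoxRecord],
    config: TrackerConfig = TrackerConfig(),
    frame_index: int | None = None,
) -> tuple[list[tuple[TrackState, BoxRecord]], list[TrackState], list[BoxRecord]]:
    """Two-stage association of predicted tracks with one frame's detections.

    Stage 1 optimally matches predicted boxes to high-confidence detections
    by IoU. Stage 2 matches the remainder by cosine distance between track
    and detection appearance vectors; when appearance is unavailable it
    repeats IoU matching over the remaining (low-confidence) detections.

    Returns (matches, unmatched_tracks, unmatched_detections).
    """
    detections = list(detections)
    if detections:
        frames = {d.frame_index for d in detections}
        if len(frames) > 1:
            raise ValueError(f"detections span multiple frames: {sorted(frames)}")
        if frame_index is None:
            frame_index = detections[0].frame_index
        dims = {len(d.appearance) for d in detections if d.appearance is not None}
        if len(dims) > 1:
            raise ValueError(f"appearance vectors of unequal length: {sorted(dims)}")
    fi = frame_index if frame_index is not None else 1
    tracks = list(tracks)
    track_boxes = [t.to_box(fi) for t in tracks]

    high = [
        j
        for j, d in enumerate(detections)
        if (d.confidence if d.confidence is not None else 1.0)
        >= config.high_conf_threshold
    ]
    low = [j for j in range(len(detections)) if j not in high]

    matches: list[tuple[TrackState, BoxRecord]] = []
    pairs = _solve_iou(
        tracks,
        track_boxes,
        [detections[j] for j in high],
        config.iou_match_threshold,
    )
    matched_t = set()
    matched_d = set()
    for ti, hj in pairs:
        dj = high[hj]
        matches.append((tracks[ti], detections[dj]))
        matched_t.add(ti)
        matched_d.add(dj)

    rem_t = [i for i in range(len(tracks)) if i not in matched_t]
    rem_d = [j for j in range(len(detections)) if j not in matched_d]

    # stage 2: appearance re-association, or ByteTrack-style low-conf IoU
    app_t = [i for i in rem_t if tracks[i].appearance is not None]
    app_d = [j for j in rem_d if detections[j].appearance is not None]
    if app_t and app_d:
        cost = np.zeros((len(app_t), len(app_d)))
        for a, i in enumerate(app_t):
            for b, j in enumerate(app_d):
                det_app = _unit(np.asarray(detections[j].appearance, dtype=float))
                cost[a, b] = 1.0 - float(tracks[i].appearance @ det_app)
        rows, cols = linear_sum_assignment(cost)
        for a, b in zip(rows, cols):
            if cost[a, b] <= config.appearance_distance_threshold:
                ti, dj = app_t[a], app_d[b]
                matches.append((tracks[ti], detections[dj]))
                matched_t.add(ti)
                matched_d.add(dj)
    else:
        low_rem = [j for j in rem_d if j in low]
        pairs = _solve_iou(
            [tracks[i] for i in rem_t],
            [track_boxes[i] for i in rem_t],
            [detections[j] for j in low_rem],
            config.iou_match_threshold,
        )
        for a, b in pairs:
            ti, dj = rem_t[a], low_rem[b]
            matches.append((tracks[ti], detections[dj]))
            matched_t.add(ti)
            matched_d.add(dj)

    unmatched_tracks = [tracks[i] for i in range(len(tracks)) if i not in matched_t]
    unmatched_dets = [
        detections[j] for j in range(len(detections)) if j not in matched_d
    ]
    return matches, unmatched_tracks, unmatched_dets


@dataclass
class MouthTracker:
    """Stateful frame-by-frame tracker; `run_tracker` is the batch entry point."""

    config: TrackerConfig = field(default_factory=TrackerConfig)
    states: list[TrackState] = field(default_factory=list)
    next_identity: int = 1
    _first_frame_seen: bool = False

    def step(
        self,
        detections: Sequence[BoxRecord],
        frame_index: int,
        transform: AffineTransform | None = None,
    ) -> list[BoxRecord]:
        """Process one frame; returns the boxes emitted for confirmed tracks."""
        cfg = self.config
        predict(self.states, transform)
        matches, unmatched_tracks, unmatched_dets = associate(
            self.states, detections, cfg, frame_index=frame_index
        )

        for track, det in matches:
            track.kalman_update(det)
            if det.appearance is not None:
                det_app = _unit(np.asarray(det.appearance, dtype=float))
                if track.appearance is None:
                    track.appearance = det_app
                else:
                    track.appearance = _unit(
                        cfg.appearance_momentum * track.appearance
                        + (1 - cfg.appearance_momentum) * det_app
                    )
            if track.status is TrackStatus.TENTATIVE and track.hits >= cfg.min_hits:
                track.status = TrackStatus.ACTIVE

        for track in unmatched_tracks:
            if track.age > cfg.max_age:
                track.status = TrackStatus.REMOVED

        for det in unmatched_dets:
            t = TrackState.from_detection(self.next_identity, det)
            self.next_identity += 1
            # targets present when tracking starts are trusted immediately
            if not self._first_frame_seen:
                t.status = TrackStatus.ACTIVE
                t.hits = cfg.min_hits
            self.states.append(t)

        emitted = [
            t.to_box(frame_index)
            for t in self.states
            if t.status is TrackStatus.ACTIVE
        ]
        self.states = [t for t in self.states if t.status is not TrackStatus.REMOVED]
        self._first_frame_seen = True
        return sorted(emitted, key=lambda r: (r.frame_index, r.identity))


def step(
    states: list[TrackState],
    detections: Sequence[BoxRecord],
    transform: AffineTransform | None = None,
    config: TrackerConfig = TrackerConfig(),
    frame_index: int | None = None,
) -> tuple[list[TrackState], list[BoxRecord]]:
    """Single-frame functional wrapper around :class:`MouthTracker`.

    The next fresh identity is inferred as one past the largest in use.
    """
    if frame_index is None:
        frame_index = detections[0].frame_index if detections else 1
    trk = MouthTracker(config=config, states=list(states))
    trk.next_identity = max((s.identity for s in states), default=0) + 1
    trk._first_frame_seen = True
    emitted = trk.step(detections, frame_index, transform)
    return trk.states, emitted


def run_tracker(
    scene: SceneBundle, config: TrackerConfig = TrackerConfig()
) -> list[BoxRecord]:
    """Track a whole scene's detections into identity-consistent trajectories."""
    if not scene.detections:
        return []
    by_frame: dict[int, list[BoxRecord]] = {}
    for d in scene.detections:
        by_frame.setdefault(d.frame_index, []).append(d)
    first = min(by_frame)
    last = max(by_frame)
    transforms = {
        t.frame_index: t for t in (scene.transforms or [])
    }
    tracker = MouthTracker(config=config)
    out: list[BoxRecord] = []
    for frame in range(first, last + 1):
        out.extend(
            tracker.step(
                by_frame.get(frame, []), frame, transforms.get(frame)
            )
        )
    return sorted(out, key=lambda r: (r.frame_index, r.identity))
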