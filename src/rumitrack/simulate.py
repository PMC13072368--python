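"""Seeded synthetic rumination scenes.

The generator emulates what the camera pipeline sees: per-cow mouth
bounding boxes whose width+height signal H oscillates once per chewing
cycle (one raised-cosine arch per cycle, cycle periods drawn uniformly
from 18–25 frames at 25 fps), organised into chewing bouts of 70–86 s
separated by flat swallowing pauses of 2–6 s. Detections are derived from
the ground truth by adding Gaussian corner noise, dropping boxes at a miss
rate, sampling confidences, and attaching per-cow appearance vectors;
optional sinusoidal camera jitter translates the whole scene, with the
exact per-frame affine transforms recorded so camera motion compensation
can be exercised end to end.

Everything is deterministic under a fixed seed. Ground truth (true chew
counts, chewing frame spans, bout/pause boundaries, injected transforms)
is recorded next to the emitted records so every downstream module can be
scored without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import AffineTransform, BoxRecord, SceneBundle, box_iou

__all__ = [
    "SimConfig",
    "CowGroundTruth",
    "SimGroundTruth",
    "simulate_cow",
    "simulate_scene",
    "occlude",
]

_JITTER_PERIOD_FRAMES = 50  # period of the sinusoidal camera sway


@dataclass(frozen=True)
class SimConfig:
    """Scene parameters. Defaults describe a typical single-cow recording."""

    n_cows: int = 1
    fps: float = 25.0
    duration_s: float = 80.0
    cycle_period_frames: tuple[int, int] = (18, 25)
    bout_length_s: tuple[float, float] = (70.0, 86.0)
    pause_length_s: tuple[float, float] = (2.0, 6.0)
    base_box: tuple[float, float] = (60.0, 50.0)
    chew_amplitude: float = 20.0
    noise_sd: float = 0.0
    miss_rate: float = 0.0
    conf_model: tuple[float, float] = (0.9, 0.05)
    camera_jitter_amp: float = 0.0
    appearance_dim: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cows < 1:
            raise ValueError("n_cows must be >= 1")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration_s must be positive")
        lo, hi = self.cycle_period_frames
        if not (2 <= lo <= hi):
            raise ValueError("cycle_period_frames range invalid")
        if not (0 <= self.miss_rate <= 1):
            raise ValueError("miss_rate must be a probability")
        if self.chew_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("chew_amplitude and noise_sd must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class CowGroundTruth:
    """Per-cow truth: what a perfect analysis should recover."""

    identity: int
    chew_count: int
    chew_frames: int  # frames covered by chewing cycles (pauses excluded)
    bouts: list[tuple[int, int]] = field(default_factory=list)  # 1-based, inclusive
    pauses: list[tuple[int, int]] = field(default_factory=list)
    cycles: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SimGroundTruth:
    cows: list[CowGroundTruth] = field(default_factory=list)


def _h_waveform(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, CowGroundTruth]:
    """H oscillation offset per frame plus the truth that generated it.

    Bouts alternate with pauses; each bout is tiled with raised-cosine
    chewing cycles (one arch per cycle, zero at the cycle boundaries), and
    frames that cannot fit one more full cycle stay flat.
    """
    n = config.n_frames
    h = np.zeros(n)
    truth = CowGroundTruth(identity=0, chew_count=0, chew_frames=0)
    lo_p, hi_p = config.cycle_period_frames
    t = 0
    in_bout = True
    while t < n:
        if in_bout:
            length = int(round(rng.uniform(*config.bout_length_s) * config.fps))
            end = min(t + length, n)
            c = t
            while True:
                period = int(rng.integers(lo_p, hi_p + 1))
                if c + period > end:
                    break
                tt = np.arange(period)
                h[c : c + period] = config.chew_amplitude * (
                    1.0 - np.cos(2.0 * np.pi * tt / period)
                )
                truth.cycles.append((c + 1, c + period))
                truth.chew_count += 1
                truth.chew_frames += period
                c += period
            if c > t:
                truth.bouts.append((t + 1, c))
            t = end
        else:
            length = int(round(rng.uniform(*config.pause_length_s) * config.fps))
            end = min(t + length, n)
            truth.pauses.append((t + 1, end))
            t = end
        in_bout = not in_bout
    return h, truth


def simulate_cow(
    config: SimConfig,
    cow_index: int = 0,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[list[BoxRecord], CowGroundTruth]:
    """Noiseless ground-truth trajectory for one cow.

    The mouth-box center stays fixed; width and height each carry half of
    the H oscillation, so H = width + height follows the cycle train
    exactly. Frames are 1-based; exactly ``duration_s * fps`` records are
    emitted.
    """
    if seed is None:
        seed = np.random.SeedSequence([config.seed, cow_index])
    rng = np.random.default_rng(seed)
    h, truth = _h_waveform(config, rng)
    identity = cow_index + 1
    truth.identity = identity

    bw, bh = config.base_box
    x0 = 50.0 + cow_index * 3.0 * bw
    y0 = 100.0
    cx = x0 + bw / 2
    cy = y0 + bh / 2
    records = []
    for t in range(config.n_frames):
        w = bw + h[t] / 2
        hh = bh + h[t] / 2
        records.append(
            BoxRecord(
                frame_index=t + 1,
                x1=cx - w / 2,
                y1=cy - hh / 2,
                x2=cx + w / 2,
                y2=cy + hh / 2,
                identity=identity,
            )
        )
    return records, truth


def _jitter_offsets(config: SimConfig) -> np.ndarray:
    """Shared sinusoidal camera translation per frame, shape (n_frames, 2)."""
    t = np.arange(config.n_frames)
    amp = config.camera_jitter_amp
    phase = 2.0 * np.pi * t / _JITTER_PERIOD_FRAMES
    return np.column_stack([amp * np.sin(phase), amp * np.cos(phase) - amp])


def simulate_scene(config: SimConfig) -> tuple[SceneBundle, SimGroundTruth]:
    """Full multi-cow scene: ground truth, transforms and degraded detections."""
    root = np.random.SeedSequence(config.seed)
    cow_seeds = root.spawn(config.n_cows)
    noise_rng = np.random.default_rng(root.spawn(1)[0])

    gt: list[BoxRecord] = []
    truth = SimGroundTruth()
    centers = []
    for i in range(config.n_cows):
        recs, cow_truth = simulate_cow(config, i, cow_seeds[i])
        # placement sanity: maximal extents of different cows must not touch
        widest = max(recs, key=lambda r: r.width)
        for other in centers:
            if box_iou(widest, other) > 0:
                raise ValueError(
                    f"cow {i} overlaps a neighbour at n_cows={config.n_cows}; "
                    "request fewer cows or widen base_box spacing"
                )
        centers.append(widest)
        gt.extend(recs)
        truth.cows.append(cow_truth)

    transforms: list[AffineTransform] | None = None
    if config.camera_jitter_amp > 0:
        offsets = _jitter_offsets(config)
        gt = [
            BoxRecord(
                frame_index=r.frame_index,
                x1=r.x1 + offsets[r.frame_index - 1, 0],
                y1=r.y1 + offsets[r.frame_index - 1, 1],
                x2=r.x2 + offsets[r.frame_index - 1, 0],
                y2=r.y2 + offsets[r.frame_index - 1, 1],
                identity=r.identity,
            )
            for r in gt
        ]
        transforms = [AffineTransform.identity(1)] + [
            AffineTransform.translation(
                t + 1,
                float(offsets[t, 0] - offsets[t - 1, 0]),
                float(offsets[t, 1] - offsets[t - 1, 1]),
            )
            for t in range(1, config.n_frames)
        ]

    # appearance cluster center per cow (unit norm)
    app_centers = {}
    for i in range(config.n_cows):
        v = noise_rng.normal(size=config.appearance_dim)
        app_centers[i + 1] = v / np.linalg.norm(v)

    detections: list[BoxRecord] = []
    conf_mean, conf_sd = config.conf_model
    for r in gt:
        if config.miss_rate > 0 and noise_rng.random() < config.miss_rate:
            continue
        if config.noise_sd > 0:
            dx1, dy1, dx2, dy2 = noise_rng.normal(0.0, config.noise_sd, size=4)
        else:
            dx1 = dy1 = dx2 = dy2 = 0.0
        x1, x2 = sorted((r.x1 + dx1, r.x2 + dx2))
        y1, y2 = sorted((r.y1 + dy1, r.y2 + dy2))
        conf = float(np.clip(noise_rng.normal(conf_mean, conf_sd), 0.05, 1.0))
        app = app_centers[r.identity] + noise_rng.normal(
            0.0, 0.05, size=config.appearance_dim
        )
        app = app / np.linalg.norm(app)
        detections.append(
            BoxRecord(
                frame_index=r.frame_index,
                x1=x1,
                y1=y1,
                x2=x2,
                y2=y2,
                confidence=conf,
                appearance=tuple(float(v) for v in app),
            )
        )

    bundle = SceneBundle(
        detections=detections,
        gt_tracks=gt,
        transforms=transforms,
        fps=config.fps,
    )
    return bundle, truth


def occlude(
    detections: list[BoxRecord],
    start_frame: int,
    end_frame: int,
    cow_gt: list[BoxRecord],
    iou_threshold: float = 0.5,
) -> list[BoxRecord]:
    """Drop one cow's detections inside [start_frame, end_frame].

    Detections carry no identity, so the occluded cow is named by its
    ground-truth records: any detection in the frame range that overlaps
    that cow's ground-truth box (IoU above threshold) is removed. Ground
    truth itself is untouched — occlusion hides the target from the
    detector, not from reality.
    """
    if end_frame < start_frame:
        return list(detections)
    gt_by_frame = {r.frame_index: r for r in cow_gt}
    out = []
    for d in detections:
        if start_frame <= d.frame_index <= end_frame:
            g = gt_by_frame.get(d.frame_index)
            if g is not None and box_iou(d, g) > iou_threshold:
                continue
        out.append(d)
    return out


def scene_frame_count(config: SimConfig) -> int:
    """Frames a recording of ``duration_s`` seconds yields at ``fps``."""
    return config.n_frames
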