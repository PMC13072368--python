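"""Chewing-signal extraction and chew counting from mouth-box trajectories.

Rumination shows up as a periodic open–close jaw motion that modulates the
geometry of the detected mouth bounding box. Per frame i the signal is

    H_i = X_i + Y_i,   X_i = x_i2 - x_i1 (width),  Y_i = y_i2 - y_i1 (height)

so H oscillates once per chewing cycle (one cycle spans roughly 18–25
frames at 25 fps). Chews are counted by a windowed alternating peak–valley
search over H:

1. the initial peak M_1 is the maximum of the first ``init_window`` frames;
2. the next valley m_i is the minimum of the ``search_window`` frames
   starting at the previous peak (inclusive);
3. the next peak M_{i+1} is the maximum of the ``search_window`` frames
   starting at m_i;
4. steps 2–3 repeat until the signal is exhausted.

When the candidate extremum falls on the last frame of its search window
while the signal is still running monotonically, the window is extended one
frame at a time until the turning point is inside it; a search that cannot
advance past the previous extremum (e.g. on a constant signal) ends the
iteration. One retained valley counts as one chew (one mouth opening
between two closures); the chewing duration in frames spans first to last
extremum inclusive.

Bout structure is read from the same signal: long near-constant stretches
of H are swallowing pauses (the bolus is being re-swallowed and the mouth
rests), and abrupt drops in H that are not part of a chew indicate the
animal changing its rumination angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .io import BoxRecord, box_dims

__all__ = [
    "ChewSignal",
    "ExtremaParams",
    "Extremum",
    "ExtremaSequence",
    "PhaseReport",
    "compute_signal",
    "extract_extrema",
    "detect_phases",
    "summarize",
]


@dataclass(frozen=True)
class ExtremaParams:
    """Windowed peak–valley search parameters (frames / pixels)."""

    init_window: int = 25
    search_window: int = 12
    min_amplitude: float = 0.0
    gap_fill: int = 5

    def __post_init__(self) -> None:
        if not (self.init_window >= self.search_window >= 2):
            raise ValueError("require init_window >= search_window >= 2")
        if self.min_amplitude < 0 or self.gap_fill < 0:
            raise ValueError("min_amplitude and gap_fill must be >= 0")


@dataclass
class ChewSignal:
    """Per-track chewing signal H indexed by (strictly increasing) frame."""

    identity: int | None
    frames: np.ndarray  # int, strictly increasing
    H: np.ndarray  # float, >= 0, same length

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.H = np.asarray(self.H, dtype=float)
        if self.frames.shape != self.H.shape:
            raise ValueError("frames and H must have equal length")
        if self.frames.size and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if np.any(~np.isfinite(self.H)) or np.any(self.H < 0):
            raise ValueError("H must be finite and non-negative")

    def __len__(self) -> int:
        return int(self.frames.size)

    def segments(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Contiguous (no missing frame) runs as (frames, H) pairs."""
        if not len(self):
            return []
        breaks = np.where(np.diff(self.frames) > 1)[0] + 1
        return [
            (f, h)
            for f, h in zip(
                np.split(self.frames, breaks), np.split(self.H, breaks)
            )
        ]


@dataclass(frozen=True)
class Extremum:
    frame: int
    value: float
    kind: Literal["peak", "valley"]


@dataclass
class ExtremaSequence:
    """Alternating peaks/valleys with the derived chew count and frame span.

    Within each contiguous signal segment the kinds strictly alternate
    starting with a peak, and every peak is at least as high as its
    neighbouring valleys.
    """

    extrema: list[Extremum] = field(default_factory=list)
    chew_count: int = 0
    chew_frames: int = 0

    @property
    def peaks(self) -> list[Extremum]:
        return [e for e in self.extrema if e.kind == "peak"]

    @property
    def valleys(self) -> list[Extremum]:
        return [e for e in self.extrema if e.kind == "valley"]


@dataclass
class PhaseReport:
    """Swallowing pauses and rumination-angle changes found in one signal."""

    swallow_segments: list[tuple[int, int]] = field(default_factory=list)
    angle_changes: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------


def compute_signal(
    track: Sequence[BoxRecord], gap_fill: int = 5
) -> ChewSignal:
    """H_i = width + height per frame for one track.

    Missing-frame runs of length <= ``gap_fill`` are linearly interpolated;
    longer runs are left as gaps, splitting the signal into segments that
    downstream analysis treats independently.
    """
    if not track:
        return ChewSignal(identity=None, frames=np.array([], int), H=np.array([]))
    idents = {r.identity for r in track}
    if len(idents) > 1:
        raise ValueError(f"track mixes identities: {sorted(map(str, idents))}")
    recs = sorted(track, key=lambda r: r.frame_index)
    frames = np.array([r.frame_index for r in recs], dtype=int)
    if np.any(np.diff(frames) == 0):
        dup = int(frames[np.where(np.diff(frames) == 0)[0][0]])
        raise ValueError(f"duplicate frame {dup} for one identity")
    H = np.array([sum(box_dims(r)) for r in recs], dtype=float)

    out_f: list[int] = [int(frames[0])]
    out_h: list[float] = [float(H[0])]
    for k in range(1, len(frames)):
        gap = int(frames[k] - frames[k - 1]) - 1
        if 0 < gap <= gap_fill:
            xs = np.arange(frames[k - 1] + 1, frames[k])
            ys = np.interp(xs, [frames[k - 1], frames[k]], [H[k - 1], H[k]])
            out_f.extend(int(x) for x in xs)
            out_h.extend(float(y) for y in ys)
        out_f.append(int(frames[k]))
        out_h.append(float(H[k]))
    return ChewSignal(
        identity=recs[0].identity, frames=np.array(out_f), H=np.array(out_h)
    )


def _windowed_argopt(
    H: np.ndarray, start: int, window: int, find_max: bool
) -> int:
    """Earliest arg-optimum of H[start : start+window], with boundary
    continuation: while the optimum sits on the window's last index and the
    signal continues, the window grows by one frame."""
    n = len(H)
    end = min(start + window, n)  # exclusive
    seg = H[start:end]
    idx = start + int(np.argmax(seg) if find_max else np.argmin(seg))
    while idx == end - 1 and end < n:
        end += 1
        seg = H[start:end]
        idx = start + int(np.argmax(seg) if find_max else np.argmin(seg))
    return idx


def _run_from(
    H: np.ndarray, start: int, params: ExtremaParams
) -> tuple[list[tuple[int, str]], int, bool]:
    """One alternating search anchored at ``start``.

    Returns (extrema as (index, kind), last search position, stalled flag).
    A run stalls when a search cannot advance past the previous extremum
    (constant stretch); otherwise it ends at the signal tail.
    """
    n = len(H)
    first = start + int(np.argmax(H[start : start + params.init_window]))
    ext: list[tuple[int, str]] = [(first, "peak")]
    find_max = False  # next search is for a valley
    pos = first
    while n - 1 - pos >= 2:
        nxt = _windowed_argopt(H, pos, params.search_window, find_max)
        if nxt <= pos:
            return ext, pos, True
        ext.append((nxt, "peak" if find_max else "valley"))
        pos = nxt
        find_max = not find_max
    return ext, pos, False


def _extract_segment(
    frames: np.ndarray, H: np.ndarray, params: ExtremaParams
) -> list[list[Extremum]]:
    """Alternating peak–valley groups for one contiguous signal segment.

    A flat stretch (e.g. a swallowing pause) stalls the windowed search;
    the search is then re-anchored past the stall so later chewing bouts
    are still counted. Each group alternates internally starting with a
    peak; re-anchored groups that never find a valley are dropped (they
    are pause artifacts), except the very first group, which preserves the
    degenerate one-peak result on constant signals.
    """
    n = len(H)
    groups: list[list[Extremum]] = []
    start = 0
    while n - start >= params.init_window:
        ext, pos, stalled = _run_from(H, start, params)
        # A re-anchored group whose initial "peak" sits on a plateau edge
        # (nothing rises into it) is a level shift, not a chew: drop its
        # leading peak-valley pair so bout-to-bout drops are not counted.
        if groups and len(ext) >= 2:
            p = ext[0][0]
            if p > 0 and H[p - 1] >= H[p]:
                ext = ext[2:]
        keep = [Extremum(int(frames[i]), float(H[i]), k) for i, k in ext]
        if params.min_amplitude > 0:
            keep = _merge_small(keep, params.min_amplitude)
        if keep and (not groups or any(e.kind == "valley" for e in keep)):
            groups.append(keep)
        if not stalled:
            break
        start = max(pos, start) + 1
    return groups


def _merge_small(ext: list[Extremum], min_amplitude: float) -> list[Extremum]:
    """Remove adjacent peak/valley pairs whose amplitude is below threshold.

    Removing an adjacent pair preserves the alternation of the remainder;
    passes repeat until every adjacent pair clears the threshold.
    """
    changed = True
    while changed and len(ext) >= 2:
        changed = False
        for i in range(len(ext) - 1):
            if abs(ext[i].value - ext[i + 1].value) < min_amplitude:
                del ext[i : i + 2]
                changed = True
                break
    return ext


def extract_extrema(
    signal: ChewSignal, params: ExtremaParams = ExtremaParams()
) -> ExtremaSequence:
    """Run the windowed peak–valley search over every contiguous segment.

    ``chew_count`` is the number of retained valleys; ``chew_frames`` sums
    the inclusive first-to-last-extremum frame span of every chewing group,
    so swallowing pauses between bouts do not count toward the duration.
    """
    extrema: list[Extremum] = []
    chew_frames = 0
    for frames, H in signal.segments():
        for group in _extract_segment(frames, H, params):
            extrema.extend(group)
            chew_frames += group[-1].frame - group[0].frame + 1
    count = sum(1 for e in extrema if e.kind == "valley")
    return ExtremaSequence(extrema=extrema, chew_count=count, chew_frames=chew_frames)


# ---------------------------------------------------------------------------


def detect_phases(
    signal: ChewSignal,
    extrema: ExtremaSequence,
    flat_window: int = 25,
    flat_range: float = 5.0,
    drop_fraction: float = 0.25,
    drop_span: int = 5,
) -> PhaseReport:
    """Find swallowing pauses and rumination-angle changes in one signal.

    A swallowing pause is a maximal run of at least ``flat_window`` frames
    over which H varies by less than ``flat_range`` pixels (the mouth rests
    while the bolus is swallowed). An angle change is a drop of H by more
    than ``drop_fraction`` of the typical oscillation amplitude (median
    peak minus median valley) within at most ``drop_span`` frames, provided
    no chewing valley lies inside the drop — a genuine chew also drops H,
    so chew valleys are excluded.
    """
    report = PhaseReport()
    for frames, H in signal.segments():
        n = len(H)
        if n == 0:
            continue
        # maximal flat runs via two pointers over the running min/max
        i = 0
        while i < n:
            lo = hi = H[i]
            j = i
            while j + 1 < n:
                lo2 = min(lo, H[j + 1])
                hi2 = max(hi, H[j + 1])
                if hi2 - lo2 >= flat_range:
                    break
                lo, hi = lo2, hi2
                j += 1
            if j - i + 1 >= flat_window:
                report.swallow_segments.append((int(frames[i]), int(frames[j])))
                i = j + 1
            else:
                i += 1

        peaks = [e.value for e in extrema.peaks]
        valleys = [e.value for e in extrema.valleys]
        if not peaks or not valleys:
            continue
        amplitude = float(np.median(peaks) - np.median(valleys))
        if amplitude <= 0:
            continue
        threshold = drop_fraction * amplitude
        valley_frames = np.array([e.frame for e in extrema.valleys])
        events: list[int] = []
        for s in range(n - 1):
            e_max = min(n - 1, s + drop_span)
            for e in range(s + 1, e_max + 1):
                if H[s] - H[e] > threshold:
                    # follow the descent to its floor: a drop that bottoms
                    # out in a counted chew valley is a chew, not an angle
                    # change
                    e_ext = e
                    while e_ext + 1 < n and H[e_ext + 1] <= H[e_ext]:
                        e_ext += 1
                    f_s, f_ext = int(frames[s]), int(frames[e_ext])
                    if np.any(
                        (valley_frames >= f_s) & (valley_frames <= f_ext)
                    ):
                        break
                    events.append(int(frames[e]))
                    break
        # collapse runs of nearby detections into single events
        for f in events:
            if not report.angle_changes or f > report.angle_changes[-1] + drop_span:
                report.angle_changes.append(f)
    report.swallow_segments.sort()
    report.angle_changes = sorted(report.angle_changes)
    return report


def summarize(
    track: Sequence[BoxRecord],
    params: ExtremaParams = ExtremaParams(),
    flat_window: int = 25,
    flat_range: float = 5.0,
    drop_fraction: float = 0.25,
    drop_span: int = 5,
) -> tuple[ChewSignal, ExtremaSequence, PhaseReport]:
    """Signal, extrema and phase report for one track, with shared params."""
    signal = compute_signal(track, gap_fill=params.gap_fill)
    extrema = extract_extrema(signal, params)
    phases = detect_phases(
        signal,
        extrema,
        flat_window=flat_window,
        flat_range=flat_range,
        drop_fraction=drop_fraction,
        drop_span=drop_span,
    )
    return signal, extrema, phases
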