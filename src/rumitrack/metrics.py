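"""Evaluation metrics for the rumination pipeline.

Three families:

* chewing errors — count error rate ``n_r = |m_r - p_r| / p_r * 100`` and
  duration relative error ``n_t = |m_t - p_t| / p_t * 100`` comparing the
  model estimate (m) against manual annotation (p);
* multi-object tracking — CLEAR-MOT accounting (MOTA, false positives,
  false negatives, identity switches) with correspondence carry-over;
* detection — precision, recall, F1 and average precision (all-point
  interpolated), with mAP@0.5 and mAP@0.5:0.95.

Core functions return full-precision values; ``display_*`` helpers apply
the rounding conventions used in report tables (integer n_r, two-decimal
n_t, three-decimal truncated F1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import BoxRecord, box_iou

__all__ = [
    "ChewErrorResult",
    "MOTResult",
    "DetectionEvalResult",
    "UndefinedMetricError",
    "chew_count_error",
    "duration_error",
    "chew_errors",
    "evaluate_tracking",
    "evaluate_detection",
    "display_count_error",
    "display_duration_error",
    "display_f1",
    "COCO_IOU_THRESHOLDS",
]

COCO_IOU_THRESHOLDS: tuple[float, ...] = tuple(
    round(0.5 + 0.05 * i, 2) for i in range(10)
)


class UndefinedMetricError(ValueError):
    """A metric's denominator is empty or zero."""


# ---------------------------------------------------------------------------
# Chewing errors
# ---------------------------------------------------------------------------

def chew_count_error(m_r: int, p_r: int) -> float:
    """Chewing count error rate n_r (%), model count m_r vs manual p_r."""
    if p_r <= 0:
        raise UndefinedMetricError("manual chew count p_r must be positive")
    return abs(m_r - p_r) / p_r * 100.0


def duration_error(m_t: int, p_t: int) -> float:
    """Rumination duration relative error n_t (%), in frames."""
    if p_t <= 0:
        raise UndefinedMetricError("manual frame count p_t must be positive")
    return abs(m_t - p_t) / p_t * 100.0


def _round_half_up(x: float, decimals: int = 0) -> float:
    scale = 10**decimals
    return math.floor(x * scale + 0.5) / scale


def display_count_error(n_r: float) -> int:
    """n_r as shown in report tables: nearest integer (half rounds up)."""
    return int(_round_half_up(n_r))


def display_duration_error(n_t: float) -> float:
    """n_t as shown in report tables: two decimals (half rounds up)."""
    return _round_half_up(n_t, 2)


def display_f1(f1: float) -> float:
    """F1 as shown in report tables: truncated to three decimals."""
    return math.floor(f1 * 1000) / 1000


@dataclass(frozen=True)
class ChewErrorResult:
    m_r: int
    p_r: int
    n_r: float
    m_t: int
    p_t: int
    n_t: float

    @property
    def n_r_display(self) -> int:
        return display_count_error(self.n_r)

    @property
    def n_t_display(self) -> float:
        return display_duration_error(self.n_t)


def chew_errors(m_r: int, p_r: int, m_t: int, p_t: int) -> ChewErrorResult:
    """Both chewing error metrics for one video."""
    return ChewErrorResult(
        m_r=m_r,
        p_r=p_r,
        n_r=chew_count_error(m_r, p_r),
        m_t=m_t,
        p_t=p_t,
        n_t=duration_error(m_t, p_t),
    )


# ---------------------------------------------------------------------------
# CLEAR-MOT tracking evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MOTResult:
    mota: float  # percent
    fp: int
    fn: int
    idsw: int
    gt_total: int


def _by_frame(records: Sequence[BoxRecord]) -> dict[int, list[BoxRecord]]:
    out: dict[int, list[BoxRecord]] = {}
    for r in records:
        out.setdefault(r.frame_index, []).append(r)
    return out


def evaluate_tracking(
    gt: Sequence[BoxRecord],
    pred: Sequence[BoxRecord],
    iou_threshold: float = 0.5,
) -> MOTResult:
    """CLEAR-MOT evaluation of predicted tracks against ground truth.

    Frame by frame, previous ground-truth/prediction identity pairings are
    kept while they still overlap at ``iou_threshold``; the remainder are
    matched by optimal IoU assignment. Unmatched predictions are false
    positives, unmatched ground-truth boxes false negatives, and a matched
    ground-truth object whose paired predicted identity differs from its
    previous pairing counts one identity switch.

    MOTA = (1 - (FP + FN + IDSw) / GT) * 100.
    """
    if not gt:
        raise UndefinedMetricError("ground truth is empty")
    for name, recs in (("gt", gt), ("pred", pred)):
        for r in recs:
            if r.identity is None:
                raise ValueError(f"{name} record without identity at frame {r.frame_index}")

    gt_frames = _by_frame(gt)
    pred_frames = _by_frame(pred)
    fp = fn = idsw = 0
    gt_total = len(gt)
    # last predicted identity paired with each gt identity
    pairing: dict[int, int] = {}

    for frame in sorted(set(gt_frames) | set(pred_frames)):
        g = gt_frames.get(frame, [])
        p = pred_frames.get(frame, [])
        matched_g: set[int] = set()
        matched_p: set[int] = set()
        # carry over surviving correspondences first
        p_by_id = {r.identity: i for i, r in enumerate(p)}
        for gi, gr in enumerate(g):
            pid = pairing.get(gr.identity)
            if pid is None or pid not in p_by_id:
                continue
            pi = p_by_id[pid]
            if pi in matched_p:
                continue
            if box_iou(gr, p[pi]) >= iou_threshold:
                matched_g.add(gi)
                matched_p.add(pi)
        # optimal assignment for the rest
        rem_g = [i for i in range(len(g)) if i not in matched_g]
        rem_p = [i for i in range(len(p)) if i not in matched_p]
        if rem_g and rem_p:
            iou = np.zeros((len(rem_g), len(rem_p)))
            for a, gi in enumerate(rem_g):
                for b, pi in enumerate(rem_p):
                    iou[a, b] = box_iou(g[gi], p[pi])
            rows, cols = linear_sum_assignment(-iou)
            for a, b in zip(rows, cols):
                if iou[a, b] < iou_threshold:
                    continue
                gi, pi = rem_g[a], rem_p[b]
                gid = g[gi].identity
                pid = p[pi].identity
                if gid in pairing and pairing[gid] != pid:
                    idsw += 1
                pairing[gid] = pid
                matched_g.add(gi)
                matched_p.add(pi)
        fn += len(g) - len(matched_g)
        fp += len(p) - len(matched_p)

    mota = (1.0 - (fp + fn + idsw) / gt_total) * 100.0
    return MOTResult(mota=mota, fp=fp, fn=fn, idsw=idsw, gt_total=gt_total)


# ---------------------------------------------------------------------------
# Detection evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionEvalResult:
    precision: float
    recall: float
    f1: float
    ap_per_threshold: dict[float, float] = field(default_factory=dict)
    map50: float = 0.0
    map5095: float = 0.0


def _match_flags(
    gt_frames: dict[int, list[BoxRecord]],
    pred_sorted: Sequence[BoxRecord],
    iou_threshold: float,
) -> np.ndarray:
    """True/false-positive flags for confidence-ordered predictions.

    Greedy within each frame: a prediction takes the highest-IoU still
    unmatched ground-truth box if that IoU clears the threshold.
    """
    used: dict[int, set[int]] = {f: set() for f in gt_frames}
    flags = np.zeros(len(pred_sorted), dtype=bool)
    for k, pr in enumerate(pred_sorted):
        cands = gt_frames.get(pr.frame_index, [])
        best, best_iou = -1, 0.0
        for gi, gr in enumerate(cands):
            if gi in used.get(pr.frame_index, set()):
                continue
            v = box_iou(pr, gr)
            if v > best_iou:
                best, best_iou = gi, v
        if best >= 0 and best_iou >= iou_threshold:
            used[pr.frame_index].add(best)
            flags[k] = True
    return flags


def _average_precision(tp_flags: np.ndarray, n_gt: int) -> float:
    """All-point interpolated area under the precision–recall curve."""
    if n_gt == 0:
        return 0.0
    tp = np.cumsum(tp_flags)
    fp = np.cumsum(~tp_flags)
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    # precision envelope (monotone non-increasing from the right)
    mrec = np.concatenate(([0.0], recall, [recall[-1] if len(recall) else 0.0]))
    mpre = np.concatenate(([1.0], precision, [0.0]))
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def evaluate_detection(
    gt: Sequence[BoxRecord],
    pred: Sequence[BoxRecord],
    iou_thresholds: Sequence[float] = COCO_IOU_THRESHOLDS,
) -> DetectionEvalResult:
    """Precision/recall/F1 at IoU 0.5 plus AP per threshold and mAPs.

    Predictions must carry confidences; matching is greedy in descending
    confidence, one ground-truth box matched at most once per threshold.
    With no predictions, precision is defined as 0.
    """
    if not gt and not pred:
        raise UndefinedMetricError("no ground truth and no predictions")
    for r in pred:
        if r.confidence is None:
            raise ValueError("prediction without confidence")
    gt_frames = _by_frame(gt)
    pred_sorted = sorted(
        pred, key=lambda r: (-r.confidence, r.frame_index)
    )

    flags50 = _match_flags(gt_frames, pred_sorted, 0.5)
    tp = int(flags50.sum())
    fp = len(pred_sorted) - tp
    fn = len(gt) - tp
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )

    ap: dict[float, float] = {}
    for thr in iou_thresholds:
        flags = flags50 if thr == 0.5 else _match_flags(gt_frames, pred_sorted, thr)
        ap[float(thr)] = _average_precision(flags, len(gt))

    map50 = ap.get(0.5, 0.0)
    coco = [ap[t] for t in COCO_IOU_THRESHOLDS if t in ap]
    map5095 = float(np.mean(coco)) if len(coco) == len(COCO_IOU_THRESHOLDS) else float(
        np.mean(list(ap.values()))
    )
    return DetectionEvalResult(
        precision=precision,
        recall=recall,
        f1=f1,
        ap_per_threshold=ap,
        map50=map50,
        map5095=map5095,
    )
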