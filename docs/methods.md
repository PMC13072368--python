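# Methods

## The measurement model

A ruminating cow chews a regurgitated bolus with a periodic open–close jaw
movement. A mouth detector yields, per video frame *i*, an axis-aligned
bounding box with corners (x₁, y₁), (x₂, y₂). The chewing signal is

    Xᵢ = xᵢ₂ − xᵢ₁,  Yᵢ = yᵢ₂ − yᵢ₁,  Hᵢ = Xᵢ + Yᵢ

i.e. box width plus height, in pixels. H oscillates once per chewing cycle;
at 25 fps one cycle spans roughly 18–25 frames. Between chewing bouts the cow
swallows the bolus and the mouth rests, so H is nearly constant for a few
seconds; a fast drop in H that is not part of a chew indicates the animal
changing its rumination (head) angle. The package quantifies all three
phenomena from tracked boxes; it never touches pixels — detection and
re-identification feature extraction happen upstream.

## Tracking

Detections are linked into identities with a SORT-family tracker:

* **State.** 8-vector (cx, cy, w, h, and per-frame velocities) with
  constant-velocity dynamics. Process/measurement noise scales are
  proportional to box height (weights 1/20 position, 1/160 velocity), the
  convention of this tracker lineage. Width/height components are clamped
  non-negative after every predict/update.
* **Camera motion compensation.** When a per-frame 2×3 affine transform is
  supplied (mapping the previous frame's pixel coordinates to the current
  frame's), each predicted state is mapped through it before association:
  positions affinely, velocities through the linear part, width/height by the
  axis scales, covariance position/velocity blocks congruently. Transforms are
  *inputs* — estimating them from video is upstream of this package; the
  simulator closes the loop by recording exactly the transforms it injects.
* **Association.** Stage 1 solves the optimal one-to-one assignment
  (Hungarian algorithm) maximizing IoU between predicted boxes and
  high-confidence detections (confidence ≥ 0.5 by default), discarding pairs
  under the IoU threshold (default 0.3). Stage 2 matches the remaining tracks
  and detections by minimal cosine distance between the track's exponentially
  smoothed appearance vector (momentum 0.9) and the detection's appearance
  vector, discarding pairs above 0.4; without appearance vectors it falls back
  to IoU matching over the remaining low-confidence detections.
* **Lifecycle.** Unmatched detections spawn tentative tracks; a track is
  confirmed after 3 updates (tracks born on the very first frame are trusted
  immediately — targets present at recording start should not cost false
  negatives during warm-up) and removed after 30 consecutive unmatched frames.
  Confirmed tracks emit a box every frame, coasting on the Kalman prediction
  through detection gaps, so short dropouts neither fragment identities nor
  punch holes in the chewing signal. Identities are positive integers in
  creation order, never reused; the whole tracker is deterministic.

None of the thresholds is intrinsic to the method; all are exposed in
`TrackerConfig` and on the command line.

## Chew counting

The windowed alternating extrema search over H:

1. the initial peak is the maximum of the first 25 frames (`init_window`);
2. the next valley is the minimum of the 12 frames (`search_window`)
   starting at the previous peak, inclusive;
3. the next peak is the maximum of the 12 frames starting at that valley;
4. repeat until fewer than two frames remain past the last extremum.

Ties take the earliest frame. Two boundary rules make the procedure total:

* **Boundary continuation.** If the candidate extremum lands on the last
  frame of its window while the signal continues, the window grows one frame
  and the search repeats. Without this, cycles of 24–25 frames (half-cycle ≥
  the 12-frame window) leave the true turning point just outside the window,
  and the search either stalls or drifts into spurious extrema; with it,
  noiseless recovery is exact across the whole 18–25-frame period range. On
  signals whose turning points fall inside the windows (periods ≤ 22), the
  rule never fires and the search reduces to the plain windowed scan.
* **Re-anchoring after stalls.** On a constant stretch (a swallowing pause)
  the search cannot advance — the window optimum is the previous extremum
  itself. The run then ends and a fresh search is anchored past the stall, so
  later bouts are still counted. A re-anchored run whose initial "peak" has
  nothing rising into it (a plateau edge) has its leading peak–valley pair
  discarded: that shape is a level shift between bouts, not a chew.
  Re-anchored runs that never find a valley are pause artifacts and are
  dropped entirely; the very first run is kept even if degenerate, so a
  constant signal yields exactly one peak and zero chews.

One **chew** is one retained valley — one mouth opening between two closures.
`chew_frames` sums the first-to-last-extremum span of every chewing run, so
pauses between bouts do not count toward rumination duration. An optional
`min_amplitude` filter (default 0 — the windowed search itself is the only
noise filter by default) merges adjacent peak–valley pairs whose amplitude is
below threshold. Tracks with missing frames are linearly interpolated across
gaps of ≤ 5 frames (`gap_fill`); longer gaps split the signal into segments
analyzed independently.

Phase detection: swallowing segments are maximal runs of ≥ 25 frames
(`flat_window`) whose H range stays under 5 px (`flat_range`); angle changes
are drops exceeding 25 % (`drop_fraction`) of the typical oscillation
amplitude (median peak − median valley) within ≤ 5 frames (`drop_span`),
excluding drops whose descent bottoms out in a counted chew valley.

## Evaluation metrics

* **Chewing errors.** n_r = |m_r − p_r|/p_r × 100 and
  n_t = |m_t − p_t|/p_t × 100 (model m vs manual p, counts and frames). Core
  functions return full precision; display helpers round n_r to the nearest
  integer and n_t to two decimals (half up), matching the bundled reference
  table. Recomputing that table reproduces all ten printed n_r cells, eight
  of ten n_t cells and both printed column means (3 %, 4 %); the two
  remaining n_t cells (videos 3 and 4) are inconsistent with the formula on
  their own printed inputs — video 4 grossly so — and are shipped flagged
  rather than matched.
* **Tracking.** CLEAR-MOT: per frame, surviving identity pairings are kept
  while IoU ≥ 0.5, the remainder matched by optimal IoU assignment; unmatched
  predictions are FP, unmatched ground truth FN, and a re-paired ground-truth
  object costs one identity switch. MOTA = (1 − (FP+FN+IDSw)/GT) × 100.
* **Detection.** Greedy confidence-descending matching, one GT box used once
  per threshold; F1 = 2PR/(P+R); AP is the all-point interpolated area under
  the precision–recall curve; mAP@0.5:0.95 averages AP over IoU thresholds
  0.50–0.95 in 0.05 steps. Displayed F1 is truncated (not rounded) to three
  decimals, the convention of the bundled benchmark rows.

## The simulator

`simulate_scene` emulates what the detector hands the tracker:

* H follows one raised-cosine arch per chewing cycle
  (h(t) = A·(1 − cos 2πt/T), A = 20 px by default, so the full swing is 2A);
  per-cycle periods are drawn uniformly from 18–25 frames; bouts of 70–86 s
  alternate with flat pauses of 2–6 s; width and height each carry half of
  the oscillation around a 60×50 px base box with a fixed center.
* Degradations: i.i.d. Gaussian corner noise (`noise_sd`; σ_H = 2·noise_sd),
  Bernoulli detection dropout (`miss_rate`), Gaussian confidences clipped to
  (0, 1], unit-norm per-cow appearance centers with small perturbations, and
  a shared sinusoidal camera translation (period 50 frames) whose exact
  per-frame transforms are recorded in the bundle.
* Ground truth records every cycle, bout, pause and transform, and exactly
  duration × fps frames are emitted per cow.

What the simulator does **not** model: pixel appearance (lighting, rain,
image blur enter only through `noise_sd`/`miss_rate` presets), perspective
change, mouth translation during chewing, correlated detector failures, and
real ReID embedding statistics. Passing tests therefore demonstrate the
correctness of the geometry, association, counting and scoring machinery —
not detector robustness on farm video.

## Problem sizes and numerical choices

Recovery studies use 50 replicates of a single 78 s bout (a typical
bolus-chewing duration); tracking checks use 40 s two-cow scenes. Noisy
recovery uses corner noise of 2 px — σ_H equal to 10 % of the 40 px H swing —
plus 5 % dropout, and reports the mean absolute count error across
replicates (about 1 %; exact at zero noise). Degenerate inputs fail fast:
NaN coordinates, duplicate frames within a track, inverted corners and
malformed MOT lines raise errors naming the offending record. All
computation is float64; no randomness exists outside the simulator, which is
fully reproducible from its seed.

## Known limitations

* Chews during pauses shorter than the search window can blur into the
  neighbouring bout's count by at most one.
* With heavy noise and no `min_amplitude`, noise wiggles during long pauses
  can register as low-amplitude chews; single-bout analyses are unaffected.
* The tracker's coasting emission reports predicted boxes during dropouts;
  with a moving target and a long gap those boxes inherit model error.
* Rumination is not discriminated from visually similar behaviours (eating,
  licking, drinking); the signal-level analysis assumes its input tracks a
  ruminating mouth.
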