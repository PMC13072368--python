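# rumitrack

Non-contact quantification of dairy-cow rumination from video-derived mouth
bounding boxes.

Rumination — the repeated regurgitation and re-chewing of partially digested
feed — is a key welfare and health indicator in dairy herds. Camera-based
monitoring detects the cow's mouth in every frame and watches the geometry of
that detection oscillate as the jaw opens and closes. `rumitrack` implements
everything downstream of the detector:

* **Tracking** — a BoT-SORT-style multi-object tracker (constant-velocity
  Kalman filter over center/size state, optional camera motion compensation
  through supplied per-frame affine transforms, two-stage association: optimal
  IoU matching of high-confidence detections, then appearance/cosine-distance
  re-association of the remainder) that turns per-frame detections into
  identity-consistent mouth trajectories.
* **Chewing analysis** — the per-frame chewing signal
  `H_i = X_i + Y_i` (bounding-box width plus height), a windowed alternating
  peak–valley search that counts chews (one valley = one mouth opening between
  two closures; each chewing cycle spans ~18–25 frames at 25 fps), and phase
  detection: flat stretches of H are swallowing pauses, abrupt non-chew drops
  are rumination-angle changes.
* **Evaluation** — chew-count error rate `n_r = |m_r − p_r|/p_r × 100` and
  duration relative error `n_t = |m_t − p_t|/p_t × 100` against manual
  annotation; CLEAR-MOT tracking metrics (MOTA, FP, FN, identity switches);
  detection precision/recall/F1 and all-point-interpolated AP with mAP@0.5 and
  mAP@0.5:0.95.
* **Simulation** — a fully seeded scene generator (raised-cosine chewing
  cycles in bouts separated by swallowing pauses, localization noise,
  detection dropout, occlusion, appearance vectors, sinusoidal camera jitter
  with recorded transforms) so the entire pipeline is testable without video.

Files use the MOT-challenge plain-text dialect
(`frame,id,left,top,width,height,conf,…`) with JSON-lines sidecars for
appearance vectors and affine transforms.

## Worked example

```sh
python examples/simulate_and_count.py
```

simulates a 78 s single-bout recording with 2 px corner noise and 5 %
detection dropout, tracks it, and counts chews from the recovered trajectory:

```
scene: 1950 frames, 1853 detections (97 dropped)
ground truth: 90 chews over 1945 chewing frames
recovered:    91 chews over 1937 frames (182 extrema)
chew-count error rate: 1.11%
```

The simulator generated 90 chewing cycles; the peak–valley search on the
tracked boxes recovered 91, a 1.11 % count error — on noiseless input the
recovery is exact. `examples/track_with_camera_motion.py` shows camera motion
compensation cancelling an injected 4 px camera sway (identical MOTA with and
without jitter), and `examples/evaluate_reference_table.py` recomputes the
bundled ten-video model-vs-manual error table.

The same pipeline is available from a shell:

```sh
rumitrack simulate --out-dir scene --seed 5 --duration-s 20
rumitrack track scene/detections.txt --out scene/tracks.txt
rumitrack analyze scene/tracks.txt --out-dir scene/analysis
rumitrack evaluate --mode track --gt scene/gt.txt --pred scene/tracks.txt
```

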