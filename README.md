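# motiftrack

Multi-animal pose tracking and unsupervised behavioral motif discovery,
downstream of any keypoint detector.

Laboratory mice of the same strain are visually near-identical, so
appearance-based re-identification fails; and hand-scoring social behavior
frame by frame does not scale. `motiftrack` takes per-frame detections —
a bounding box and K keypoints (snout, left ear, right ear, tail base for
the mouse schema) with confidences — and provides the computational core of
a tracking-and-ethogramming pipeline:

* **Identity association.** Each animal in frame *t* is summarized by a
  hierarchical descriptor `D_i^t`: its body box plus a small square "part
  box" centered on every keypoint. Descriptors in adjacent frames are
  scored with

  `Sim(D_i^t, D_j^t+1) = IOU(box_i^t, box_j^t+1) + (1/n) Σ_k IOU(P_ik^t, P_jk^t+1)`

  (range [0, 2]) and linked by sorted-greedy matching: the globally most
  similar unassigned pair first, repeated until one side is exhausted.
* **Trajectory curation.** Per-keypoint constant-acceleration Kalman
  filtering with an RTS smoother; a user correction at one frame is
  propagated across a half-open curation interval `[in, out)` as a
  near-zero-noise measurement, and identity swaps are exact relabelings.
* **Behavioral features.** Tracked sequences are cut into 15-frame clips
  (500 ms at 25 fps). One animal is the *reference* mouse: the scene is
  rigidly aligned so its middle-frame body axis (tail base → snout) lies on
  the positive x axis, and a dictionary of per-animal and social kinematic
  features (body length, ear angles, frame-to-frame displacement,
  snout–snout and snout–tail-base vectors, relative body/head orientation)
  is computed per frame, z-scored per column across clips, and weighted.
* **Motif discovery.** Ward agglomerative clustering on the feature rows;
  flat motif labels from a dendrogram threshold cut (`thred`); inspection
  reports (per-cluster feature heatmap, per-feature mutual information
  with labels, inter-cluster similarity, medoid representatives).
* **Evaluation.** Keypoint-adapted CLEAR-MOT metrics — a predicted keypoint
  matches ground truth within 5% of the ground-truth box diagonal; MOTA,
  MOTP (as percent localization similarity), and confidence-ranked mAP —
  plus the Adjusted Rand Index for clustering agreement.
* **Synthetic arena.** A seeded two-mouse simulator with motif-structured
  kinematics (walk, turn, groom, chase, anogenital sniff, nose-to-nose...),
  Gaussian keypoint noise, dropouts, and identity-crossing episodes,
  providing ground truth for every stage.

## Worked example

```python
import motiftrack as mt
from motiftrack.pipeline import track_session

session = mt.standard_benchmark(seed=7)      # 1,000 frames, 2 mice
tracked = track_session(session)             # identities from geometry only
print(mt.identity_accuracy(tracked, session.ground_truth))
report = mt.mota_motp(tracked, session.ground_truth)
```

prints (see `examples/01_simulate_and_track.py` and
`examples/02_evaluate_tracking.py`):

```
frame-wise identity accuracy: 100.00%
MOTA 99.3%   MOTP 65.2%   mAP 99.4%
misses 43, false positives 15, identity mismatches 0 over 8000 ground-truth keypoints
```

The tracker kept both identities through every crossing episode; the 43
misses are the simulated 0.5% detection dropout, and MOTP of 65% reflects
2%-of-body-length detection noise against the 5%-of-diagonal match
threshold. Motif discovery on the 300-row pure-motif benchmark
(`examples/04_discover_motifs.py`):

```
cut at thred=127.5: 3 clusters, ARI vs generator labels = 1.000
```

Each capability has a short narrative script under `examples/`. The same
workflows are available from the shell via the `motiftrack` console script
(`simulate`, `track`, `curate`, `features`, `cluster`, `evaluate-mot`,
`evaluate-ari`), which writes a `manifest.json` per run.

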