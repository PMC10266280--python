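# Methods

## Identity association

Animals of one strain cannot be told apart by appearance, so identity is
propagated purely geometrically. The descriptor of animal *i* at frame *t*
is its body bounding box together with one square *part box* per keypoint,
centered on the keypoint with side `part_box_scale × diagonal(body box)`.
The default `part_box_scale = 0.1` makes the descriptor scale-invariant
across image resolutions; part boxes may extend beyond the body box (no
clipping). Descriptor similarity is the body-box IOU plus the mean IOU of
part boxes compared at matching keypoint index, hence in [0, 2]: the first
term captures gross position, the second orientation and pose. Part boxes
are compared index-to-index (snout with snout), never across indices.

Matching between adjacent frames is *sorted-greedy*: all pairwise
similarities are computed, the globally highest-scoring pair with both
members unassigned is linked, and the procedure repeats until either frame
is exhausted. Ties break deterministically by (lower previous id, lower
detection index). Zero-similarity pairs are still linked while both sides
have members (configurable via `min_match_similarity`). Greedy is not
globally optimal; it equals the Hungarian optimum whenever cross-identity
similarities vanish, and the difference only matters in heavy-overlap
frames.

Track assembly assigns ids 1..m in detection order on the first frame (ids
are arbitrary labels — evaluation treats them up to permutation), matches
each later frame against the most recent descriptor of every active id,
and retires an id after `max_gap = 5` frames without a match. Unmatched
detections open fresh ids only while fewer than `max_ids` are alive;
surplus detections are dropped lowest-mean-confidence first and logged.

## Trajectory smoothing and curation

Keypoint motion is modeled per (track, keypoint) with a six-state
constant-acceleration Kalman filter, state (x, y, vx, vy, ax, ay), unit
frame step, process noise from integrated white jerk with spectral density
`q` (default 0.5 px²/frame³) and base measurement variance `r` (default
4 px², i.e. ±2 px detector jitter) scaled by 1/confidence per observation.
Confidence-0 observations are treated as missing (pure prediction). A
fixed-interval RTS backward smoother runs by default (`smooth=False` gives
the forward filter only). On noisy constant-velocity tracks the smoother
roughly halves RMSE; on clean data `r` should be set small to match.

A curation correction carries exact coordinates at one frame plus the
half-open interval [in, out) over which the error is presumed to persist —
the interval semantics of interactive proofreading. The interval is
re-filtered with the corrected frame injected as a near-zero-noise
(1e-9 px²) measurement, the corrected frame is then pinned to the user's
exact values, and frames outside the interval are untouched. Identity
swaps are pure relabelings over the interval (the geometry is right, only
the labels are wrong), which makes a double swap the identity operation.
With a persistent offset error in the remaining interval observations the
re-filter reduces, but cannot eliminate, the interval error — the
observations themselves still vote for the offset.

## Clips, alignment, features

Behavior is analyzed in clips of W = 15 consecutive frames (500 ms at
25 fps, the sub-second timescale of rodent action blocks), non-overlapping
by default. Clips are only taken where every track is present on every
frame; a clip is dropped when any animal has more than 20% of its keypoint
observations below confidence 0.1, and surviving low-confidence points are
linearly interpolated in time.

Geometric conventions: body vector = tail base → snout; head vector = ear
midpoint → snout; body center = midpoint of snout and tail base. Signed
angles live in the image coordinate system as given (y down): `sin` is the
normalized cross product, `cos` the normalized dot product, neutral (0, 1)
where a defining vector vanishes. Adjacent-frame features pad the first
frame with their neutral value to keep length W.

For directional features the scene is rigidly aligned so the reference
mouse's middle-frame body vector lies on the positive x axis (tail base at
the origin). Intrinsic features (lengths, angles to the own body vector)
are rotation-invariant by construction; the reference mouse's displacement
direction and all inter-animal vectors are measured in the
reference-anchored frame; the non-reference mouse's intrinsic angles come
from its own geometry (the self-anchored view is exposed in the
intermediate arrays for custom features). The choice of +x rather than −x
for the aligned body axis only flips sign conventions of directional
features and is applied consistently.

Each gated clip yields one row per choice of reference animal (two rows
for a dyad; individual mode is the same construction with social feature
weights 0 and the distance gate disabled). Rows are the time-domain
concatenation of per-frame feature values. Under `zscore_all` every
(feature, frame-position) column is z-scored across rows — zero-variance
columns become 0 with a warning — then multiplied by the feature weight
(default 1; 0 removes the feature). Custom features are callables over the
five intermediate pose arrays (reference raw/self-aligned, non-reference
raw/self-aligned/reference-aligned) returning one value per frame; they
participate in normalization and weighting exactly like built-ins. A
spectral (DFT-magnitude) per-feature representation was considered and
deliberately left out: the time-domain concatenation is sufficient for the
package's benchmarks and keeps rows interpretable.

## Motif clustering and reports

Ward minimum-variance linkage on Euclidean distances between rows (the
metric Ward requires), cut at a linkage-distance threshold `thred`: motifs
are the connected components after removing merges above the threshold.
`thred` is expressed in linkage units of the weighted z-scored table; the
intended workflow is to inspect the dendrogram and re-cut, and
`suggest_threshold(tree, C)` automates the eyeball step by placing the cut
mid-gap so that C clusters emerge. Labels are renumbered by first
appearance in row order for stable reporting.

Reports: the feature heatmap is the per-cluster mean of per-clip feature
means on the normalized scale. Mutual information between a feature and
the labels uses a plug-in estimator on 10 quantile bins of the per-clip
mean, log base 2; its chance-level bias is ≈ (bins−1)(clusters−1)/(2N ln 2)
bits (≈ 0.04 at N = 300), which is why the pure-noise floor is assessed as
a Monte-Carlo mean over independent noise features. Cluster similarity is
`exp(−d/m)` of centroid distance d scaled by the median inter-centroid
distance m — bounded in (0, 1], diagonal 1; highly similar clusters are
candidates for merging. The representative clip is the medoid (minimum
summed feature distance to cluster members; ties to the lowest clip id).

## Tracking evaluation

CLEAR-MOT adapted to keypoints: the evaluated objects are individual
keypoints, matched per anatomical index by minimum-total-distance
assignment among pairs within τ × diagonal of the *ground-truth* animal's
box (τ = 0.05; the ground-truth box keeps the threshold
prediction-independent). MOTA = 100·(1 − (misses + FP + mismatches)/gt
keypoints). Identity mismatches are animal-level events: a ground-truth
identity's associated predicted id (majority vote over its matched
keypoints) changing between consecutive matched frames, with a
simultaneous pairwise exchange counted as a single swap event — so an
injected swap-and-swap-back scores exactly 2. MOTP is reported as percent
localization similarity, 100 · mean(1 − d/(τ·diagonal)) over matches,
putting it on the same 0–100 scale as MOTA; this is a convention choice,
not a claim of bit-compatibility with any external evaluator. AP ranks all
predictions of one keypoint index by confidence across frames, matches
greedily to unused ground truth within threshold, and integrates the
all-points precision–recall curve; mAP averages over keypoint indices.
ARI is the standard permutation-model index (delegated to scikit-learn,
cross-checked in tests against a pair-counting oracle).

## Synthetic arena

The simulator drives a four-keypoint rigid-ish mouse (snout 0.5 L ahead of
the body center, ears 0.15 L forward and ±0.2 L lateral, tail base 0.5 L
behind; L = 60 px body length in a 640×480 px cage) through a schedule of
motif segments: walking (6 px/frame, wandering heading, wall reflection),
turning (0.15 rad/frame), still grooming (near-zero displacement with head
jitter), rearing proxy (body-length compression), chase/follow (the
follower steers toward a station 1–2 L behind the leader), anogenital
sniffing (follower snout pinned ~0.15 L behind the leader's tail base) and
nose-to-nose (facing poses, snout gap ~0.15 L). All motif kinematics are
invented proxies — the real behaviors have no published generative model —
and live in one config block. Observations add Gaussian keypoint noise
(default σ = 1.2 px = 2% of body length, typical detector jitter), drop
detections at 0.5% per animal-frame, shuffle per-frame detection order and
strip identities. All randomness flows from a single seeded generator, so
sessions are bit-reproducible.

Two physical-realism constraints matter for what the benchmarks can show.
First, bodies are solid: centers keep a minimum separation of 0.45 L, and
identity-crossing episodes steer the follower *past* a point 0.45 L beside
the leader at capped speed (10 px/frame) — the bounding boxes overlap
heavily (IOU > 0.3) but the bodies never coincide. A full-coincidence pass
would make identity unrecoverable for any geometric tracker (and is
impossible for real mice), so the ≥ 99% tracking accuracy the benchmark
demonstrates should be read as robustness to realistic brush-past
crossings, not to true occlusion or overlap of bodies. Second, the
motif-clustering benchmark generates each clip as an independent
15-frame pure-motif episode with role-symmetric dyad geometry (side-by-side
anti-parallel for individual motifs, station placement for social ones) and
a narrow separation band. This realizes within-motif feature spreads small
enough that the planted effects exceed 3 pooled standard deviations; real
sessions mix motifs mid-clip and have far more geometric variety, so the
ARI achieved here is an upper bound on, not a prediction of, real-data
agreement with human annotation.

### Problem sizes

The standard tracking benchmark is 1,000 frames × 2 mice (σ = 2% of body
length, 0.5% dropout, 3 crossing episodes). The clustering benchmark is
150 clips (50 per motif) × 2 reference choices = 300 rows × 525 columns.
Kalman evaluation uses 200-frame tracks × 20 replicates; the chance-ARI
baseline 200 random partition pairs of 1,000 items. These sizes make every
result reproducible on a laptop in seconds while keeping Monte-Carlo
fluctuations well inside the asserted margins.

## Known limitations

* The tracker is frame-to-frame greedy with no motion model in the
  matcher; long occlusions (beyond `max_gap`) re-seed identities.
* MOTP's percent-similarity convention and the cluster-similarity kernel
  are this package's own definitions; compare across tools with care.
* The curation re-filter runs only inside the interval, so it inherits the
  interval's erroneous observations as soft evidence; it improves but does
  not replace the observations.
* The feature dictionary assumes the four-keypoint mouse schema for its
  named features; other schemas can use custom features but not the
  built-ins.
* Clustering quality on real videos depends on homogeneous imaging
  (angle, scale); heterogeneous recordings produce condition-specific
  clusters rather than uniform behavior patterns.
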