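"""Identity association across frames for near-identical animals.

Appearance-based re-identification fails when animals look alike, so
identities are propagated with a purely geometric *hierarchical descriptor*:
the whole-body bounding box plus one small "part box" centered on each
keypoint. The similarity of two descriptors from adjacent frames is

    Sim(D_i, D_j) = IOU(body_i, body_j) + (1/n) * sum_k IOU(P_ik, P_jk)

so it lies in [0, 2]: the body term captures position, the part-box average
captures orientation and pose. Matching is sorted-greedy: all cross-frame
pairs are scored, the globally most similar unassigned pair is linked,
then the next, until one side is exhausted.

Part boxes are squares with side ``part_box_scale`` times the body-box
diagonal (default 0.1), which makes the descriptor scale-invariant across
image resolutions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from motiftrack.pose_io import (
    BoundingBox,
    FrameDetections,
    PoseInstance,
    TrackedSequence,
)

logger = logging.getLogger(__name__)

_DEGENERATE_SIDE_EPS = 1e-6


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 for disjoint or zero-area."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    if union <= 0.0:
        return 0.0
    return inter / union


@dataclass(frozen=True)
class Descriptor:
    """Hierarchical box descriptor for one animal in one frame."""

    instance: PoseInstance
    body_box: BoundingBox
    part_boxes: tuple[BoundingBox, ...]
    degenerate: bool = False

    @property
    def n(self) -> int:
        return len(self.part_boxes)


def build_descriptor(inst: PoseInstance, part_box_scale: float = 0.1) -> Descriptor:
    """Build the body-box + part-box descriptor for a pose instance.

    Part boxes are squares centered on each keypoint with side
    ``part_box_scale * diagonal(body box)``; they may extend beyond the body
    box (no clipping). A zero-diagonal body box yields a descriptor flagged
    ``degenerate`` with a minimum epsilon side.
    """
    if part_box_scale <= 0:
        raise ValueError(f"part_box_scale must be positive, got {part_box_scale}")
    diag = inst.box.diagonal
    degenerate = diag <= 0.0
    side = max(part_box_scale * diag, _DEGENERATE_SIDE_EPS if degenerate else 0.0)
    if side <= 0.0:  # defensive; diag > 0 implies side > 0
        side = _DEGENERATE_SIDE_EPS
    half = 0.5 * side
    parts = tuple(
        BoundingBox(kp.x - half, kp.y - half, kp.x + half, kp.y + half)
        for kp in inst.keypoints
    )
    return Descriptor(inst, inst.box, parts, degenerate=degenerate)


def similarity(d1: Descriptor, d2: Descriptor) -> float:
    """Descriptor similarity in [0, 2]: body IOU + mean part-box IOU.

    Part boxes are compared at matching keypoint index (snout with snout,
    tail base with tail base, ...).
    """
    if d1.n != d2.n:
        raise ValueError(f"keypoint count mismatch: {d1.n} vs {d2.n}")
    body = iou(d1.body_box, d2.body_box)
    if d1.n == 0:
        return body
    parts = sum(iou(p, q) for p, q in zip(d1.part_boxes, d2.part_boxes))
    return body + parts / d1.n


@dataclass(frozen=True)
class MatchResult:
    """Outcome of sorted-greedy matching between two frames.

    ``pairs`` holds (prev descriptor, next descriptor, similarity), sorted by
    descending similarity in the order the greedy procedure linked them.
    """

    pairs: tuple[tuple[Descriptor, Descriptor, float], ...]
    unmatched_prev: tuple[Descriptor, ...]
    unmatched_next: tuple[Descriptor, ...]


def match_frames(
    prev: list[Descriptor],
    next: list[Descriptor],
    min_match_similarity: float = 0.0,
) -> MatchResult:
    """Greedily link descriptors across adjacent frames by similarity.

    All pairwise similarities are computed; the globally highest-scoring
    pair whose members are both unassigned is linked first, then the next,
    repeating until either side is exhausted. Ties break deterministically
    by (lower prev index, lower next index). Pairs scoring strictly below
    ``min_match_similarity`` are never linked; with the default 0 even
    zero-similarity pairs are linked while both sides have members left.
    """
    scores = [[similarity(p, q) for q in next] for p in prev]
    selected = greedy_select(scores, min_score=min_match_similarity)
    used_prev = {i for i, _, _ in selected}
    used_next = {j for _, j, _ in selected}
    return MatchResult(
        pairs=tuple((prev[i], next[j], s) for i, j, s in selected),
        unmatched_prev=tuple(p for i, p in enumerate(prev) if i not in used_prev),
        unmatched_next=tuple(q for j, q in enumerate(next) if j not in used_next),
    )


def greedy_select(
    scores, min_score: float = 0.0
) -> list[tuple[int, int, float]]:
    """Sorted-greedy selection on a rows-by-columns score matrix.

    Returns (row, column, score) triples in the order linked: repeatedly the
    globally highest-scoring pair with both members unassigned, ties broken
    by (lower row, lower column), until either side is exhausted or only
    pairs below ``min_score`` remain.
    """
    flat = [
        (float(s), i, j)
        for i, row in enumerate(scores)
        for j, s in enumerate(row)
    ]
    flat.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_i: set[int] = set()
    used_j: set[int] = set()
    out: list[tuple[int, int, float]] = []
    for s, i, j in flat:
        if i in used_i or j in used_j:
            continue
        if s < min_score:
            break
        used_i.add(i)
        used_j.add(j)
        out.append((i, j, s))
    return out


def track_sequence(
    frames: list[FrameDetections],
    max_ids: int = 2,
    part_box_scale: float = 0.1,
    max_gap: int = 5,
    min_match_similarity: float = 0.0,
    fps: float = 25.0,
    num_pose: int = 4,
) -> TrackedSequence:
    """Assemble persistent tracks from time-ordered per-frame detections.

    The first frame's detections receive ids 1..m in detection order (ids
    are arbitrary labels; evaluation treats them up to permutation). Each
    later frame is matched against the most recent descriptor of every
    *active* id — an id stays active for at most ``max_gap`` frames without
    a match, then retires. Unmatched detections open fresh ids while fewer
    than ``max_ids`` are alive in the frame's candidate pool; surplus
    detections are dropped lowest-mean-confidence first and logged.
    """
    prev_index = None
    for fr in frames:
        if prev_index is not None and fr.frame_index <= prev_index:
            raise ValueError("frames out of order")
        prev_index = fr.frame_index

    # active id -> (descriptor, frame index of last match)
    active: dict[int, tuple[Descriptor, int]] = {}
    out_frames: list[FrameDetections] = []

    for fr in frames:
        # retire ids unseen for more than max_gap frames
        active = {
            tid: (d, last)
            for tid, (d, last) in active.items()
            if fr.frame_index - last <= max_gap
        }
        detections = [build_descriptor(inst, part_box_scale) for inst in fr.instances]
        id_order = sorted(active)  # deterministic tie-break by lower id
        prev_descs = [active[tid][0] for tid in id_order]
        result = match_frames(prev_descs, detections, min_match_similarity)

        desc_to_id = {id(active[tid][0]): tid for tid in id_order}
        assigned: list[tuple[int, Descriptor]] = []
        for p, q, _score in result.pairs:
            assigned.append((desc_to_id[id(p)], q))

        fresh = list(result.unmatched_next)
        free_ids = sorted(set(range(1, max_ids + 1)) - set(active))
        if len(fresh) > len(free_ids):
            # keep the most confident detections, drop and log the surplus
            fresh.sort(key=lambda d: -d.instance.mean_confidence)
            for d in fresh[len(free_ids):]:
                logger.warning(
                    "frame %d: dropping surplus detection (mean confidence %.3f)",
                    fr.frame_index, d.instance.mean_confidence,
                )
            fresh = fresh[:len(free_ids)]
        for tid, q in zip(free_ids, fresh):
            assigned.append((tid, q))

        instances = []
        for tid, q in sorted(assigned, key=lambda t: t[0]):
            instances.append(replace(q.instance, track_id=tid))
            active[tid] = (q, fr.frame_index)
        out_frames.append(FrameDetections(fr.frame_index, tuple(instances)))

    return TrackedSequence(
        frames=tuple(out_frames),
        fps=fps,
        num_pose=num_pose,
        max_ids=max_ids,
    )
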