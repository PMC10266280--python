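"""Keypoint-adapted CLEAR-MOT tracking metrics and clustering agreement.

The classical CLEAR-MOT metrics treat whole objects; here each keypoint is
the evaluated object, with an adaptive match threshold: a predicted
keypoint matches a ground-truth keypoint of the same anatomical index when
their distance is at most tau times the diagonal of the *ground-truth*
animal's bounding box (default tau = 0.05, i.e. 5% of the diagonal — the
ground-truth box so that the threshold does not depend on the prediction).

* MOTA = 100 * (1 - (misses + false positives + mismatches) / gt keypoints);
  a mismatch is an animal-level identity event, counted when a ground-truth
  identity's associated predicted track id changes between consecutive
  matched frames. MOTA can be negative.
* MOTP is reported as a percentage localization similarity,
  100 * mean(1 - d / (tau * diagonal)) over matches, so that a perfect
  tracker scores 100 — the convention that puts MOTP on the same 0-100
  scale as MOTA.
* AP per keypoint index ranks all predictions by confidence, matches them
  greedily to unused ground truth within the threshold, and integrates the
  all-points precision-recall curve; mAP averages over keypoint indices.

Clustering agreement uses the standard permutation-model Adjusted Rand
Index: 1 for identical partitions, near 0 for random ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from motiftrack.pose_io import FrameDetections, TrackedSequence

_BIG = 1e9


@dataclass(frozen=True)
class MatchRule:
    """Keypoint match threshold: fraction tau of the gt box diagonal."""

    tau: float = 0.05

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class KeypointMatches:
    """Per-keypoint-index correspondence for one frame."""

    # per keypoint index: list of (gt instance idx, pred instance idx,
    # distance, threshold used)
    matches: dict[int, list[tuple[int, int, float, float]]]
    misses: dict[int, list[int]]
    false_positives: dict[int, list[int]]


@dataclass(frozen=True)
class MOTReport:
    mota: float
    motp: float
    map: float
    misses: int
    false_positives: int
    mismatches: int
    gt_keypoints: int
    frames_evaluated: int
    per_keypoint: dict[int, dict[str, float]] = field(default_factory=dict)


def match_keypoints(
    pred: FrameDetections,
    gt: FrameDetections,
    rule: MatchRule = MatchRule(),
) -> KeypointMatches:
    """Minimum-total-distance one-to-one keypoint assignment per index.

    For each anatomical keypoint index the candidate pairs within the
    threshold are assigned by the Hungarian algorithm; unmatched ground
    truth are misses, unmatched predictions false positives.
    """
    if pred.frame_index != gt.frame_index:
        raise ValueError("frames differ")
    K = max(
        [i.num_keypoints for i in list(gt.instances) + list(pred.instances)],
        default=0,
    )
    matches: dict[int, list[tuple[int, int, float, float]]] = {}
    misses: dict[int, list[int]] = {}
    fps: dict[int, list[int]] = {}
    for k in range(K):
        gts = [
            (gi, inst.keypoints[k], rule.tau * inst.box.diagonal)
            for gi, inst in enumerate(gt.instances)
            if k < inst.num_keypoints
        ]
        preds = [
            (pi, inst.keypoints[k])
            for pi, inst in enumerate(pred.instances)
            if k < inst.num_keypoints
        ]
        cost = np.full((len(gts), len(preds)), _BIG)
        for a, (_, gkp, thr) in enumerate(gts):
            for b, (_, pkp) in enumerate(preds):
                d = float(np.hypot(gkp.x - pkp.x, gkp.y - pkp.y))
                if d <= thr:
                    cost[a, b] = d
        mk: list[tuple[int, int, float, float]] = []
        used_g: set[int] = set()
        used_p: set[int] = set()
        if cost.size:
            rows, cols = linear_sum_assignment(cost)
            for a, b in zip(rows, cols):
                if cost[a, b] >= _BIG:
                    continue
                mk.append((gts[a][0], preds[b][0], cost[a, b], gts[a][2]))
                used_g.add(a)
                used_p.add(b)
        matches[k] = mk
        misses[k] = [gts[a][0] for a in range(len(gts)) if a not in used_g]
        fps[k] = [preds[b][0] for b in range(len(preds)) if b not in used_p]
    return KeypointMatches(matches=matches, misses=misses, false_positives=fps)


def _frame_identity_map(
    pred: FrameDetections, gt: FrameDetections, km: KeypointMatches
) -> dict[int, int]:
    """gt track id -> predicted track id, by majority vote over the gt
    animal's matched keypoints (ties -> lowest predicted id)."""
    votes: dict[int, dict[int, int]] = {}
    for k, mk in km.matches.items():
        for gi, pi, _d, _t in mk:
            g_id = gt.instances[gi].track_id
            p_id = pred.instances[pi].track_id
            if g_id is None or p_id is None:
                continue
            votes.setdefault(g_id, {}).setdefault(p_id, 0)
            votes[g_id][p_id] += 1
    out: dict[int, int] = {}
    for g_id, tally in votes.items():
        best = max(tally.items(), key=lambda t: (t[1], -t[0]))
        out[g_id] = best[0]
    return out


def _count_switch_events(last: dict[int, int], now: dict[int, int]) -> int:
    """Identity mismatch events between consecutive matched frames.

    A ground-truth identity whose associated predicted id changed is one
    event — except that a simultaneous pairwise exchange (two identities
    trading predicted ids) is a single swap event, so that an injected
    swap-and-swap-back sequence counts exactly 2 mismatches.
    """
    changed = [g for g, p in now.items() if g in last and last[g] != p]
    events = 0
    done: set[int] = set()
    for g in changed:
        if g in done:
            continue
        partner = next(
            (h for h in changed
             if h != g and h not in done
             and last.get(h) == now[g] and now.get(h) == last[g]),
            None,
        )
        done.add(g)
        if partner is not None:
            done.add(partner)
        events += 1
    return events


def mota_motp(
    pred: TrackedSequence,
    gt: TrackedSequence,
    rule: MatchRule = MatchRule(),
) -> MOTReport:
    """Compute MOTA / MOTP / mAP over the frames common to both sequences."""
    if pred.num_pose != gt.num_pose:
        raise ValueError("keypoint schemas differ")
    if pred.fps != gt.fps:
        raise ValueError("frame rates differ")
    pred_by = {f.frame_index: f for f in pred.frames}
    gt_by = {f.frame_index: f for f in gt.frames}
    common = sorted(set(pred_by) & set(gt_by))

    n_miss = n_fp = n_mm = n_gt = 0
    sum_sim = 0.0
    n_match = 0
    per_k: dict[int, dict[str, float]] = {
        k: {"misses": 0, "false_positives": 0, "matches": 0, "sim": 0.0}
        for k in range(gt.num_pose)
    }
    last_map: dict[int, int] = {}
    for f in common:
        pf, gf = pred_by[f], gt_by[f]
        n_gt += sum(i.num_keypoints for i in gf.instances)
        km = match_keypoints(pf, gf, rule)
        for k in range(gt.num_pose):
            mk = km.matches.get(k, [])
            per_k[k]["matches"] += len(mk)
            per_k[k]["misses"] += len(km.misses.get(k, []))
            per_k[k]["false_positives"] += len(km.false_positives.get(k, []))
            for _gi, _pi, d, thr in mk:
                s = 1.0 - d / thr
                per_k[k]["sim"] += s
                sum_sim += s
                n_match += 1
            n_miss += len(km.misses.get(k, []))
            n_fp += len(km.false_positives.get(k, []))
        fmap = _frame_identity_map(pf, gf, km)
        n_mm += _count_switch_events(last_map, fmap)
        last_map.update(fmap)

    mota = 100.0 * (1.0 - (n_miss + n_fp + n_mm) / n_gt) if n_gt else 100.0
    motp = 100.0 * (sum_sim / n_match) if n_match else 0.0
    ap_per_k, map_ = keypoint_ap(pred, gt, rule)
    per_keypoint = {
        k: {
            "motp": 100.0 * v["sim"] / v["matches"] if v["matches"] else 0.0,
            "misses": v["misses"],
            "false_positives": v["false_positives"],
            "matches": v["matches"],
            "ap": ap_per_k.get(k, 0.0),
        }
        for k, v in per_k.items()
    }
    return MOTReport(
        mota=mota,
        motp=motp,
        map=map_,
        misses=n_miss,
        false_positives=n_fp,
        mismatches=n_mm,
        gt_keypoints=n_gt,
        frames_evaluated=len(common),
        per_keypoint=per_keypoint,
    )


def keypoint_ap(
    pred: TrackedSequence,
    gt: TrackedSequence,
    rule: MatchRule = MatchRule(),
) -> tuple[dict[int, float], float]:
    """Per-keypoint average precision (%) and their mean (mAP).

    All predictions of one keypoint index are ranked by confidence across
    frames and matched greedily to the nearest unused ground-truth keypoint
    of the same frame within the threshold; AP is the area under the
    all-points precision-recall curve.
    """
    pred_by = {f.frame_index: f for f in pred.frames}
    gt_by = {f.frame_index: f for f in gt.frames}
    common = sorted(set(pred_by) & set(gt_by))
    K = gt.num_pose
    ap: dict[int, float] = {}
    for k in range(K):
        entries = []  # (confidence, frame, x, y)
        for f in common:
            for inst in pred_by[f].instances:
                if k < inst.num_keypoints:
                    kp = inst.keypoints[k]
                    entries.append((kp.confidence, f, kp.x, kp.y))
        gts: dict[int, list[tuple[float, float, float, bool]]] = {}
        npos = 0
        for f in common:
            for inst in gt_by[f].instances:
                if k < inst.num_keypoints:
                    kp = inst.keypoints[k]
                    gts.setdefault(f, []).append(
                        [kp.x, kp.y, rule.tau * inst.box.diagonal, False]
                    )
                    npos += 1
        entries.sort(key=lambda e: (-e[0], e[1]))
        tp = np.zeros(len(entries))
        for i, (_conf, f, x, y) in enumerate(entries):
            best_j, best_d = -1, np.inf
            for j, g in enumerate(gts.get(f, [])):
                if g[3]:
                    continue
                d = float(np.hypot(g[0] - x, g[1] - y))
                if d <= g[2] and d < best_d:
                    best_j, best_d = j, d
            if best_j >= 0:
                gts[f][best_j][3] = True
                tp[i] = 1.0
        if npos == 0:
            ap[k] = 100.0
            continue
        if len(entries) == 0:
            ap[k] = 0.0
            continue
        cum_tp = np.cumsum(tp)
        recall = cum_tp / npos
        precision = cum_tp / np.arange(1, len(entries) + 1)
        # all-points interpolation: precision envelope from the right
        env = np.maximum.accumulate(precision[::-1])[::-1]
        r_prev = 0.0
        area = 0.0
        for r, p in zip(recall, env):
            area += (r - r_prev) * p
            r_prev = r
        ap[k] = 100.0 * area
    return ap, float(np.mean(list(ap.values()))) if ap else 0.0


def adjusted_rand_index(a, b) -> float:
    """Permutation-model ARI between two labelings of the same items."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(adjusted_rand_score(a, b))


def identity_accuracy(pred: TrackedSequence, gt: TrackedSequence) -> float:
    """Frame-wise identity accuracy of detected animals, up to permutation.

    Per frame, predicted instances are paired with ground-truth instances
    by minimum body-center distance (Hungarian). The gt-to-pred id
    permutation is fixed on the first frame with matches; thereafter a
    paired instance is correct when its predicted id equals the fixed
    mapping of its gt id. Returns correct / paired over all common frames.
    """
    pred_by = {f.frame_index: f for f in pred.frames}
    gt_by = {f.frame_index: f for f in gt.frames}
    common = sorted(set(pred_by) & set(gt_by))
    mapping: dict[int, int] = {}
    correct = total = 0
    for f in common:
        pf, gf = pred_by[f], gt_by[f]
        if not pf.instances or not gf.instances:
            continue
        pc = np.array([i.box.center for i in pf.instances])
        gc = np.array([i.box.center for i in gf.instances])
        cost = np.linalg.norm(gc[:, None, :] - pc[None, :, :], axis=2)
        rows, cols = linear_sum_assignment(cost)
        pairs = [
            (gf.instances[a].track_id, pf.instances[b].track_id)
            for a, b in zip(rows, cols)
        ]
        if not mapping:
            mapping = {g: p for g, p in pairs if g is not None and p is not None}
        for g, p in pairs:
            if g is None or p is None or g not in mapping:
                continue
            total += 1
            if mapping[g] == p:
                correct += 1
    return correct / total if total else 1.0
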