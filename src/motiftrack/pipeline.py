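"""Convenience glue joining the stages into runnable workflows."""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from motiftrack.arena import SimulatedSession
from motiftrack.features import (
    Clip,
    FeatureConfig,
    FeatureTable,
    build_feature_table,
    extract_clips,
)
from motiftrack.tracking import track_sequence
from motiftrack.pose_io import TrackedSequence


def track_session(session: SimulatedSession, **kwargs) -> TrackedSequence:
    """Run identity tracking on a simulated session's noisy detections."""
    return track_sequence(
        list(session.detections),
        max_ids=session.ground_truth.max_ids,
        fps=session.ground_truth.fps,
        num_pose=session.ground_truth.num_pose,
        **kwargs,
    )


def motif_clip_set(
    sessions: Sequence[SimulatedSession],
    labels: Sequence[str],
    window: int = 15,
) -> tuple[list[Clip], list[str]]:
    """One clip per pure-motif session, with globally unique clip ids."""
    clips: list[Clip] = []
    kept: list[str] = []
    for i, (sess, lab) in enumerate(zip(sessions, labels)):
        cs = extract_clips(sess.ground_truth, window=window)
        if not cs:
            continue
        clips.append(replace(cs[0], clip_id=i))
        kept.append(lab)
    return clips, kept


def motif_feature_table(
    sessions: Sequence[SimulatedSession],
    labels: Sequence[str],
    cfg: FeatureConfig | None = None,
    window: int = 15,
) -> tuple[FeatureTable, np.ndarray]:
    """Feature table over a pure-motif clip set plus per-row labels.

    Each clip contributes one row per reference-animal choice; rows carry
    the clip's motif label.
    """
    clips, kept = motif_clip_set(sessions, labels, window)
    label_by_clip = {c.clip_id: kept[i] for i, c in enumerate(clips)}
    table = build_feature_table(clips, cfg or FeatureConfig())
    row_labels = np.array([label_by_clip[cid] for cid in table.clip_ids])
    return table, row_labels
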