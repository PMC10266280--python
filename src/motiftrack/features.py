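"""Pose clips, rigid alignment, and the behavioral feature dictionary.

Behavior is analyzed in *clips*: windows of W consecutive tracked frames
(default W = 15, i.e. 500 ms at 25 fps, matching the sub-second timescale of
rodent action blocks). One animal of the dyad is designated the *reference*
mouse; the other is the *non-reference* (feature suffix ``_TO``) mouse. For
directional features the scene is rigidly aligned so that the reference
mouse's body at the clip's middle frame lies on the positive x axis: its
tail base maps to the origin and its snout to (body_length, 0).

Geometric conventions (the vectors the features are built from):

* body vector: tail base -> snout,
* head vector: ear midpoint -> snout,
* body center: midpoint of snout and tail base,
* signed angles use the image coordinate system as given (y down);
  ``sin`` is the cross product term, ``cos`` the dot product term, both
  normalized. Angles between two vectors are rotation-invariant; directions
  (of displacements and inter-animal vectors) are measured in the aligned
  frame.

The built-in dictionary covers per-animal kinematics (body length, ear
distances and angles, frame-to-frame displacement) for both animals plus
social geometry (relative body/head orientation, snout-snout and
snout-tail-base vectors). Users can register custom features over the five
intermediate pose arrays; they participate in weighting and normalization
exactly like built-ins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from motiftrack.pose_io import TrackedSequence

logger = logging.getLogger(__name__)

SNOUT, LEFT_EAR, RIGHT_EAR, TAIL_BASE = 0, 1, 2, 3

#: Per-animal features of the reference mouse (suffix-free). The same
#: features with suffix ``_TO`` describe the non-reference mouse.
INDIVIDUAL_FEATURES = (
    "body_length",
    "body_change_sin",
    "left_ear",
    "left_ear_cos",
    "left_ear_sin",
    "right_ear",
    "right_ear_cos",
    "right_ear_sin",
    "displace_rho",
    "displace_sin",
    "displace_cos",
)

#: Inter-animal features (zero-weighted in individual mode).
SOCIAL_FEATURES = (
    "two_body_sin",
    "two_body_cos",
    "two_head_sin",
    "two_head_cos",
    "TM_nose_RM_tail_rho",
    "TM_nose_RM_tail_sin",
    "TM_nose_RM_tail_cos",
    "RM_nose_TM_tail_rho",
    "RM_nose_TM_tail_sin",
    "RM_nose_TM_tail_cos",
    "nose_nose_rho",
    "nose_nose_sin",
    "nose_nose_cos",
)

FEATURE_NAMES = (
    INDIVIDUAL_FEATURES
    + tuple(f"{name}_TO" for name in INDIVIDUAL_FEATURES)
    + SOCIAL_FEATURES
)

#: registry of user-defined features: name -> fn(intermediates) -> (W,) array
_CUSTOM_FEATURES: dict[str, Callable[[Mapping[str, np.ndarray]], np.ndarray]] = {}


@dataclass(frozen=True)
class Clip:
    """A W-frame window of poses for all animals of the scene.

    ``data`` has shape (animals, W, K, 3) with the last axis (x, y,
    confidence). ``track_ids[a]`` is the persistent id of animal axis a.
    ``reference``/``non_reference`` index the animal axis.
    """

    clip_id: int
    start_frame: int
    data: np.ndarray
    track_ids: tuple[int, ...]
    reference: int = 0
    non_reference: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[3] != 3:
            raise ValueError("clip data must have shape (animals, W, K, 3)")
        if self.non_reference is not None and self.non_reference == self.reference:
            raise ValueError("reference and non-reference must differ")

    @property
    def n_animals(self) -> int:
        return self.data.shape[0]

    @property
    def window(self) -> int:
        return self.data.shape[1]

    @property
    def middle(self) -> int:
        return self.window // 2

    def with_reference(self, reference: int) -> "Clip":
        others = [a for a in range(self.n_animals) if a != reference]
        return replace(
            self, reference=reference,
            non_reference=others[0] if others else None,
        )


@dataclass(frozen=True)
class AlignedClip:
    """Clip geometry after a rigid transform, plus the transform itself."""

    clip: Clip
    data: np.ndarray            # same shape as clip.data, coordinates aligned
    anchor: str                 # 'self' or 'reference'
    translation: tuple[float, float]
    rotation: float             # radians, applied after translation


@dataclass(frozen=True)
class FeatureSeries:
    """One named per-frame feature series of one clip."""

    name: str
    values: np.ndarray
    units: str = "pixels"


@dataclass
class FeatureConfig:
    """Weights, normalization and social gating for the feature table.

    ``weights`` maps feature name -> non-negative weight; unlisted features
    default to 1. ``norm`` is ``'zscore_all'`` (z-score each (feature,
    frame-position) column across clips) or ``'none'``.
    ``distance_threshold`` gates social clips: a clip enters the table only
    if the two animals' body centers come within this distance (pixels) at
    some frame. Individual mode is expressed as an infinite threshold plus
    zero weights on the social features (see :meth:`individual`).
    """

    weights: dict[str, float] = field(default_factory=dict)
    norm: str = "zscore_all"
    distance_threshold: float = math.inf
    window: int = 15

    def __post_init__(self) -> None:
        if self.norm not in ("zscore_all", "none"):
            raise ValueError(f"unknown norm {self.norm!r}")
        for name, w in self.weights.items():
            if w < 0:
                raise ValueError(f"negative weight for {name!r}")

    def weight(self, name: str) -> float:
        return self.weights.get(name, 1.0)

    @classmethod
    def individual(cls, **kwargs) -> "FeatureConfig":
        """Config for individual-behavior mode: social features weighted 0
        and the distance gate disabled (threshold beyond any cage)."""
        weights = dict(kwargs.pop("weights", {}))
        for name in SOCIAL_FEATURES:
            weights.setdefault(name, 0.0)
        return cls(weights=weights, distance_threshold=math.inf, **kwargs)


@dataclass(frozen=True)
class FeatureTable:
    """Clips-by-(features x W) matrix after normalization and weighting."""

    values: np.ndarray               # (n_rows, n_features * W)
    feature_names: tuple[str, ...]
    window: int
    clip_ids: tuple[int, ...]
    references: tuple[int, ...]      # reference track id per row
    start_frames: tuple[int, ...]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def feature_block(self, name: str) -> np.ndarray:
        """The (n_rows, W) column block of one feature."""
        i = self.feature_names.index(name)
        return self.values[:, i * self.window:(i + 1) * self.window]

    def per_clip_means(self) -> np.ndarray:
        """(n_rows, n_features) matrix of per-clip means of each feature."""
        n_feat = len(self.feature_names)
        return self.values.reshape(self.n_rows, n_feat, self.window).mean(axis=2)

    def to_dataframe(self) -> pd.DataFrame:
        cols = [
            f"{name}@{t}"
            for name in self.feature_names
            for t in range(self.window)
        ]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "clip_id", self.clip_ids)
        df.insert(1, "reference", self.references)
        df.insert(2, "start_frame", self.start_frames)
        return df


# ---------------------------------------------------------------------------
# Clip extraction
# ---------------------------------------------------------------------------

def extract_clips(
    seq: TrackedSequence,
    window: int = 15,
    stride: int | None = None,
    max_missing: float = 0.2,
    confidence_floor: float = 0.1,
) -> list[Clip]:
    """Cut a fully tracked sequence into W-frame clips.

    Windows are placed at the given stride (default ``window``,
    non-overlapping) over runs of consecutive frames in which every track
    is present. A clip is dropped (and logged) when any animal has more
    than ``max_missing`` of its keypoint observations below
    ``confidence_floor``; surviving low-confidence observations are
    linearly interpolated in time from confident neighbors.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    stride = window if stride is None else stride

    ids = sorted(
        {i.track_id for fr in seq.frames for i in fr.instances if i.track_id}
    )
    if not ids:
        return []
    K = seq.num_pose
    by_frame = {fr.frame_index: fr for fr in seq.frames}
    indices = [fr.frame_index for fr in seq.frames]

    clips: list[Clip] = []
    clip_id = 0
    start = 0
    while start + window <= len(indices):
        fidx = indices[start:start + window]
        if fidx[-1] - fidx[0] != window - 1:
            start += 1  # gap in frame numbering: slide to the next run
            continue
        present = all(
            {i.track_id for i in by_frame[f].instances} >= set(ids)
            for f in fidx
        )
        if not present:
            start += stride
            continue
        data = np.zeros((len(ids), window, K, 3))
        for a, tid in enumerate(ids):
            for t, f in enumerate(fidx):
                inst = next(
                    i for i in by_frame[f].instances if i.track_id == tid
                )
                for k, kp in enumerate(inst.keypoints):
                    data[a, t, k] = (kp.x, kp.y, kp.confidence)
        low = data[..., 2] < confidence_floor        # (A, W, K)
        if (low.reshape(len(ids), -1).mean(axis=1) > max_missing).any():
            logger.info(
                "dropping clip at frame %d: too many low-confidence keypoints",
                fidx[0],
            )
            start += stride
            continue
        data = _interpolate_low_confidence(data, low)
        clips.append(
            Clip(
                clip_id=clip_id,
                start_frame=fidx[0],
                data=data,
                track_ids=tuple(ids),
                reference=0,
                non_reference=1 if len(ids) > 1 else None,
            )
        )
        clip_id += 1
        start += stride
    return clips


def _interpolate_low_confidence(data: np.ndarray, low: np.ndarray) -> np.ndarray:
    """Linearly interpolate (x, y) of low-confidence observations in time."""
    out = data.copy()
    A, W, K, _ = data.shape
    t = np.arange(W)
    for a in range(A):
        for k in range(K):
            bad = low[a, :, k]
            if not bad.any() or bad.all():
                continue
            good = ~bad
            for c in (0, 1):
                out[a, bad, k, c] = np.interp(t[bad], t[good], data[a, good, k, c])
    return out


# ---------------------------------------------------------------------------
# Rigid alignment
# ---------------------------------------------------------------------------

def _rigid_transform(tail: np.ndarray, snout: np.ndarray):
    """Translation + rotation mapping ``tail``->origin, ``snout``->(+x)."""
    body = snout - tail
    norm = float(np.hypot(body[0], body[1]))
    if norm < 1e-12:
        raise ValueError("degenerate body vector: snout coincides with tail base")
    phi = math.atan2(body[1], body[0])
    c, s = math.cos(phi), math.sin(phi)
    R = np.array([[c, s], [-s, c]])  # rotates the body vector onto +x
    return tail, R, phi


def align_clip(clip: Clip, anchor: str = "reference") -> AlignedClip:
    """Rigidly align a clip to an anchor animal's middle-frame body axis.

    ``anchor='reference'`` uses the reference animal, ``'self'`` the
    non-reference animal (for its intrinsic directional features). The same
    translation + rotation is applied to every frame of every animal, so
    all distances are preserved; the anchor animal's middle-frame tail base
    lands on the origin and its snout on the positive x axis.
    """
    if anchor == "reference":
        a = clip.reference
    elif anchor == "self":
        if clip.non_reference is None:
            raise ValueError("clip has no non-reference animal")
        a = clip.non_reference
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    mid = clip.middle
    tail = clip.data[a, mid, TAIL_BASE, :2].astype(float)
    snout = clip.data[a, mid, SNOUT, :2].astype(float)
    origin, R, phi = _rigid_transform(tail, snout)
    out = clip.data.copy()
    xy = out[..., :2] - origin
    out[..., :2] = xy @ R.T
    return AlignedClip(
        clip=clip, data=out, anchor=anchor,
        translation=(-float(origin[0]), -float(origin[1])), rotation=-phi,
    )


# ---------------------------------------------------------------------------
# Feature computation
# ---------------------------------------------------------------------------

def _angle_between(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(sin, cos) of the signed angle from u to v, per frame; neutral (0, 1)
    where either vector vanishes."""
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    dot = u[:, 0] * v[:, 0] + u[:, 1] * v[:, 1]
    denom = np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    ok = denom > 1e-12
    s = np.where(ok, cross / np.where(ok, denom, 1.0), 0.0)
    c = np.where(ok, dot / np.where(ok, denom, 1.0), 1.0)
    return s, c


def _direction(v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rho, sin, cos) of per-frame vectors relative to the +x axis."""
    rho = np.linalg.norm(v, axis=1)
    ok = rho > 1e-12
    s = np.where(ok, v[:, 1] / np.where(ok, rho, 1.0), 0.0)
    c = np.where(ok, v[:, 0] / np.where(ok, rho, 1.0), 1.0)
    return rho, s, c


def _individual_features(pose: np.ndarray, aligned: np.ndarray) -> dict[str, np.ndarray]:
    """Per-animal features; ``pose`` raw (W, K, 2) for invariant quantities,
    ``aligned`` (W, K, 2) for displacement directions."""
    snout, lear, rear, tail = (pose[:, i] for i in range(4))
    body = snout - tail
    out: dict[str, np.ndarray] = {}
    out["body_length"] = np.linalg.norm(body, axis=1)

    s, _ = _angle_between(body[:-1], body[1:])
    out["body_change_sin"] = np.concatenate([[0.0], s])

    for name, ear in (("left_ear", lear), ("right_ear", rear)):
        vec = ear - snout  # snout -> ear vector
        out[name] = np.linalg.norm(vec, axis=1)
        s, c = _angle_between(vec, body)
        out[f"{name}_sin"] = s
        out[f"{name}_cos"] = c

    center = 0.5 * (aligned[:, SNOUT] + aligned[:, TAIL_BASE])
    disp = center[1:] - center[:-1]
    rho, s, c = _direction(disp)
    out["displace_rho"] = np.concatenate([[0.0], rho])
    out["displace_sin"] = np.concatenate([[0.0], s])
    out["displace_cos"] = np.concatenate([[1.0], c])
    return out


def intermediate_arrays(clip: Clip) -> dict[str, np.ndarray]:
    """The five intermediate pose arrays custom features are defined over.

    Each is (W, K, 3): the reference mouse raw and self-aligned, the
    non-reference mouse raw, self-aligned, and aligned to the reference.
    """
    ref_aligned = align_clip(clip, "reference").data
    out = {
        "pose_clips": clip.data[clip.reference],
        "pose_clips_align": ref_aligned[clip.reference],
    }
    if clip.non_reference is not None:
        other_self = align_clip(clip, "self").data
        out["poseTheOther_clips"] = clip.data[clip.non_reference]
        out["poseTheOther_clips_alignSelf"] = other_self[clip.non_reference]
        out["poseTheOther_clips_alignToOther"] = ref_aligned[clip.non_reference]
    return out


def compute_features(clip: Clip, include_custom: bool = True) -> list[FeatureSeries]:
    """Compute the full feature dictionary for one clip.

    Intrinsic features (lengths, angles relative to the own body vector)
    are rotation-invariant; displacement directions of the reference mouse
    and all inter-animal vectors are measured in the reference-anchored
    aligned frame, the non-reference mouse's displacement direction in the
    reference-anchored frame as well, and its intrinsic angles from its own
    geometry.
    """
    arrays = intermediate_arrays(clip)
    W = clip.window
    feats: dict[str, np.ndarray] = {}

    ref_raw = arrays["pose_clips"][..., :2]
    ref_aln = arrays["pose_clips_align"][..., :2]
    feats.update(_individual_features(ref_raw, ref_aln))

    if clip.non_reference is not None:
        oth_raw = arrays["poseTheOther_clips"][..., :2]
        oth_to = arrays["poseTheOther_clips_alignToOther"][..., :2]
        for name, series in _individual_features(oth_raw, oth_to).items():
            feats[f"{name}_TO"] = series

        # social geometry in the reference-anchored frame
        r = align_clip(clip, "reference")
        ref_a = r.data[clip.reference][..., :2]
        oth_a = r.data[clip.non_reference][..., :2]
        body_r = ref_a[:, SNOUT] - ref_a[:, TAIL_BASE]
        body_o = oth_a[:, SNOUT] - oth_a[:, TAIL_BASE]
        s, c = _angle_between(body_r, body_o)
        feats["two_body_sin"], feats["two_body_cos"] = s, c
        head_r = ref_a[:, SNOUT] - 0.5 * (ref_a[:, LEFT_EAR] + ref_a[:, RIGHT_EAR])
        head_o = oth_a[:, SNOUT] - 0.5 * (oth_a[:, LEFT_EAR] + oth_a[:, RIGHT_EAR])
        s, c = _angle_between(head_r, head_o)
        feats["two_head_sin"], feats["two_head_cos"] = s, c

        pairs = {
            # reference tail base -> non-reference snout
            "TM_nose_RM_tail": oth_a[:, SNOUT] - ref_a[:, TAIL_BASE],
            # reference snout -> non-reference tail base
            "RM_nose_TM_tail": oth_a[:, TAIL_BASE] - ref_a[:, SNOUT],
            "nose_nose": oth_a[:, SNOUT] - ref_a[:, SNOUT],
        }
        for name, vec in pairs.items():
            rho, s, c = _direction(vec)
            feats[f"{name}_rho"] = rho
            feats[f"{name}_sin"] = s
            feats[f"{name}_cos"] = c

    if include_custom:
        for name, fn in _CUSTOM_FEATURES.items():
            series = np.asarray(fn(arrays), dtype=float)
            if series.shape != (W,):
                raise ValueError(
                    f"custom feature {name!r} returned shape {series.shape}, "
                    f"expected ({W},)"
                )
            feats[name] = series

    out = []
    for name, values in feats.items():
        bad = ~np.isfinite(values)
        if bad.any():
            raise ValueError(
                f"feature {name!r} produced NaN/inf at frame {int(np.argmax(bad))}"
            )
        units = "unitless" if name.endswith(("_sin", "_cos")) else "pixels"
        out.append(FeatureSeries(name, values, units))
    return out


def register_custom_feature(
    name: str,
    definition: Callable[[Mapping[str, np.ndarray]], np.ndarray],
) -> None:
    """Register a user feature over the five intermediate pose arrays.

    The callable receives the dict from :func:`intermediate_arrays` and
    must return one value per frame (a length-W array). The feature then
    participates in configuration, normalization, and weighting exactly
    like built-ins.
    """
    if name in FEATURE_NAMES or name in _CUSTOM_FEATURES:
        raise ValueError(f"feature {name!r} already defined")
    _CUSTOM_FEATURES[name] = definition


def unregister_custom_feature(name: str) -> None:
    _CUSTOM_FEATURES.pop(name, None)


def custom_feature_names() -> tuple[str, ...]:
    return tuple(_CUSTOM_FEATURES)


# ---------------------------------------------------------------------------
# Social gating and table assembly
# ---------------------------------------------------------------------------

def social_gate(clip: Clip, distance_threshold: float) -> bool:
    """True iff the animals' body centers come within the threshold at some
    frame of the clip. With a threshold at or beyond the cage diameter every
    clip passes, which is how individual mode disables the gate."""
    if clip.non_reference is None:
        return True
    centers = 0.5 * (clip.data[:, :, SNOUT, :2] + clip.data[:, :, TAIL_BASE, :2])
    d = np.linalg.norm(
        centers[clip.reference] - centers[clip.non_reference], axis=1
    )
    return bool(d.min() <= distance_threshold)


def build_feature_table(
    clips: Sequence[Clip],
    cfg: FeatureConfig | None = None,
) -> FeatureTable:
    """Assemble the normalized, weighted clips-by-features matrix.

    Every gated clip contributes one row per choice of reference animal
    (two rows for a dyad). Under ``zscore_all`` each (feature,
    frame-position) column is z-scored across rows before weighting;
    zero-variance columns become 0 with a warning rather than NaN.
    """
    cfg = cfg or FeatureConfig()
    if len(clips) < 2:
        raise ValueError("need at least 2 clips")

    rows: list[np.ndarray] = []
    meta: list[tuple[int, int, int]] = []   # clip_id, reference track id, start
    names: tuple[str, ...] | None = None
    for clip in clips:
        if not social_gate(clip, cfg.distance_threshold):
            continue
        for ref in range(clip.n_animals):
            c = clip.with_reference(ref)
            series = compute_features(c)
            if names is None:
                names = tuple(s.name for s in series)
            rows.append(np.concatenate([s.values for s in series]))
            meta.append((clip.clip_id, clip.track_ids[ref], clip.start_frame))
    if len(rows) < 2:
        raise ValueError("fewer than 2 clips passed the social gate")

    X = np.vstack(rows)
    W = clips[0].window
    if cfg.norm == "zscore_all":
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        degenerate = sd <= 1e-12
        if degenerate.any():
            logger.warning(
                "%d zero-variance feature columns set to 0 under zscore_all",
                int(degenerate.sum()),
            )
        X = np.where(degenerate, 0.0, (X - mean) / np.where(degenerate, 1.0, sd))
    w = np.repeat([cfg.weight(n) for n in names], W)
    X = X * w
    return FeatureTable(
        values=X,
        feature_names=names,
        window=W,
        clip_ids=tuple(m[0] for m in meta),
        references=tuple(m[1] for m in meta),
        start_frames=tuple(m[2] for m in meta),
    )
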