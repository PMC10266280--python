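"""Kalman smoothing of keypoint trajectories and curation propagation.

Keypoint motion between frames is modeled per keypoint with a 6-state
constant-acceleration filter, state (x, y, vx, vy, ax, ay), driven by
discrete white-noise jerk with spectral density ``q`` (pixels^2/frame^3).
Positions are observed directly with base measurement variance ``r``
(pixels^2) scaled by 1/confidence, so low-confidence detections pull the
estimate less; confidence-0 observations are treated as missing and the
filter predicts through them. A fixed-interval RTS (Rauch-Tung-Striebel)
backward smoother refines the forward pass by default.

User corrections mirror interactive curation: a correction carries the
exact coordinates at one frame plus a half-open frame interval
[in_frame, out_frame) over which the error is presumed to persist. Keypoint
corrections re-filter the interval with the corrected frame injected as a
near-zero-noise measurement; identity-swap corrections are pure relabelings
over the interval (the geometry is right, only the labels are wrong).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from motiftrack.pose_io import (
    FrameDetections,
    Keypoint,
    PoseInstance,
    TrackedSequence,
)

_CORRECTION_NOISE = 1e-9  # variance of an injected user measurement


@dataclass(frozen=True)
class FilterConfig:
    """Noise parameters of the constant-acceleration motion model.

    q: process noise spectral density, pixels^2 per frame^3.
    r: base measurement noise variance, pixels^2 (scaled by 1/confidence).
    smooth: run the RTS backward smoother after the forward pass.
    """

    q: float = 0.5
    r: float = 4.0
    smooth: bool = True

    def __post_init__(self) -> None:
        if self.q <= 0 or self.r <= 0:
            raise ValueError("q and r must be positive")


@dataclass(frozen=True)
class KeypointTrack:
    """Time series of one keypoint of one track."""

    track_id: int
    keypoint_index: int
    frames: tuple[int, ...]
    x: tuple[float, ...]
    y: tuple[float, ...]
    confidence: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.frames)
        if not (len(self.x) == len(self.y) == len(self.confidence) == n):
            raise ValueError("ragged keypoint track")
        if any(b <= a for a, b in zip(self.frames, self.frames[1:])):
            raise ValueError("frames must be strictly increasing")


@dataclass(frozen=True)
class Correction:
    """One user edit: a keypoint move or an identity swap over an interval.

    For a keypoint move, ``x``/``y`` are the corrected coordinates at
    ``frame`` and the re-filtering applies over [in_frame, out_frame).
    For an identity swap, ``swap_with`` names the second track and the
    labels are exchanged on every frame of the interval.
    """

    frame: int
    track_id: int
    in_frame: int
    out_frame: int
    keypoint_index: int | None = None
    x: float | None = None
    y: float | None = None
    swap_with: int | None = None

    def __post_init__(self) -> None:
        if not (self.in_frame <= self.frame < self.out_frame):
            raise ValueError(
                f"correction frame {self.frame} outside interval "
                f"[{self.in_frame}, {self.out_frame})"
            )
        is_swap = self.swap_with is not None
        is_move = self.keypoint_index is not None
        if is_swap == is_move:
            raise ValueError(
                "correction must be either a keypoint move or an identity swap"
            )
        if is_move and (self.x is None or self.y is None):
            raise ValueError("keypoint correction requires x and y")


# ---------------------------------------------------------------------------
# Constant-acceleration Kalman filter + RTS smoother
# ---------------------------------------------------------------------------

def _ca_matrices(q: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Transition F, observation H and process covariance Q for dt = 1."""
    f1 = np.array([[1.0, 1.0, 0.5],
                   [0.0, 1.0, 1.0],
                   [0.0, 0.0, 1.0]])
    F = np.kron(f1, np.eye(2))  # state order (x, y, vx, vy, ax, ay)
    H = np.zeros((2, 6))
    H[0, 0] = 1.0
    H[1, 1] = 1.0
    # continuous white-noise jerk integrated over one frame
    g = np.array([1.0 / 6.0, 0.5, 1.0])
    q1 = q * np.outer(g, g)
    Q = np.kron(q1, np.eye(2))
    return F, H, Q


def _run_filter(
    zs: np.ndarray,
    r_scales: np.ndarray,
    cfg: FilterConfig,
) -> np.ndarray:
    """Filter (and optionally smooth) a (T, 2) observation array.

    ``r_scales[t]`` multiplies the base measurement variance at step t;
    a non-finite scale marks a missing observation (pure prediction).
    Returns the (T, 2) position estimates.
    """
    T = zs.shape[0]
    F, H, Q = _ca_matrices(cfg.q)
    n = 6

    x = np.zeros(n)
    x[:2] = zs[0] if np.isfinite(r_scales[0]) else zs[np.isfinite(r_scales)][0]
    P = np.eye(n) * 500.0
    P[:2, :2] = np.eye(2) * cfg.r

    xs_f = np.zeros((T, n))
    Ps_f = np.zeros((T, n, n))
    xs_p = np.zeros((T, n))
    Ps_p = np.zeros((T, n, n))

    for t in range(T):
        if t == 0:
            xp, Pp = x, P
        else:
            xp = F @ xs_f[t - 1]
            Pp = F @ Ps_f[t - 1] @ F.T + Q
        xs_p[t], Ps_p[t] = xp, Pp
        if np.isfinite(r_scales[t]):
            R = np.eye(2) * (cfg.r * r_scales[t])
            S = H @ Pp @ H.T + R
            try:
                K = Pp @ H.T @ np.linalg.inv(S)
            except np.linalg.LinAlgError as exc:
                raise ValueError(f"singular innovation covariance at step {t}") from exc
            xs_f[t] = xp + K @ (zs[t] - H @ xp)
            Ps_f[t] = (np.eye(n) - K @ H) @ Pp
        else:
            xs_f[t], Ps_f[t] = xp, Pp

    if not cfg.smooth:
        return xs_f[:, :2]

    xs_s = xs_f.copy()
    Ps_s = Ps_f.copy()
    for t in range(T - 2, -1, -1):
        try:
            C = Ps_f[t] @ F.T @ np.linalg.inv(Ps_p[t + 1])
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular predicted covariance at step {t + 1}") from exc
        xs_s[t] = xs_f[t] + C @ (xs_s[t + 1] - xs_p[t + 1])
        Ps_s[t] = Ps_f[t] + C @ (Ps_s[t + 1] - Ps_p[t + 1]) @ C.T
    return xs_s[:, :2]


def kalman_filter_track(
    track: KeypointTrack,
    cfg: FilterConfig = FilterConfig(),
) -> KeypointTrack:
    """Smooth one keypoint track; confidence-0 points become predictions.

    Output has the same frames and confidences; only coordinates change.
    """
    T = len(track.frames)
    if T < 2:
        raise ValueError("need at least 2 observations to filter")
    zs = np.column_stack([track.x, track.y]).astype(float)
    conf = np.asarray(track.confidence, dtype=float)
    r_scales = np.where(conf > 0.0, 1.0 / np.maximum(conf, 1e-12), np.inf)
    est = _run_filter(zs, r_scales, cfg)
    if not np.all(np.isfinite(est)):
        raise ValueError("filter produced non-finite coordinates")
    return replace(track, x=tuple(est[:, 0]), y=tuple(est[:, 1]))


# ---------------------------------------------------------------------------
# Sequence-level curation
# ---------------------------------------------------------------------------

def _swap_identities(
    seq: TrackedSequence, corr: Correction
) -> TrackedSequence:
    a, b = corr.track_id, corr.swap_with
    new_frames = []
    for fr in seq.frames:
        if corr.in_frame <= fr.frame_index < corr.out_frame:
            insts = []
            for inst in fr.instances:
                if inst.track_id == a:
                    insts.append(replace(inst, track_id=b))
                elif inst.track_id == b:
                    insts.append(replace(inst, track_id=a))
                else:
                    insts.append(inst)
            new_frames.append(FrameDetections(fr.frame_index, tuple(insts)))
        else:
            new_frames.append(fr)
    return replace(seq, frames=tuple(new_frames))


def apply_correction(
    seq: TrackedSequence,
    corr: Correction,
    cfg: FilterConfig = FilterConfig(),
) -> TrackedSequence:
    """Apply one curation edit and propagate it across its interval.

    Keypoint corrections re-filter the (track, keypoint) series restricted
    to [in_frame, out_frame) with the corrected frame injected as a
    near-zero-noise measurement, then force the corrected frame to the
    user's exact coordinates. Frames outside the interval are untouched.
    """
    known_ids = {
        inst.track_id for fr in seq.frames for inst in fr.instances
    }
    if corr.track_id not in known_ids:
        raise ValueError(f"unknown track_id {corr.track_id}")
    if corr.swap_with is not None:
        if corr.swap_with not in known_ids:
            raise ValueError(f"unknown track_id {corr.swap_with}")
        return _swap_identities(seq, corr)

    k = corr.keypoint_index
    # collect the interval's observations for this (track, keypoint)
    obs: list[tuple[int, float, float, float]] = []  # frame, x, y, r_scale
    for fr in seq.frames:
        if not corr.in_frame <= fr.frame_index < corr.out_frame:
            continue
        for inst in fr.instances:
            if inst.track_id != corr.track_id:
                continue
            kp = inst.keypoints[k]
            if fr.frame_index == corr.frame:
                obs.append((fr.frame_index, corr.x, corr.y,
                            _CORRECTION_NOISE / cfg.r))
            else:
                scale = 1.0 / kp.confidence if kp.confidence > 0 else np.inf
                obs.append((fr.frame_index, kp.x, kp.y, scale))
    if not any(f == corr.frame for f, *_ in obs):
        raise ValueError(
            f"track {corr.track_id} absent at correction frame {corr.frame}"
        )

    if len(obs) >= 2:
        zs = np.array([[o[1], o[2]] for o in obs])
        r_scales = np.array([o[3] for o in obs])
        est = _run_filter(zs, r_scales, cfg)
    else:
        est = np.array([[corr.x, corr.y]])
    new_xy = {o[0]: (est[i, 0], est[i, 1]) for i, o in enumerate(obs)}
    new_xy[corr.frame] = (corr.x, corr.y)  # curated frame exact

    new_frames = []
    for fr in seq.frames:
        if fr.frame_index not in new_xy:
            new_frames.append(fr)
            continue
        insts = []
        for inst in fr.instances:
            if inst.track_id == corr.track_id:
                nx, ny = new_xy[fr.frame_index]
                kps = list(inst.keypoints)
                kps[k] = Keypoint(float(nx), float(ny), kps[k].confidence)
                insts.append(replace(inst, keypoints=tuple(kps)))
            else:
                insts.append(inst)
        new_frames.append(FrameDetections(fr.frame_index, tuple(insts)))
    return replace(seq, frames=tuple(new_frames))


def extract_keypoint_tracks(seq: TrackedSequence) -> list[KeypointTrack]:
    """Split a tracked sequence into per-(track, keypoint) time series."""
    series: dict[tuple[int, int], list[tuple[int, float, float, float]]] = {}
    for fr in seq.frames:
        for inst in fr.instances:
            for k, kp in enumerate(inst.keypoints):
                series.setdefault((inst.track_id, k), []).append(
                    (fr.frame_index, kp.x, kp.y, kp.confidence)
                )
    out = []
    for (tid, k), rows in sorted(series.items()):
        out.append(
            KeypointTrack(
                track_id=tid,
                keypoint_index=k,
                frames=tuple(r[0] for r in rows),
                x=tuple(r[1] for r in rows),
                y=tuple(r[2] for r in rows),
                confidence=tuple(r[3] for r in rows),
            )
        )
    return out
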