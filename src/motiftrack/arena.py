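"""Seeded two-mouse arena simulator with motif-structured kinematics.

The simulator provides ground truth for every other stage: it drives a
four-keypoint rigid-ish mouse model (snout ahead of the body center, ears
lateral, tail base behind) through a schedule of behavioral motifs, then
derives noisy detections by adding Gaussian keypoint noise, dropping
detections at a dropout rate, shuffling per-frame detection order, and
stripping identities. Identity-crossing events — episodes in which one
mouse approaches and passes through the other's position so the bounding
boxes overlap heavily — stress-test the tracker the way real cage crossings
do.

Motif kinematics are simple proxies chosen to make the motifs separable in
the package's own feature space (e.g. walking and grooming differ in
frame-to-frame displacement; nose-to-nose and anogenital sniffing pin the
relevant snout-to-landmark distance below 0.3 body lengths). All parameters
live in :class:`ArenaConfig` / :class:`MotifSpec`; all randomness flows from
one seeded generator so a session is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from motiftrack.pose_io import (
    BoundingBox,
    FrameDetections,
    Keypoint,
    PoseInstance,
    TrackedSequence,
)

MOTIF_NAMES = (
    "walk", "turn", "still_groom", "rear_proxy",
    "chase", "follow", "anogenital_sniff", "nose_nose",
)


@dataclass(frozen=True)
class MotifSpec:
    """One scheduled behavioral segment.

    speed: leader speed, px/frame. turn_rate: heading change, rad/frame.
    gap: follower-to-leader distance target in body lengths (chase/follow).
    """

    name: str
    duration: int
    speed: float = 6.0
    turn_rate: float = 0.0
    gap: float = 1.5

    def __post_init__(self) -> None:
        if self.name not in MOTIF_NAMES:
            raise ValueError(f"unknown motif {self.name!r}")
        if self.duration < 1:
            raise ValueError("duration must be >= 1")
        if self.speed < 0:
            raise ValueError("speed must be >= 0")


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry and noise of the simulated cage.

    Defaults model a home-cage top-down view: 640x480 px arena, 60 px adult
    mouse body length, keypoint noise sigma of 2% body length (typical
    detector jitter), 0.5% detection dropout, and 3 crossing events per
    session.
    """

    width: float = 640.0
    height: float = 480.0
    body_length: float = 60.0
    ear_forward: float = 0.15      # ear anchor ahead of center, body lengths
    ear_lateral: float = 0.2       # ear offset to the side, body lengths
    keypoint_noise: float = 1.2    # sigma, px (2% of body length)
    dropout: float = 0.005
    n_crossings: int = 3
    box_margin: float = 0.15       # box inflation, body lengths
    randomize_init: bool = False   # random initial placement (else fixed)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.body_length <= 0:
            raise ValueError("body length must be positive")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be a probability")
        if self.keypoint_noise < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass(frozen=True)
class SimulatedSession:
    """Ground truth, noisy detections, and motif labels for one session."""

    ground_truth: TrackedSequence
    detections: tuple[FrameDetections, ...]
    frame_motifs: tuple[str, ...]          # motif name per frame (dyad-level)
    config: ArenaConfig
    schedule: tuple[MotifSpec, ...]

    @property
    def n_frames(self) -> int:
        return len(self.ground_truth.frames)

    def clip_motifs(self, window: int = 15, stride: int | None = None) -> list[str]:
        """Majority motif label per clip window (same placement rule as
        feature extraction on a gap-free session)."""
        stride = window if stride is None else stride
        out = []
        start = 0
        while start + window <= self.n_frames:
            seg = self.frame_motifs[start:start + window]
            out.append(max(set(seg), key=lambda m: (seg.count(m), m)))
            start += stride
        return out


def _pose_keypoints(
    center: np.ndarray, heading: float, cfg: ArenaConfig,
    body_scale: float = 1.0, head_jitter: np.ndarray | None = None,
) -> np.ndarray:
    """(4, 2) noiseless keypoints from center + heading."""
    L = cfg.body_length * body_scale
    h = np.array([math.cos(heading), math.sin(heading)])
    n = np.array([-math.sin(heading), math.cos(heading)])  # mouse's left
    snout = center + 0.5 * L * h
    lear = center + cfg.ear_forward * L * h + cfg.ear_lateral * L * n
    rear = center + cfg.ear_forward * L * h - cfg.ear_lateral * L * n
    tail = center - 0.5 * cfg.body_length * h  # tail anchored at full length
    pts = np.vstack([snout, lear, rear, tail])
    if head_jitter is not None:
        pts[:3] += head_jitter
    return pts


def _clamp(center: np.ndarray, cfg: ArenaConfig, heading: float) -> tuple[np.ndarray, float]:
    """Keep the body inside the arena; reflect heading off walls."""
    m = 0.7 * cfg.body_length
    x, y = center
    if x < m:
        x = m
        heading = math.pi - heading
    elif x > cfg.width - m:
        x = cfg.width - m
        heading = math.pi - heading
    if y < m:
        y = m
        heading = -heading
    elif y > cfg.height - m:
        y = cfg.height - m
        heading = -heading
    return np.array([x, y]), heading


def _init_state(
    config: ArenaConfig, first: MotifSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Initial centers and headings; with ``randomize_init`` the leader is
    placed uniformly in the central arena and the follower starts at its
    station for social motifs (so short pure-motif sessions begin in
    character)."""
    L = config.body_length
    if not config.randomize_init:
        centers = np.array([
            [config.width * 0.35, config.height * 0.5],
            [config.width * 0.65, config.height * 0.5],
        ])
        return centers, np.array([0.0, math.pi])
    c0 = np.array([
        rng.uniform(0.25 * config.width, 0.75 * config.width),
        rng.uniform(0.25 * config.height, 0.75 * config.height),
    ])
    h0 = rng.uniform(-math.pi, math.pi)
    hvec = np.array([math.cos(h0), math.sin(h0)])
    if first.name in ("chase", "follow"):
        c1 = c0 - first.gap * L * hvec
        h1 = h0
    elif first.name == "anogenital_sniff":
        c1 = c0 - (L + 0.15 * L) * hvec
        h1 = h0
    elif first.name == "nose_nose":
        c1 = c0 + (L + 0.15 * L) * hvec
        h1 = h0 + math.pi
    else:
        # side-by-side anti-parallel placement: each mouse sees the other
        # on its left at the same bearing, so the dyad geometry is
        # invariant under exchanging the reference role (a 180-degree
        # rotation about the midpoint) and the relative geometry is
        # consistent across clips
        left = np.array([-math.sin(h0), math.cos(h0)])
        r = rng.uniform(1.1, 1.4) * L
        c1 = c0 + r * left
        h1 = h0 + math.pi + rng.normal(0.0, 0.1)
    centers = np.vstack([c0, c1])
    for a, h in enumerate((h0, h1)):
        centers[a], _ = _clamp(centers[a], config, h)
    return centers, np.array([h0, h1])


def simulate(config: ArenaConfig, schedule: list[MotifSpec]) -> SimulatedSession:
    """Run the two-mouse simulation over a motif schedule.

    Mouse 1 is the leader, mouse 2 the follower in social motifs. Crossing
    events are injected at evenly spaced frames: the follower steers
    through the leader's position at capped speed, forcing box-overlap
    episodes, then resumes its schedule. Fully reproducible from
    ``config.seed``.
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    max_feasible = 0.25 * min(config.width, config.height)
    for spec in schedule:
        if spec.speed > max_feasible:
            raise ValueError(
                f"motif {spec.name!r} speed {spec.speed} infeasible for arena"
            )
    rng = np.random.default_rng(config.seed)
    L = config.body_length
    total = sum(s.duration for s in schedule)

    # crossing windows: follower steered through the leader
    cross_starts = set()
    if config.n_crossings > 0:
        for i in range(config.n_crossings):
            cross_starts.add(int((i + 1) * total / (config.n_crossings + 1)))
    cross_until = -1

    centers, headings = _init_state(config, schedule[0], rng)
    max_step = 10.0

    truth_frames: list[FrameDetections] = []
    det_frames: list[FrameDetections] = []
    frame_motifs: list[str] = []

    frame = 0
    for spec in schedule:
        for _ in range(spec.duration):
            crossing = frame in cross_starts or frame <= cross_until
            if frame in cross_starts:
                cross_until = frame + 60  # upper bound; ends when passed
                cross_passed = False

            # --- leader (mouse index 0) kinematics -----------------------
            name = spec.name
            if name in ("walk", "chase", "follow"):
                headings[0] += rng.normal(0.0, 0.03)
                step = spec.speed
            elif name == "turn":
                headings[0] += spec.turn_rate if spec.turn_rate else 0.15
                step = min(spec.speed, 1.0)
            elif name in ("still_groom", "rear_proxy",
                          "anogenital_sniff", "nose_nose"):
                step = 0.3
                headings[0] += rng.normal(0.0, 0.01)
            centers[0] = centers[0] + step * np.array(
                [math.cos(headings[0]), math.sin(headings[0])]
            )
            centers[0], headings[0] = _clamp(centers[0], config, headings[0])

            # --- follower (mouse index 1) kinematics ----------------------
            if crossing:
                delta = centers[0] - centers[1]
                dist = float(np.hypot(*delta))
                if not cross_passed and dist > 1e-9:
                    # brush past: aim half a body length beside the leader
                    # (bodies never coincide, but the boxes overlap heavily)
                    perp = np.array([-delta[1], delta[0]]) / dist
                    aim = centers[0] + 0.45 * L * perp - centers[1]
                    headings[1] = math.atan2(aim[1], aim[0])
                centers[1] = centers[1] + max_step * np.array(
                    [math.cos(headings[1]), math.sin(headings[1])]
                )
                if dist < 0.6 * L:
                    cross_passed = True
                if cross_passed and dist > 1.2 * L:
                    cross_until = frame  # episode over
            elif name in ("chase", "follow"):
                target = centers[0] - spec.gap * L * np.array(
                    [math.cos(headings[0]), math.sin(headings[0])]
                )
                delta = target - centers[1]
                dist = float(np.hypot(*delta))
                if dist > 1e-9:
                    headings[1] = math.atan2(delta[1], delta[0])
                centers[1] = centers[1] + min(spec.speed * 1.1, dist) * np.array(
                    [math.cos(headings[1]), math.sin(headings[1])]
                )
            elif name in ("anogenital_sniff", "nose_nose"):
                hvec = np.array([math.cos(headings[0]), math.sin(headings[0])])
                if name == "anogenital_sniff":
                    # follower snout ~0.15 body lengths behind the tail base
                    tail0 = centers[0] - 0.5 * L * hvec
                    target = tail0 - (0.5 * L + 0.15 * L) * hvec
                    want_heading = headings[0]
                else:
                    # facing poses, snout gap ~0.15 body lengths
                    snout0 = centers[0] + 0.5 * L * hvec
                    target = snout0 + (0.5 * L + 0.15 * L) * hvec
                    want_heading = headings[0] + math.pi
                target = target + rng.normal(0.0, 0.02 * L, 2)
                delta = target - centers[1]
                dist = float(np.hypot(*delta))
                if dist > max_step:
                    # approach the station at capped speed (no teleporting)
                    headings[1] = math.atan2(delta[1], delta[0])
                    centers[1] = centers[1] + max_step * delta / dist
                else:
                    headings[1] = want_heading
                    centers[1] = target
            else:  # independent individual behavior
                if name == "walk":
                    headings[1] += rng.normal(0.0, 0.03)
                    step = spec.speed
                elif name == "turn":
                    headings[1] += spec.turn_rate if spec.turn_rate else 0.15
                    step = min(spec.speed, 1.0)
                else:
                    step = 0.3
                    headings[1] += rng.normal(0.0, 0.01)
                centers[1] = centers[1] + step * np.array(
                    [math.cos(headings[1]), math.sin(headings[1])]
                )
            centers[1], headings[1] = _clamp(centers[1], config, headings[1])
            # solid bodies: two mice cannot interpenetrate, so centers keep
            # a minimum separation of ~one body width
            sep = centers[1] - centers[0]
            d01 = float(np.hypot(*sep))
            min_sep = 0.45 * L
            if d01 < min_sep:
                if d01 < 1e-9:
                    sep = np.array([math.cos(headings[1] + math.pi / 2),
                                    math.sin(headings[1] + math.pi / 2)])
                    d01 = 1.0
                centers[1] = centers[0] + min_sep * sep / d01

            # --- realize keypoints, boxes, noise --------------------------
            body_scale = 0.6 if name == "rear_proxy" else 1.0
            gt_instances = []
            det_instances = []
            for a in (0, 1):
                jitter = None
                if name == "still_groom":
                    jitter = rng.normal(0.0, 0.02 * L, (3, 2))
                pts = _pose_keypoints(
                    centers[a], headings[a], config,
                    body_scale=body_scale, head_jitter=jitter,
                )
                margin = config.box_margin * L
                box = BoundingBox(
                    pts[:, 0].min() - margin, pts[:, 1].min() - margin,
                    pts[:, 0].max() + margin, pts[:, 1].max() + margin,
                )
                gt_instances.append(PoseInstance(
                    frame, box,
                    tuple(Keypoint(p[0], p[1], 1.0) for p in pts),
                    track_id=a + 1,
                ))
                noisy = pts + rng.normal(0.0, config.keypoint_noise, pts.shape)
                conf = np.clip(rng.normal(0.9, 0.05, 4), 0.5, 1.0)
                nbox = BoundingBox(
                    noisy[:, 0].min() - margin, noisy[:, 1].min() - margin,
                    noisy[:, 0].max() + margin, noisy[:, 1].max() + margin,
                )
                if rng.random() >= config.dropout:
                    det_instances.append(PoseInstance(
                        frame, nbox,
                        tuple(Keypoint(p[0], p[1], c)
                              for p, c in zip(noisy, conf)),
                        track_id=None,
                    ))
            order = rng.permutation(len(det_instances))
            truth_frames.append(FrameDetections(frame, tuple(gt_instances)))
            det_frames.append(FrameDetections(
                frame, tuple(det_instances[i] for i in order)
            ))
            frame_motifs.append(name)
            frame += 1

    truth = TrackedSequence(
        frames=tuple(truth_frames), fps=25.0, num_pose=4, max_ids=2
    )
    return SimulatedSession(
        ground_truth=truth,
        detections=tuple(det_frames),
        frame_motifs=tuple(frame_motifs),
        config=config,
        schedule=tuple(schedule),
    )


def standard_benchmark(seed: int = 0, keypoint_noise: float | None = None) -> SimulatedSession:
    """The canonical 1,000-frame two-mouse session used across tests.

    Two mice, keypoint noise sigma = 2% of body length (overridable to
    sweep noise), 0.5% dropout, 3 crossing events, schedule cycling
    walk / still_groom / chase / nose_nose in 60-frame blocks (multiples of
    the 15-frame clip window, so clips are motif-pure).
    """
    cfg = ArenaConfig(seed=seed)
    if keypoint_noise is not None:
        cfg = replace(cfg, keypoint_noise=keypoint_noise)
    block = [
        MotifSpec("walk", 60, speed=6.0),
        MotifSpec("still_groom", 60),
        MotifSpec("chase", 60, speed=6.0),
        MotifSpec("nose_nose", 60),
    ]
    schedule: list[MotifSpec] = []
    total = 0
    while total + 240 <= 960:
        schedule.extend(block)
        total += 240
    schedule.append(MotifSpec("walk", 1000 - total, speed=6.0))
    return simulate(cfg, schedule)


def motif_benchmark(
    seed: int = 0, clips_per_motif: int = 50, window: int = 15
) -> tuple[list["SimulatedSession"], list[str]]:
    """Pure-motif clip set for clustering recovery.

    Each clip is an independent ``window``-frame simulation of one motif
    from walk / still_groom / nose_nose with randomized initial geometry
    (the follower starts at its social station, so every frame of the clip
    is in character). Keypoint noise is 1% of body length and there are no
    dropouts or crossings: motif effect sizes are set by the kinematics.

    Returns the per-clip sessions and the matching motif labels; each
    social clip later yields two feature rows carrying the same label.
    """
    motifs = [
        MotifSpec("walk", window, speed=6.0),
        MotifSpec("still_groom", window),
        MotifSpec("nose_nose", window),
    ]
    root = np.random.default_rng(seed)
    sessions: list[SimulatedSession] = []
    labels: list[str] = []
    for spec in motifs:
        for _ in range(clips_per_motif):
            sub = int(root.integers(0, 2**31 - 1))
            cfg = ArenaConfig(
                seed=sub, keypoint_noise=0.6, dropout=0.0,
                n_crossings=0, randomize_init=True,
            )
            sessions.append(simulate(cfg, [spec]))
            labels.append(spec.name)
    return sessions, labels


def detections_to_sequence(session: SimulatedSession) -> list[FrameDetections]:
    """The noisy, identity-stripped detections as a plain frame list."""
    return list(session.detections)
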