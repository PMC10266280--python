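import numpy as np
import pytest

from motiftrack.pose_io import (
    BoundingBox,
    FrameDetections,
    Keypoint,
    PoseInstance,
    TrackedSequence,
)


def make_instance(frame, cx, cy, heading=0.0, body=40.0, track_id=None,
                  confidence=1.0):
    """A four-keypoint mouse-like pose at (cx, cy) facing ``heading``."""
    h = np.array([np.cos(heading), np.sin(heading)])
    n = np.array([-np.sin(heading), np.cos(heading)])
    c = np.array([cx, cy], dtype=float)
    pts = [
        c + 0.5 * body * h,                      # snout
        c + 0.15 * body * h + 0.2 * body * n,    # left ear
        c + 0.15 * body * h - 0.2 * body * n,    # right ear
        c - 0.5 * body * h,                      # tail base
    ]
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    m = 0.15 * body
    box = BoundingBox(min(xs) - m, min(ys) - m, max(xs) + m, max(ys) + m)
    kps = tuple(Keypoint(p[0], p[1], confidence) for p in pts)
    return PoseInstance(frame, box, kps, track_id)


def make_sequence(n_frames, speeds=((2.0, 0.0), (-2.0, 0.0)),
                  starts=((100.0, 100.0), (300.0, 300.0)), body=40.0):
    """Two mice moving at constant velocity; fully tracked, confidence 1."""
    frames = []
    for t in range(n_frames):
        insts = []
        for a, ((vx, vy), (x0, y0)) in enumerate(zip(speeds, starts)):
            heading = np.arctan2(vy, vx) if (vx, vy) != (0.0, 0.0) else 0.0
            insts.append(
                make_instance(t, x0 + vx * t, y0 + vy * t, heading, body,
                              track_id=a + 1)
            )
        frames.append(FrameDetections(t, tuple(insts)))
    return TrackedSequence(tuple(frames), fps=25.0, num_pose=4, max_ids=2)


@pytest.fixture
def two_mouse_sequence():
    return make_sequence(60)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
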