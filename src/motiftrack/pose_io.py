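"""Domain types for multi-animal keypoint detections and file dialects.

Coordinates are continuous pixels in image convention: origin at the top-left
corner, x increasing rightward, y increasing *downward*. Frame indices are
0-based; frame ranges elsewhere in the package are half-open [start, end).

Two JSON dialects are supported:

* the *annotation* dialect produced by box-and-point labeling tools — a list
  of image records, each holding an ordered ``annotations`` list in which
  every animal contributes one bounding-box record (class ``"Face"``)
  followed by its keypoint records (class ``"point"``) in a fixed anatomical
  order;
* the *tracked-results* dialect written by this package — a versioned
  mapping of frame index to per-animal records with a persistent track id.

Missing keypoints are encoded as confidence 0 with their last coordinates
carried through, never as absent entries, so per-frame arrays stay
rectangular.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

#: Canonical keypoint order for the two-mouse schema.
MOUSE_KEYPOINTS = ("snout", "left_ear", "right_ear", "tail_base")

TRACKED_SCHEMA_VERSION = "motiftrack-tracked-1"


class ParseError(ValueError):
    """Raised when an input file violates its dialect."""


class SchemaError(ValueError):
    """Raised when record structure conflicts with the session schema."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates (x right, y down)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if self.x_max < self.x_min or self.y_max < self.y_min:
            raise ValueError(
                f"degenerate box: ({self.x_min},{self.y_min})-({self.x_max},{self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def diagonal(self) -> float:
        return math.hypot(self.width, self.height)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))


@dataclass(frozen=True)
class Keypoint:
    """A named anatomical landmark with a detector confidence in [0, 1]."""

    x: float
    y: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class PoseInstance:
    """One animal in one frame: box, ordered keypoints, optional track id."""

    frame_index: int
    box: BoundingBox
    keypoints: tuple[Keypoint, ...]
    track_id: int | None = None

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        if self.track_id is not None and self.track_id < 1:
            raise ValueError("track_id must be a positive integer")
        object.__setattr__(self, "keypoints", tuple(self.keypoints))

    @property
    def num_keypoints(self) -> int:
        return len(self.keypoints)

    @property
    def mean_confidence(self) -> float:
        if not self.keypoints:
            return 0.0
        return sum(k.confidence for k in self.keypoints) / len(self.keypoints)


@dataclass(frozen=True)
class FrameDetections:
    """All pose instances observed in one frame."""

    frame_index: int
    instances: tuple[PoseInstance, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "instances", tuple(self.instances))
        for inst in self.instances:
            if inst.frame_index != self.frame_index:
                raise ValueError(
                    f"instance frame {inst.frame_index} != frame {self.frame_index}"
                )
        ids = [i.track_id for i in self.instances if i.track_id is not None]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate track_id in frame {self.frame_index}")


@dataclass(frozen=True)
class TrackedSequence:
    """A time-ordered sequence of frames with persistent identities.

    ``num_pose`` is the number of keypoints per animal (K) and ``max_ids``
    the maximum number of animals (M); every non-null track id must lie in
    1..M.
    """

    frames: tuple[FrameDetections, ...]
    fps: float = 25.0
    num_pose: int = 4
    max_ids: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "frames", tuple(self.frames))
        prev = -1
        for fr in self.frames:
            if fr.frame_index <= prev:
                raise ValueError("frame indices must be strictly increasing")
            prev = fr.frame_index
            for inst in fr.instances:
                if inst.num_keypoints != self.num_pose:
                    raise SchemaError(
                        f"frame {fr.frame_index}: instance has "
                        f"{inst.num_keypoints} keypoints, expected {self.num_pose}"
                    )
                if inst.track_id is not None and inst.track_id > self.max_ids:
                    raise ValueError(
                        f"track_id {inst.track_id} exceeds max_ids {self.max_ids}"
                    )

    def __len__(self) -> int:
        return len(self.frames)

    def slice_frames(self, start: int, end: int) -> "TrackedSequence":
        """Restrict to frame indices in the half-open interval [start, end)."""
        kept = tuple(f for f in self.frames if start <= f.frame_index < end)
        return replace(self, frames=kept)


# ---------------------------------------------------------------------------
# Annotation dialect
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path, num_pose: int = 4) -> list[FrameDetections]:
    """Read a box-and-point annotation JSON file.

    Each image record groups its ``annotations`` list by order: one ``"Face"``
    box record starts an animal, and the following ``num_pose`` ``"point"``
    records are its keypoints. Confidences are set to 1.0 (human ground
    truth). Frame indices follow file order.
    """
    path = Path(path)
    try:
        records = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(records, list):
        raise ParseError(f"{path}: top level must be a list of image records")

    frames: list[FrameDetections] = []
    for frame_index, rec in enumerate(records):
        anns = rec.get("annotations")
        if anns is None:
            raise ParseError(f"frame {frame_index}: missing 'annotations'")
        instances: list[PoseInstance] = []
        i = 0
        while i < len(anns):
            a = anns[i]
            cls = a.get("class")
            if cls != "Face":
                raise ParseError(
                    f"frame {frame_index}: expected a 'Face' box record, got "
                    f"class {cls!r} at position {i}"
                )
            try:
                box = BoundingBox(
                    float(a["x"]), float(a["y"]),
                    float(a["x"]) + float(a["width"]),
                    float(a["y"]) + float(a["height"]),
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(
                    f"frame {frame_index}: malformed box record: {exc}"
                ) from exc
            pts: list[Keypoint] = []
            i += 1
            while i < len(anns) and anns[i].get("class") == "point":
                p = anns[i]
                try:
                    pts.append(Keypoint(float(p["x"]), float(p["y"]), 1.0))
                except (KeyError, TypeError, ValueError) as exc:
                    raise ParseError(
                        f"frame {frame_index}: malformed point record: {exc}"
                    ) from exc
                i += 1
            if len(pts) != num_pose:
                raise SchemaError(
                    f"frame {frame_index}: animal has {len(pts)} keypoints, "
                    f"expected num_pose={num_pose}"
                )
            instances.append(
                PoseInstance(frame_index, box, tuple(pts), track_id=None)
            )
        frames.append(FrameDetections(frame_index, tuple(instances)))
    return frames


# ---------------------------------------------------------------------------
# Tracked-results dialect
# ---------------------------------------------------------------------------

def write_tracked(seq: TrackedSequence, path: str | Path) -> None:
    """Serialize a fully tracked sequence; coordinates at full precision."""
    for fr in seq.frames:
        for inst in fr.instances:
            if inst.track_id is None:
                raise ValueError(
                    f"frame {fr.frame_index}: instance without track_id"
                )
    payload = {
        "schema_version": TRACKED_SCHEMA_VERSION,
        "fps": seq.fps,
        "num_pose": seq.num_pose,
        "max_ids": seq.max_ids,
        "frames": {
            str(fr.frame_index): [
                {
                    "track_id": inst.track_id,
                    "box": [inst.box.x_min, inst.box.y_min,
                            inst.box.x_max, inst.box.y_max],
                    "keypoints": [v for k in inst.keypoints
                                  for v in (k.x, k.y, k.confidence)],
                }
                for inst in fr.instances
            ]
            for fr in seq.frames
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_tracked(path: str | Path) -> TrackedSequence:
    """Read a tracked-results JSON file; rejects unknown schema versions."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON: {exc}") from exc
    version = payload.get("schema_version")
    if version != TRACKED_SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: unknown schema version {version!r}; "
            f"expected {TRACKED_SCHEMA_VERSION!r}"
        )
    frames: list[FrameDetections] = []
    for key in sorted(payload["frames"], key=int):
        frame_index = int(key)
        instances = []
        for rec in payload["frames"][key]:
            flat = rec["keypoints"]
            if len(flat) % 3 != 0:
                raise ParseError(
                    f"frame {frame_index}: keypoint array length {len(flat)} "
                    "not a multiple of 3"
                )
            kps = tuple(
                Keypoint(flat[j], flat[j + 1], flat[j + 2])
                for j in range(0, len(flat), 3)
            )
            instances.append(
                PoseInstance(
                    frame_index,
                    BoundingBox(*rec["box"]),
                    kps,
                    track_id=rec["track_id"],
                )
            )
        frames.append(FrameDetections(frame_index, tuple(instances)))
    return TrackedSequence(
        frames=tuple(frames),
        fps=payload["fps"],
        num_pose=payload["num_pose"],
        max_ids=payload["max_ids"],
    )


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

def export_csv(
    seq: TrackedSequence,
    path: str | Path,
    keypoint_names: Sequence[str] = MOUSE_KEYPOINTS,
) -> int:
    """Write one row per (frame, track, keypoint); returns the row count."""
    n = 0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["frame", "track_id", "keypoint_index", "keypoint_name",
             "x", "y", "confidence"]
        )
        for fr in seq.frames:
            for inst in fr.instances:
                for k, kp in enumerate(inst.keypoints):
                    name = keypoint_names[k] if k < len(keypoint_names) else str(k)
                    writer.writerow(
                        [fr.frame_index, inst.track_id, k, name,
                         repr(kp.x), repr(kp.y), repr(kp.confidence)]
                    )
                    n += 1
    return n
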