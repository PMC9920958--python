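"""Reading, validating, and flattening per-frame 2-D pose detections.

A pose estimator (e.g. AlphaPose with a COCO-pretrained model) emits, per
video frame, 17 body-joint image coordinates ``(x, y)`` plus a detection
confidence ``score`` for each joint. Flattened, that is 51 attributes per
frame (17 * (2 + 1)). This module defines the in-memory frame types and
the JSON/CSV readers and writers used by the rest of the pipeline.

Conventions
-----------
* Joint order follows the COCO-17 convention (see :data:`COCO_JOINTS`).
* Flattened attribute order interleaves per joint: ``x1, y1, s1, ..., x17,
  y17, s17`` (:data:`ATTR_COLUMNS`).
* Coordinates are raw pixel units; any normalization happens downstream.
* Activity labels are integer class ids ``1..12``; a missing label is
  ``None``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: COCO-17 joint names, in keypoint-array order.
COCO_JOINTS: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

N_JOINTS = 17
#: attributes per frame: (x, y, score) per joint
N_ATTRS = N_JOINTS * 3

#: Flattened attribute column names: x1,y1,s1,...,x17,y17,s17.
ATTR_COLUMNS: tuple[str, ...] = tuple(
    f"{axis}{j + 1}" for j in range(N_JOINTS) for axis in ("x", "y", "s")
)

#: Valid activity class ids (12 scripted daily/fall activities).
VALID_LABELS = frozenset(range(1, 13))


class PoseValidationError(ValueError):
    """Raised when a record violates the pose-frame contract."""


class PoseParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending record."""


@dataclass(frozen=True)
class Keypoint:
    """One joint detection: image coordinates plus confidence in [0, 1]."""

    x: float
    y: float
    score: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise PoseValidationError(f"non-finite keypoint coordinates ({self.x}, {self.y})")
        if not (math.isfinite(self.score) and 0.0 <= self.score <= 1.0):
            raise PoseValidationError(f"keypoint score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class PoseFrame:
    """A single frame's skeleton: exactly 17 keypoints in COCO order."""

    frame_index: int
    keypoints: tuple[Keypoint, ...]
    label: int | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise PoseValidationError(f"negative frame_index {self.frame_index}")
        if len(self.keypoints) != N_JOINTS:
            raise PoseValidationError(
                f"frame {self.frame_index}: expected {N_JOINTS} keypoints, got {len(self.keypoints)}"
            )
        if self.label is not None and self.label not in VALID_LABELS:
            raise PoseValidationError(
                f"frame {self.frame_index}: label {self.label} not a valid class id 1-12"
            )

    @property
    def mean_score(self) -> float:
        return float(np.mean([k.score for k in self.keypoints]))


@dataclass
class PoseSequence:
    """A time-ordered sequence of pose frames from one source.

    ``fps`` defaults to 18 so that a 36-frame window spans 2 seconds.
    """

    frames: list[PoseFrame] = field(default_factory=list)
    fps: float = 18.0
    source_id: str = ""

    def __post_init__(self) -> None:
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise PoseValidationError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


def flatten_frame(frame: PoseFrame) -> np.ndarray:
    """Flatten a frame to its 51-float attribute vector (x1,y1,s1,...)."""
    out = np.empty(N_ATTRS, dtype=np.float64)
    for j, kp in enumerate(frame.keypoints):
        out[3 * j] = kp.x
        out[3 * j + 1] = kp.y
        out[3 * j + 2] = kp.score
    return out


def unflatten_frame(
    attrs: Sequence[float],
    frame_index: int = 0,
    label: int | None = None,
    source_id: str = "",
) -> PoseFrame:
    """Inverse of :func:`flatten_frame`: rebuild a frame from 51 attributes."""
    attrs = np.asarray(attrs, dtype=np.float64)
    if attrs.shape != (N_ATTRS,):
        raise PoseValidationError(f"expected {N_ATTRS} attributes, got shape {attrs.shape}")
    kps = tuple(
        Keypoint(float(attrs[3 * j]), float(attrs[3 * j + 1]), float(attrs[3 * j + 2]))
        for j in range(N_JOINTS)
    )
    return PoseFrame(frame_index=frame_index, keypoints=kps, label=label, source_id=source_id)


def _frame_id_of(record: dict, position: int) -> int:
    for key in ("frame", "frame_index", "image_id"):
        if key in record:
            raw = record[key]
            if isinstance(raw, str):
                # AlphaPose writes image file names like "123.jpg"
                digits = "".join(c for c in Path(raw).stem if c.isdigit())
                if not digits:
                    raise PoseParseError(f"record {position}: cannot parse frame id from {raw!r}")
                return int(digits)
            return int(raw)
    raise PoseParseError(f"record {position}: no frame/image_id field")


def read_pose_json(path: str | Path) -> list[PoseFrame]:
    """Read an AlphaPose-style detection JSON into one frame per frame id.

    The file holds a list of detection records, each with an image/frame id
    and a 51-value ``keypoints`` array (x, y, score interleaved). When a
    frame has several detections (multiple people), the detection with the
    highest mean keypoint score is kept; ties keep the first occurrence.
    """
    path = Path(path)
    with path.open() as fh:
        try:
            records = json.load(fh)
        except json.JSONDecodeError as exc:
            raise PoseParseError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(records, list):
        raise PoseParseError(f"{path}: expected a top-level list of detection records")

    best: dict[int, tuple[float, int, PoseFrame]] = {}
    for pos, rec in enumerate(records):
        if not isinstance(rec, dict) or "keypoints" not in rec:
            raise PoseParseError(f"record {pos}: not a detection record with 'keypoints'")
        fidx = _frame_id_of(rec, pos)
        kp_arr = rec["keypoints"]
        if len(kp_arr) != N_ATTRS:
            raise PoseValidationError(
                f"record {pos} (frame {fidx}): keypoint array length {len(kp_arr)} != {N_ATTRS}"
            )
        try:
            frame = unflatten_frame(kp_arr, frame_index=fidx, label=rec.get("label"))
        except (PoseValidationError, TypeError, ValueError) as exc:
            raise PoseParseError(f"record {pos} (frame {fidx}): {exc}") from exc
        score = frame.mean_score
        cur = best.get(fidx)
        # strictly-greater keeps the first occurrence on ties
        if cur is None or score > cur[0]:
            best[fidx] = (score, pos, frame)
    return [best[k][2] for k in sorted(best)]


def read_pose_csv(path: str | Path) -> list[PoseFrame]:
    """Read the pose CSV dialect: header ``frame,label,x1,y1,s1,...,x17,y17,s17``.

    One row per frame, in file order. The label column may be empty
    (missing label); otherwise it must parse to a class id 1-12.
    """
    path = Path(path)
    frames: list[PoseFrame] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise PoseParseError(f"{path}: empty file, no header row")
        required = ["frame", "label", *ATTR_COLUMNS]
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise PoseValidationError(f"{path}: missing columns: {', '.join(missing)}")
        has_source = "source_id" in reader.fieldnames
        for rownum, row in enumerate(reader, start=2):
            try:
                attrs = [float(row[c]) for c in ATTR_COLUMNS]
                fidx = int(row["frame"])
            except ValueError as exc:
                raise PoseParseError(f"{path}: row {rownum}: non-numeric value ({exc})") from exc
            raw_label = (row["label"] or "").strip()
            label = int(float(raw_label)) if raw_label else None
            source = row["source_id"] if has_source else ""
            try:
                frames.append(
                    unflatten_frame(attrs, frame_index=fidx, label=label, source_id=source)
                )
            except PoseValidationError as exc:
                raise PoseValidationError(f"{path}: row {rownum}: {exc}") from exc
    return frames


def write_pose_csv(frames: Iterable[PoseFrame], path: str | Path) -> None:
    """Write frames in the CSV dialect read back by :func:`read_pose_csv`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "label", "source_id", *ATTR_COLUMNS])
        for f in frames:
            label = "" if f.label is None else f.label
            writer.writerow(
                [f.frame_index, label, f.source_id, *(repr(float(v)) for v in flatten_frame(f))]
            )
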