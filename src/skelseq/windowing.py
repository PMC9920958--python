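"""Sliding-window feature construction.

Each classification instance is one window of 36 consecutive frames
(2 seconds at 18 fps). Only three frames of the window — the first, the
middle, and the last — are kept, so a window flattens to a 153-float
feature vector (51 skeleton attributes x 3 frames, frame-major). Windows
are stepped along the sequence with a configurable stride (default 1
frame) and labeled by a configurable rule.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from skelseq.pose_io import N_ATTRS, PoseSequence, flatten_frame

#: feature length under default spec: 51 attributes x 3 selected frames
N_FEATURES = 3 * N_ATTRS


@dataclass(frozen=True)
class WindowSpec:
    """Geometry and labeling policy of the sliding window.

    ``selected_offsets`` are 0-based offsets within the window; the default
    (0, 17, 35) keeps the first frame, the middle (floor((36-1)/2)), and the
    last frame of a 36-frame window.
    """

    window_frames: int = 36
    selected_offsets: tuple[int, ...] = (0, 17, 35)
    stride_frames: int = 1
    label_rule: str = "majority"  # or "last"
    impute_missing: bool = False  # last-observation-carried-forward instead of dropping

    def __post_init__(self) -> None:
        if self.window_frames < 1:
            raise ValueError("window_frames must be >= 1")
        if self.stride_frames < 1:
            raise ValueError("stride_frames must be >= 1")
        offs = self.selected_offsets
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("selected_offsets must be strictly increasing")
        if offs[0] < 0 or offs[-1] >= self.window_frames:
            raise ValueError("selected_offsets must lie within [0, window_frames-1]")
        if self.label_rule not in ("majority", "last"):
            raise ValueError(f"unknown label_rule {self.label_rule!r}")

    @property
    def n_features(self) -> int:
        return len(self.selected_offsets) * N_ATTRS


@dataclass(frozen=True)
class FeatureWindow:
    """One labeled window: concatenation of the selected frames' attributes."""

    features: np.ndarray
    label: int
    window_start: int
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "features", np.asarray(self.features, dtype=np.float64).ravel()
        )


def assign_label(frame_labels: Sequence[int | None], rule: str = "majority") -> int | None:
    """Assign a window label from its frames' per-frame labels.

    ``majority`` returns the most frequent label, ties broken by the label
    of the last frame (falling back to the most frequent among tied labels
    occurring latest); ``last`` returns the final frame's label. Missing
    (None) labels are ignored; if every label is missing, returns None
    (the caller drops the window).
    """
    if len(frame_labels) == 0:
        raise ValueError("empty label list")
    present = [lab for lab in frame_labels if lab is not None]
    if not present:
        return None
    if rule == "last":
        return present[-1]
    if rule != "majority":
        raise ValueError(f"unknown label rule {rule!r}")
    counts = Counter(present)
    top = max(counts.values())
    tied = {lab for lab, c in counts.items() if c == top}
    if len(tied) == 1:
        return tied.pop()
    # tie-break: latest-occurring frame whose label is among the tied set
    for lab in reversed(present):
        if lab in tied:
            return lab
    raise AssertionError("unreachable")


def build_windows(seq: PoseSequence, spec: WindowSpec = WindowSpec()) -> list[FeatureWindow]:
    """Slide ``spec``-shaped windows along ``seq`` and emit feature vectors.

    Frames are laid out on the frame-index grid; gaps in ``frame_index``
    are missing frames. A window that covers a missing frame is dropped
    (default) or imputed by carrying the last observed frame forward
    (``spec.impute_missing``). A window whose frames all lack labels is
    dropped. Returns an empty list when fewer than ``window_frames``
    usable frames exist.
    """
    windows, _ = build_windows_report(seq, spec)
    return windows


def build_windows_report(
    seq: PoseSequence, spec: WindowSpec = WindowSpec()
) -> tuple[list[FeatureWindow], dict[str, int]]:
    """As :func:`build_windows`, also returning drop counts by reason."""
    report = {"emitted": 0, "dropped_missing_frame": 0, "dropped_unlabeled": 0}
    if len(seq) == 0:
        return [], report
    first = seq.frames[0].frame_index
    last = seq.frames[-1].frame_index
    span = last - first + 1
    # dense grid over the frame-index range; None marks a missing frame
    grid: list = [None] * span
    for f in seq.frames:
        grid[f.frame_index - first] = f
    if spec.impute_missing:
        carried = None
        for i, f in enumerate(grid):
            if f is None:
                grid[i] = carried
            else:
                carried = f
        # leading gap (before any observation) stays missing

    W = spec.window_frames
    out: list[FeatureWindow] = []
    flat_cache: dict[int, np.ndarray] = {}
    for start in range(0, span - W + 1, spec.stride_frames):
        chunk = grid[start : start + W]
        if any(f is None for f in chunk):
            report["dropped_missing_frame"] += 1
            continue
        label = assign_label([f.label for f in chunk], spec.label_rule)
        if label is None:
            report["dropped_unlabeled"] += 1
            continue
        parts = []
        for off in spec.selected_offsets:
            f = chunk[off]
            vec = flat_cache.get(id(f))
            if vec is None:
                vec = flatten_frame(f)
                flat_cache[id(f)] = vec
            parts.append(vec)
        out.append(
            FeatureWindow(
                features=np.concatenate(parts),
                label=label,
                window_start=first + start,
                source_id=seq.source_id,
            )
        )
        report["emitted"] += 1
    return out, report


def windows_to_frame(windows: Iterable[FeatureWindow]) -> pd.DataFrame:
    """Tabulate windows as ``label, f001..fNNN, window_start, source_id``."""
    windows = list(windows)
    if not windows:
        cols = ["label"] + [f"f{i + 1:03d}" for i in range(N_FEATURES)]
        return pd.DataFrame(columns=cols + ["window_start", "source_id"])
    n_feat = windows[0].features.size
    feat = np.vstack([w.features for w in windows])
    df = pd.DataFrame(feat, columns=[f"f{i + 1:03d}" for i in range(n_feat)])
    df.insert(0, "label", [w.label for w in windows])
    df["window_start"] = [w.window_start for w in windows]
    df["source_id"] = [w.source_id for w in windows]
    return df


def frame_to_windows(df: pd.DataFrame) -> list[FeatureWindow]:
    """Inverse of :func:`windows_to_frame`."""
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    return [
        FeatureWindow(
            features=row[feat_cols].to_numpy(dtype=np.float64),
            label=int(row["label"]),
            window_start=int(row.get("window_start", 0)),
            source_id=str(row.get("source_id", "")),
        )
        for _, row in df.iterrows()
    ]
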