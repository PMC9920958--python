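"""Deterministic synthetic 17-joint motion generator.

Emulates labeled skeleton trajectories for the 12 activity classes (five
fall styles plus seven daily activities) so that every pipeline stage is
testable without the real recordings. Archetypes are deliberately simple
analytic motions — sinusoidal limb oscillation, horizontal drift, seated
and lying postures, and a monotone downward displacement of the upper
body over about one second for the fall classes — plus Gaussian pixel
noise. Each class also carries a distinct horizontal anchor so classes
are linearly separable in window-feature space as noise goes to zero.
Detection scores are drawn uniformly in [0.5, 1] (informative channel,
not class-leaking). Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from skelseq.pose_io import Keypoint, N_JOINTS, PoseFrame, PoseSequence

#: Published per-class sliding-window counts of the 12-activity corpus
#: (fall styles 1-5, then walking, standing, sitting, picking up an
#: object, jumping, laying, unknown); used as imbalance shares.
UPFALL_WINDOW_COUNTS: dict[int, int] = {
    1: 1_473,
    2: 1_473,
    3: 1_858,
    4: 1_560,
    5: 1_863,
    6: 38_570,
    7: 51_573,
    8: 45_439,
    9: 1_456,
    10: 22_067,
    11: 38_771,
    12: 1_394,
}

FALL_CLASSES = (1, 2, 3, 4, 5)
MINORITY_CLASSES = (1, 2, 3, 4, 5, 9, 12)

# canonical standing skeleton: (x, y) offsets from the hip center, pixels,
# image convention (y grows downward)
_TEMPLATE = np.array(
    [
        (0, -80),  # nose
        (-5, -85), (5, -85),  # eyes
        (-10, -82), (10, -82),  # ears
        (-20, -60), (20, -60),  # shoulders
        (-28, -35), (28, -35),  # elbows
        (-32, -10), (32, -10),  # wrists
        (-12, 0), (12, 0),  # hips
        (-12, 40), (12, 40),  # knees
        (-12, 80), (12, 80),  # ankles
    ],
    dtype=np.float64,
)
_UPPER_BODY = np.arange(0, 11)  # nose..wrists
_LIMBS = np.array([7, 8, 9, 10, 13, 14, 15, 16])  # elbows, wrists, knees, ankles


@dataclass(frozen=True)
class _Archetype:
    cx: float  # horizontal anchor (class-distinct)
    osc_amp: float = 0.0  # limb oscillation amplitude, px
    osc_freq: float = 0.0  # Hz
    body_amp: float = 0.0  # whole-body vertical oscillation, px
    body_freq: float = 0.0
    drift_vx: float = 0.0  # horizontal drift, px/s
    drop_px: float = 0.0  # fall displacement of the upper body, px
    drop_duration: float = 1.0  # seconds for the drop
    lean_px: float = 0.0  # horizontal lean during the drop
    dip_px: float = 0.0  # down-and-back-up dip (picking up), px
    squash: float = 1.0  # vertical posture scale (laying < sitting < 1)
    base_y: float = 240.0  # hip-center height


def _archetypes(width: float) -> dict[int, _Archetype]:
    # class anchors spread across the frame; motions follow the activity.
    # noise_sd is the difficulty dial: anchors are ~43 px apart, so small
    # noise keeps classes trivially separable while pose-estimation noise of
    # a few tens of pixels makes few-shot classes genuinely hard.
    cx = {c: width * (0.12 + 0.068 * (c - 1)) for c in range(1, 13)}
    return {
        1: _Archetype(cx[1], drop_px=170, drop_duration=0.9, lean_px=45),  # fall fwd, hands
        2: _Archetype(cx[2], drop_px=150, drop_duration=1.1, lean_px=30),  # fall fwd, knees
        3: _Archetype(cx[3], drop_px=165, drop_duration=1.0, lean_px=-40),  # fall backward
        4: _Archetype(cx[4], drop_px=160, drop_duration=0.8, lean_px=-60),  # fall sideways
        5: _Archetype(cx[5], drop_px=110, drop_duration=1.2, lean_px=10),  # fall onto chair
        6: _Archetype(cx[6], osc_amp=15, osc_freq=1.5, drift_vx=25),  # walking
        7: _Archetype(cx[7], osc_amp=2, osc_freq=0.3),  # standing
        8: _Archetype(cx[8], osc_amp=3, osc_freq=0.2, squash=0.55, base_y=300),  # sitting
        9: _Archetype(cx[9], dip_px=120),  # picking up an object
        10: _Archetype(cx[10], body_amp=25, body_freq=2.0, osc_amp=8, osc_freq=2.0),  # jumping
        11: _Archetype(cx[11], osc_amp=1.5, osc_freq=0.15, squash=0.18, base_y=430),  # laying
        12: _Archetype(cx[12], osc_amp=6, osc_freq=0.45, drift_vx=-10),  # unknown
    }


@dataclass(frozen=True)
class MotionConfig:
    """Study conditions of the synthetic corpus.

    ``class_counts`` maps class id to the number of sequences generated;
    ``seconds`` is each sequence's duration (default 4 s = 72 frames at
    18 fps, i.e. 37 unit-stride 36-frame windows per sequence);
    ``noise_sd`` is per-coordinate Gaussian jitter in pixels emulating
    pose-estimator noise.
    """

    n_classes: int = 12
    class_counts: Mapping[int, int] = field(
        default_factory=lambda: {c: 10 for c in range(1, 13)}
    )
    fps: float = 18.0
    seconds: float = 4.0
    noise_sd: float = 3.0
    frame_size: tuple[int, int] = (640, 480)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.class_counts.values()):
            raise ValueError("sequence counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if sum(self.class_counts.values()) == 0:
            raise ValueError("zero total sequences requested")


def _class_trajectory(
    arch: _Archetype, n_frames: int, fps: float, rng: np.random.Generator
) -> np.ndarray:
    """Noise-free joint coordinates, shape (n_frames, 17, 2)."""
    t = np.arange(n_frames) / fps
    xy = np.empty((n_frames, N_JOINTS, 2))
    template = _TEMPLATE.copy()
    template[:, 1] *= arch.squash
    xy[:] = template[None, :, :]
    xy[..., 0] += arch.cx + arch.drift_vx * t[:, None]
    xy[..., 1] += arch.base_y

    if arch.osc_amp:
        phase = rng.uniform(0, 2 * np.pi)
        osc = arch.osc_amp * np.sin(2 * np.pi * arch.osc_freq * t + phase)
        signs = np.where(np.isin(np.arange(N_JOINTS), _LIMBS[::2]), 1.0, -1.0)
        xy[:, _LIMBS, 0] += osc[:, None] * signs[_LIMBS]
    if arch.body_amp:
        phase = rng.uniform(0, 2 * np.pi)
        bounce = arch.body_amp * np.abs(np.sin(2 * np.pi * arch.body_freq * t + phase))
        xy[..., 1] -= bounce[:, None]
    if arch.drop_px:
        # monotone upper-body descent over ~1 s starting mid-sequence
        t0 = 0.35 * t[-1]
        prog = np.clip((t - t0) / arch.drop_duration, 0.0, 1.0)
        xy[:, _UPPER_BODY, 1] += arch.drop_px * prog[:, None]
        xy[:, _UPPER_BODY, 0] += arch.lean_px * prog[:, None]
    if arch.dip_px:
        # half-sine dip down and back up across the sequence
        dip = arch.dip_px * np.sin(np.pi * t / t[-1])
        xy[:, _UPPER_BODY, 1] += dip[:, None]
    return xy


def generate_sequence(
    class_id: int, config: MotionConfig, rng: np.random.Generator, source_id: str = ""
) -> PoseSequence:
    """One labeled synthetic pose sequence for ``class_id``."""
    arch = _archetypes(config.frame_size[0])[class_id]
    n_frames = int(round(config.seconds * config.fps))
    xy = _class_trajectory(arch, n_frames, config.fps, rng)
    if config.noise_sd:
        xy = xy + rng.normal(0.0, config.noise_sd, size=xy.shape)
    w, h = config.frame_size
    xy[..., 0] = np.clip(xy[..., 0], 0, w - 1)
    xy[..., 1] = np.clip(xy[..., 1], 0, h - 1)
    scores = rng.uniform(0.5, 1.0, size=(n_frames, N_JOINTS))
    frames = [
        PoseFrame(
            frame_index=i,
            keypoints=tuple(
                Keypoint(float(xy[i, j, 0]), float(xy[i, j, 1]), float(scores[i, j]))
                for j in range(N_JOINTS)
            ),
            label=class_id,
            source_id=source_id,
        )
        for i in range(n_frames)
    ]
    return PoseSequence(frames=frames, fps=config.fps, source_id=source_id)


def generate_dataset(config: MotionConfig = MotionConfig()) -> list[PoseSequence]:
    """Generate the full labeled corpus; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    sequences = []
    for class_id in sorted(config.class_counts):
        if not 1 <= class_id <= config.n_classes:
            raise ValueError(f"class id {class_id} outside 1..{config.n_classes}")
        for rep in range(config.class_counts[class_id]):
            sid = f"synth-c{class_id:02d}-{rep:04d}"
            sequences.append(generate_sequence(class_id, config, rng, source_id=sid))
    return sequences


def imbalance_profile(
    style: str = "upfall_like", budget: int = 1000, n_classes: int = 12
) -> dict[int, int]:
    """Allocate ``budget`` items across classes.

    ``upfall_like`` follows the published window-count shares (walking
    18.59%, each fall style under 1%, ...); ``uniform`` splits evenly.
    Largest-remainder rounding conserves the budget exactly; every class
    receives at least one item.
    """
    if budget < n_classes:
        raise ValueError(f"budget {budget} below the number of classes {n_classes}")
    if style == "uniform":
        shares = np.ones(n_classes)
    elif style == "upfall_like":
        if n_classes != 12:
            raise ValueError("upfall_like profile is defined for 12 classes")
        shares = np.array([UPFALL_WINDOW_COUNTS[c] for c in range(1, 13)], dtype=np.float64)
    else:
        raise ValueError(f"unknown style {style!r}")
    shares = shares / shares.sum()
    raw = shares * budget
    counts = np.floor(raw).astype(int)
    rem = budget - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    # guarantee one item per class, borrowing from the largest
    while (counts == 0).any():
        counts[counts.argmax()] -= 1
        counts[np.flatnonzero(counts == 0)[0]] += 1
    return {c + 1: int(counts[c]) for c in range(n_classes)}
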