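"""Seeded generators of synthetic clips, observers, and rating tables.

The generators emulate the statistical structure the detectors and
evaluators assume in real action-observation footage, at desk scale: a
static (optionally noisy) background, a single moving region inside a
vertical "actor" band whose motion starts at a known true frame between 2
and 18, small sub-area/sub-threshold distractor events (shadows, flicker),
three-category rating tables with a configurable confusion kernel, and
observer pools whose category recognition switches on at a true frame r.
Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .psychometrics import DEFAULT_LABELS, RatingMatrix
from .staircase import ObserverModel
from .video_core import FrameSequence

__all__ = [
    "Distractor",
    "SyntheticVideoSpec",
    "SyntheticRatingSpec",
    "make_motion_video",
    "make_ratings",
    "make_observer_pool",
]


@dataclass(frozen=True)
class Distractor:
    """A small change event that must NOT be reported as actor motion.

    A rectangle of ``w x h`` pixels at (x, y) (1-based, top-left) whose
    intensity deviates by ``intensity_step`` on alternating runs of
    ``period`` frames starting at frame 2 — a cartoon of the shadow/flicker
    false-positive sources real footage exhibits.  Callers keep it harmless
    by making it sub-area (w*h below the detector's minimum box area) or
    sub-threshold (step below 10 % of the intensity range).
    """

    x: int
    y: int
    w: int
    h: int
    intensity_step: int = 30
    period: int = 1

    def active(self, frame_index: int) -> bool:
        if frame_index < 2:
            return False
        return ((frame_index - 2) // self.period) % 2 == 0


@dataclass(frozen=True)
class SyntheticVideoSpec:
    """Recipe for one synthetic clip.

    Defaults mirror the regime the detector is built for, scaled down from
    720x1280 HD to a 200x200 desk-test raster: 60 frames/s, true motion
    onset within frames 2-18, one 30x30 moving patch stepping 120 gray
    levels above a quiet background, fully inside the actor band.
    """

    width: int = 200
    height: int = 200
    n_frames: int = 60
    fps: float = 60.0
    background_level: int = 30
    background_noise_sd: float = 0.0
    onset_frame: int = 10
    patch_size: tuple[int, int] = (30, 30)  # (w, h)
    patch_intensity_step: int = 120
    patch_position: tuple[int, int] | None = None  # 1-based (x, y); None = centered
    patch_velocity: tuple[int, int] = (0, 0)  # pixels/frame after onset
    distractors: tuple[Distractor, ...] = ()
    actor_band: tuple[int, int] | None = None  # 1-based inclusive (y_min, y_max)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.onset_frame <= self.n_frames:
            raise ValueError(
                f"onset_frame must be in [2, {self.n_frames}], got {self.onset_frame}"
            )
        pw, ph = self.patch_size
        if pw < 1 or ph < 1:
            raise ValueError("patch must be at least 1x1")
        x, y = self.resolved_patch_position()
        if x < 1 or y < 1 or x + pw - 1 > self.width or y + ph - 1 > self.height:
            raise ValueError("patch (with its start position) must lie inside the frame")

    def resolved_patch_position(self) -> tuple[int, int]:
        if self.patch_position is not None:
            return self.patch_position
        pw, ph = self.patch_size
        band = self.actor_band or (1, self.height)
        x = max(1, (self.width - pw) // 2 + 1)
        y = max(band[0], (band[0] + band[1] - ph) // 2)
        return (x, y)


def make_motion_video(spec: SyntheticVideoSpec) -> tuple[FrameSequence, dict]:
    """Render a clip from a spec; returns the sequence and its ground truth.

    Frames before the onset contain only the background (plus distractor
    events and noise); from ``onset_frame`` on, the patch is present and
    drifts linearly at ``patch_velocity``.  Identical specs give
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    pw, ph = spec.patch_size
    x0, y0 = spec.resolved_patch_position()
    base = np.full((spec.height, spec.width), spec.background_level, dtype=np.float64)
    frames = np.empty((spec.n_frames, spec.height, spec.width), dtype=np.uint8)
    for t in range(1, spec.n_frames + 1):
        img = base.copy()
        for d in spec.distractors:
            if d.active(t):
                img[d.y - 1 : d.y - 1 + d.h, d.x - 1 : d.x - 1 + d.w] += d.intensity_step
        if t >= spec.onset_frame:
            k = t - spec.onset_frame
            x = x0 + k * spec.patch_velocity[0]
            y = y0 + k * spec.patch_velocity[1]
            x = min(max(1, x), spec.width - pw + 1)
            y = min(max(1, y), spec.height - ph + 1)
            img[y - 1 : y - 1 + ph, x - 1 : x - 1 + pw] += spec.patch_intensity_step
        if spec.background_noise_sd > 0:
            img += rng.normal(0.0, spec.background_noise_sd, size=img.shape)
        frames[t - 1] = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    truth = {
        "onset_frame": spec.onset_frame,
        "patch_x": x0,
        "patch_y": y0,
        "patch_w": pw,
        "patch_h": ph,
        "actor_band": spec.actor_band or (1, spec.height),
    }
    return FrameSequence(frames=frames, fps=spec.fps), truth


def _uniform_offdiagonal_kernel(k: int, diagonal: float) -> np.ndarray:
    kernel = np.full((k, k), (1.0 - diagonal) / (k - 1))
    np.fill_diagonal(kernel, diagonal)
    return kernel


@dataclass(frozen=True)
class SyntheticRatingSpec:
    """Recipe for a synthetic multi-rater rating table.

    Defaults emulate the evaluation setting the metrics target: 135 items
    (three balanced categories), 51 raters, and a confusion kernel whose
    diagonal matches an overall recognition accuracy of about 89 % with
    errors spread evenly over the other two categories.
    """

    n_items: int = 135
    n_raters: int = 51
    labels: tuple[str, ...] = DEFAULT_LABELS
    kernel: tuple[tuple[float, ...], ...] | None = None  # rows: truth -> assigned
    diagonal: float = 0.886
    balanced: bool = True
    seed: int = 0

    def kernel_array(self) -> np.ndarray:
        k = len(self.labels)
        if self.kernel is None:
            kernel = _uniform_offdiagonal_kernel(k, self.diagonal)
        else:
            kernel = np.asarray(self.kernel, dtype=float)
        if kernel.shape != (k, k):
            raise ValueError(f"kernel must be {k}x{k} for labels {self.labels}")
        if np.any(kernel < 0) or not np.allclose(kernel.sum(axis=1), 1.0):
            raise ValueError("each kernel row must be a probability distribution")
        return kernel


def make_ratings(spec: SyntheticRatingSpec) -> RatingMatrix:
    """Draw a rating table: truth per item, then responses from the kernel
    row of each item's truth.  Balanced mode assigns items to categories as
    evenly as possible before a seeded shuffle; otherwise truth is uniform."""
    rng = np.random.default_rng(spec.seed)
    k = len(spec.labels)
    kernel = spec.kernel_array()
    if spec.balanced:
        truth_idx = np.tile(np.arange(k), spec.n_items // k + 1)[: spec.n_items]
        rng.shuffle(truth_idx)
    else:
        truth_idx = rng.integers(0, k, size=spec.n_items)
    responses = np.empty((spec.n_items, spec.n_raters), dtype=np.int64)
    for i, ti in enumerate(truth_idx):
        responses[i] = rng.choice(k, size=spec.n_raters, p=kernel[ti])
    items = [f"video_{i + 1:03d}" for i in range(spec.n_items)]
    raters = [f"rater_{j + 1:02d}" for j in range(spec.n_raters)]
    label_arr = np.asarray(spec.labels)
    ratings = pd.DataFrame(label_arr[responses], index=items, columns=raters)
    ratings.index.name = "video_id"
    truth = pd.Series(label_arr[truth_idx], index=ratings.index, name="truth")
    return RatingMatrix(ratings=ratings, truth=truth, labels=spec.labels)


def make_observer_pool(
    true_frames: Mapping[str, int],
    n_frames: Mapping[str, int] | None = None,
    guess_rate: float = 1.0 / 3.0,
    lapse_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, ObserverModel]:
    """One seeded observer per video, keyed like ``true_frames``.

    Each observer's stream comes from an independent child of the pool seed,
    so replaying the pool reproduces every staircase trajectory exactly.
    ``n_frames``, when given, validates that each true frame r lies within
    its video's frame range.
    """
    if n_frames is not None:
        for vid, r in true_frames.items():
            if vid not in n_frames:
                raise ValueError(f"no frame count for video {vid!r}")
            if not 1 <= r <= n_frames[vid]:
                raise ValueError(
                    f"true frame {r} outside [1, {n_frames[vid]}] for video {vid!r}"
                )
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(true_frames))
    return {
        vid: ObserverModel(r=r, guess_rate=guess_rate, lapse_rate=lapse_rate, seed=child)
        for (vid, r), child in zip(sorted(true_frames.items()), children)
    }
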