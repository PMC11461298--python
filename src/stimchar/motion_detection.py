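"""Frame-differencing motion-onset detection.

Each frame of a clip is converted to grayscale and compared pixel-wise to the
static initial frame.  Pixels whose intensity differs by at least a fixed
fraction of the 8-bit range (default 10 %, i.e. |delta| >= 25.5) are marked as
changed; connected changed regions are reduced to bounding boxes, and boxes
are kept only if their area reaches a minimum (default 400 px, rejecting
sensor noise and flicker) and they overlap a vertical band where the actor
sits.  The first frame with at least one surviving box is the motion onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops

from .video_core import FrameSequence, to_grayscale

__all__ = [
    "MotionDetectionConfig",
    "Box",
    "OnsetResult",
    "difference_mask",
    "motion_boxes",
    "detect_motion_onset",
]


@dataclass(frozen=True)
class MotionDetectionConfig:
    """Detector parameters.

    threshold_fraction:
        Fraction of the full intensity range a pixel must change by to count
        as different; 0.10 means an integer difference of at least 26 on
        8-bit input ("at least 10 %": ties count as changed).
    min_box_area:
        Minimum bounding-box area (w x h, pixels) for a changed region to be
        treated as actor motion rather than noise.
    roi_y:
        Inclusive 1-based (y_min, y_max) row band containing the actor;
        ``None`` means the full frame height.
    reference_frame:
        1-based index of the static reference frame (never updated).
    """

    threshold_fraction: float = 0.10
    min_box_area: int = 400
    roi_y: tuple[int, int] | None = None
    reference_frame: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError(
                f"threshold_fraction must be in (0, 1), got {self.threshold_fraction}"
            )
        if self.min_box_area < 1:
            raise ValueError(f"min_box_area must be >= 1, got {self.min_box_area}")
        if self.roi_y is not None:
            y_min, y_max = self.roi_y
            if not 1 <= y_min <= y_max:
                raise ValueError(f"invalid roi_y band {self.roi_y}")
        if self.reference_frame < 1:
            raise ValueError("reference_frame must be >= 1")


@dataclass(frozen=True)
class Box:
    """Axis-aligned bounding box of one connected changed region.

    ``x``, ``y`` are the 1-based column/row of the top-left pixel.
    """

    x: int
    y: int
    w: int
    h: int

    @property
    def area(self) -> int:
        return self.w * self.h

    @property
    def y_extent(self) -> tuple[int, int]:
        """Inclusive 1-based row range covered by the box."""
        return (self.y, self.y + self.h - 1)


@dataclass
class OnsetResult:
    """Outcome of onset detection for one clip.

    ``onset_frame`` is the first (1-based) frame with a surviving motion box,
    or ``None`` if no frame qualifies.  ``box_log`` maps each examined frame
    (2..n_frames) to its surviving boxes.
    """

    video_id: str
    onset_frame: int | None
    box_log: dict[int, list[Box]] = field(repr=False, default_factory=dict)


def difference_mask(
    gray_frame: np.ndarray, gray_reference: np.ndarray, threshold_fraction: float = 0.10
) -> np.ndarray:
    """Boolean mask of pixels differing from the reference by >= the threshold.

    The cutoff is ``threshold_fraction * (levels - 1)`` = 25.5 gray levels at
    the default 10 %, so an integer difference of 26 is the smallest change
    that registers.
    """
    gray_frame = np.asarray(gray_frame)
    gray_reference = np.asarray(gray_reference)
    if gray_frame.ndim != 2 or gray_reference.ndim != 2:
        raise ValueError("difference_mask expects single-channel frames")
    if gray_frame.shape != gray_reference.shape:
        raise ValueError(
            f"frame shape {gray_frame.shape} != reference shape {gray_reference.shape}"
        )
    delta = np.abs(gray_frame.astype(np.int16) - gray_reference.astype(np.int16))
    return delta >= threshold_fraction * 255.0


def motion_boxes(mask: np.ndarray, config: MotionDetectionConfig) -> list[Box]:
    """Bounding boxes of 8-connected changed regions that pass the filters.

    A box survives if its area (w x h) reaches ``min_box_area`` and its row
    extent intersects the actor band ``roi_y``.  Boxes are ordered
    top-to-bottom, then left-to-right.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    labeled = label(mask, connectivity=2)
    boxes = []
    for region in regionprops(labeled):
        r0, c0, r1, c1 = region.bbox  # half-open, 0-based
        box = Box(x=c0 + 1, y=r0 + 1, w=c1 - c0, h=r1 - r0)
        if box.area < config.min_box_area:
            continue
        if config.roi_y is not None:
            lo, hi = box.y_extent
            if hi < config.roi_y[0] or lo > config.roi_y[1]:
                continue
        boxes.append(box)
    boxes.sort(key=lambda b: (b.y, b.x))
    return boxes


def detect_motion_onset(
    seq: FrameSequence,
    config: MotionDetectionConfig | None = None,
    video_id: str = "",
) -> OnsetResult:
    """Report the first frame with actor motion relative to the static reference.

    Every frame from 2 to the end is differenced against the reference frame
    (frame 1 by default); the onset is the earliest frame whose difference
    mask yields at least one box surviving the area and ROI filters.
    """
    if config is None:
        config = MotionDetectionConfig()
    if seq.n_frames < 2:
        raise ValueError("onset detection needs at least 2 frames")
    if config.reference_frame > seq.n_frames:
        raise ValueError(
            f"reference_frame {config.reference_frame} beyond clip length {seq.n_frames}"
        )
    reference = to_grayscale(seq.frame(config.reference_frame))
    onset: int | None = None
    box_log: dict[int, list[Box]] = {}
    for t in range(2, seq.n_frames + 1):
        mask = difference_mask(to_grayscale(seq.frame(t)), reference, config.threshold_fraction)
        boxes = motion_boxes(mask, config)
        box_log[t] = boxes
        if onset is None and boxes:
            onset = t
    return OnsetResult(video_id=video_id, onset_frame=onset, box_log=box_log)
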