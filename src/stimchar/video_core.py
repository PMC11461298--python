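"""Frame sequences: loading, saving, grayscale conversion, onset-aligned trimming.

The unit of work throughout the package is a :class:`FrameSequence` — an
ordered stack of 8-bit frames with a frame rate.  Frames are indexed
**1-based** in every public interface: frame 1 is the static reference frame
of a clip, so the earliest frame on which motion can be registered is
frame 2.

Two storage formats are supported:

* a directory of numbered PNG images plus a small ``metadata.json`` sidecar
  (lossless; the format used for fixtures and threshold-sensitive work), and
* any movie container a locally available imageio plugin can decode
  (e.g. MP4/M4V where an ffmpeg backend is installed).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FrameSequence",
    "VideoMetadata",
    "VideoReadError",
    "load_video",
    "save_video",
    "to_grayscale",
    "trim_to_onset",
    "resolve_onsets",
    "OnsetResolution",
    "read_onset_overrides",
]

_IMAGE_EXTENSIONS = {".png", ".bmp", ".tif", ".tiff", ".jpg", ".jpeg"}

# BT.601 luma weights for RGB -> gray.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class VideoReadError(ValueError):
    """Raised when a path cannot be decoded into a frame sequence."""


@dataclass
class FrameSequence:
    """An ordered stack of equally sized 8-bit frames.

    Parameters
    ----------
    frames:
        Array of shape ``(T, H, W)`` (grayscale) or ``(T, H, W, 3)`` (RGB),
        dtype ``uint8``, ``T >= 1``.
    fps:
        Frames per second; positive. Default 60, the recording rate the
        rest of the package assumes when a container carries no rate.
    """

    frames: np.ndarray
    fps: float = 60.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.dtype != np.uint8:
            raise ValueError(f"frames must be uint8, got {self.frames.dtype}")
        if self.frames.ndim not in (3, 4):
            raise ValueError(
                f"frames must have shape (T, H, W) or (T, H, W, 3), got {self.frames.shape}"
            )
        if self.frames.ndim == 4 and self.frames.shape[-1] not in (1, 3):
            raise ValueError(f"unsupported channel count {self.frames.shape[-1]}")
        if self.frames.shape[0] < 1:
            raise ValueError("a frame sequence needs at least one frame")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def height(self) -> int:
        return int(self.frames.shape[1])

    @property
    def width(self) -> int:
        return int(self.frames.shape[2])

    @property
    def n_channels(self) -> int:
        return 1 if self.frames.ndim == 3 else int(self.frames.shape[-1])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def frame(self, index: int) -> np.ndarray:
        """Return frame ``index`` (1-based)."""
        if not 1 <= index <= self.n_frames:
            raise IndexError(f"frame index {index} outside [1, {self.n_frames}]")
        return self.frames[index - 1]

    def metadata(self, video_id: str = "") -> "VideoMetadata":
        return VideoMetadata(video_id=video_id, n_frames=self.n_frames, fps=self.fps)


@dataclass(frozen=True)
class VideoMetadata:
    video_id: str
    n_frames: int
    fps: float

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


def _natural_key(p: Path):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", p.name)]


def _load_frame_dir(path: Path, fps: float | None, default_fps: float) -> FrameSequence:
    import imageio.v3 as iio

    files = sorted(
        (f for f in path.iterdir() if f.suffix.lower() in _IMAGE_EXTENSIONS),
        key=_natural_key,
    )
    if not files:
        raise VideoReadError(f"no frame images found in directory {path}")
    frames = np.stack([np.asarray(iio.imread(f)) for f in files])
    if frames.dtype != np.uint8:
        frames = frames.astype(np.uint8)
    if fps is None:
        meta_path = path / "metadata.json"
        if meta_path.exists():
            fps = float(json.loads(meta_path.read_text()).get("fps", default_fps))
        else:
            fps = default_fps
    return FrameSequence(frames=frames, fps=fps)


def load_video(
    path: str | Path, fps: float | None = None, default_fps: float = 60.0
) -> FrameSequence:
    """Read a video file or a directory of ordered frame images.

    ``fps`` overrides any container/sidecar value; when the container carries
    no rate, ``default_fps`` applies.
    """
    path = Path(path)
    if not path.exists():
        raise VideoReadError(f"no such video: {path}")
    if path.is_dir():
        return _load_frame_dir(path, fps, default_fps)
    if path.stat().st_size == 0:
        raise VideoReadError(f"empty video file: {path}")

    import imageio.v3 as iio

    try:
        frames = np.stack(list(iio.imiter(path)))
    except Exception as exc:  # plugin missing or corrupt stream
        raise VideoReadError(f"cannot decode video {path}: {exc}") from exc
    if frames.dtype != np.uint8:
        frames = frames.astype(np.uint8)
    if fps is None:
        try:
            meta = iio.immeta(path)
            fps = float(meta["fps"]) if "fps" in meta else default_fps
        except Exception:
            fps = default_fps
    return FrameSequence(frames=frames, fps=fps)


def save_video(seq: FrameSequence, path: str | Path, lossless: bool | None = None) -> None:
    """Write ``seq`` either as a PNG frame directory (lossless) or a movie file.

    A path without a movie suffix is treated as a frame directory; each frame
    is written as ``frame_0001.png`` etc. with a ``metadata.json`` recording
    the frame rate, so that :func:`load_video` round-trips frame count, fps
    and pixel values exactly.
    """
    if seq.n_frames < 1:  # pragma: no cover - FrameSequence already enforces this
        raise ValueError("cannot save an empty sequence")
    path = Path(path)
    as_dir = lossless if lossless is not None else path.suffix.lower() not in {
        ".mp4",
        ".m4v",
        ".avi",
        ".mov",
        ".gif",
    }
    import imageio.v3 as iio

    if as_dir:
        path.mkdir(parents=True, exist_ok=True)
        width = len(str(seq.n_frames))
        for i in range(seq.n_frames):
            iio.imwrite(path / f"frame_{i + 1:0{width}d}.png", seq.frames[i])
        (path / "metadata.json").write_text(
            json.dumps({"fps": seq.fps, "n_frames": seq.n_frames}) + "\n"
        )
    else:
        try:
            iio.imwrite(path, seq.frames, fps=seq.fps)
        except Exception as exc:
            raise IOError(f"cannot encode video {path}: {exc}") from exc


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert one 8-bit frame to a single grayscale channel.

    3-channel input is combined with BT.601 luma weights (0.299, 0.587,
    0.114) and rounded half-up; 1-channel input passes through unchanged.
    """
    frame = np.asarray(frame)
    if frame.dtype != np.uint8:
        raise ValueError(f"expected uint8 frame, got {frame.dtype}")
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[-1] == 1:
        return frame[..., 0]
    if frame.ndim == 3 and frame.shape[-1] == 3:
        luma = frame.astype(np.float64) @ _LUMA_WEIGHTS
        return np.floor(luma + 0.5).astype(np.uint8)
    raise ValueError(f"unsupported frame shape {frame.shape}")


def trim_to_onset(seq: FrameSequence, onset_frame: int) -> FrameSequence:
    """Trim so the clip starts at the frame *preceding* motion onset.

    With a (1-based) onset at frame ``k``, the returned sequence contains the
    original frames ``k-1 .. n``; motion then begins at frame 2 of the result,
    with frame 1 a still reference.  Output length is ``n - k + 2``.
    """
    if not 2 <= onset_frame <= seq.n_frames:
        raise ValueError(
            f"onset_frame must be in [2, {seq.n_frames}], got {onset_frame}"
        )
    return FrameSequence(frames=seq.frames[onset_frame - 2 :].copy(), fps=seq.fps)


@dataclass
class OnsetResolution:
    """Automatic onsets merged with human overrides."""

    onsets: dict[str, int]
    disagreements: pd.DataFrame = field(repr=False)


def resolve_onsets(
    auto: Mapping[str, int], manual: Mapping[str, int]
) -> OnsetResolution:
    """Apply human-judged onset overrides on top of automatic detections.

    Wherever a manual judgment exists it wins; the returned report lists every
    video where human and algorithm disagreed (the typical causes in real
    footage are small shadows, clothing wrinkles, or eye movements fooling the
    detector).
    """
    missing = sorted(set(manual) - set(auto))
    if missing:
        raise KeyError(f"manual onsets for unknown videos: {missing}")
    resolved = dict(auto)
    rows = []
    for vid, frame in manual.items():
        if frame != auto[vid]:
            rows.append({"video_id": vid, "auto": auto[vid], "manual": frame})
        resolved[vid] = frame
    report = pd.DataFrame(rows, columns=["video_id", "auto", "manual"])
    return OnsetResolution(onsets=resolved, disagreements=report)


def read_onset_overrides(path: str | Path) -> dict[str, int]:
    """Read a CSV of columns ``video_id, onset_frame`` (onsets must be >= 2)."""
    table = pd.read_csv(path, dtype={"video_id": str})
    if not {"video_id", "onset_frame"} <= set(table.columns):
        raise ValueError(f"{path}: expected columns video_id, onset_frame")
    onsets = dict(zip(table["video_id"], table["onset_frame"].astype(int)))
    bad = {v: k for v, k in onsets.items() if k < 2}
    if bad:
        raise ValueError(
            f"{path}: onset_frame must be >= 2 (frame 1 is the reference), got {bad}"
        )
    return onsets
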