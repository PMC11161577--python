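"""Video, mask, table, and configuration I/O.

Clips are multi-page TIFF stacks (the capture pipeline converts CXD
recordings; AVI requires a codec stack not bundled here and raises a
format error directing to TIFF). Frames are returned as grayscale
floats in [0, 1]. Tables are comma-separated UTF-8 CSV with a header
row; configuration is YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .errors import FormatError, ParameterError

__all__ = [
    "VideoClip",
    "RunConfig",
    "read_video",
    "write_video",
    "read_masks",
    "write_masks",
    "write_png",
]


@dataclass
class VideoClip:
    """T x H x W grayscale frame stack with calibration."""

    frames: np.ndarray
    fps: float
    pixel_size: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ParameterError("frames must be (T, H, W)")
        if self.fps <= 0 or self.pixel_size <= 0:
            raise ParameterError("fps and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape


def _to_unit_float(frames: np.ndarray) -> np.ndarray:
    if frames.dtype == np.uint8:
        return frames.astype(np.float32) / 255.0
    if frames.dtype == np.uint16:
        return frames.astype(np.float32) / 65535.0
    return np.clip(frames.astype(np.float32), 0.0, 1.0)


def read_video(path, fps: float, pixel_size: float) -> VideoClip:
    """Read a grayscale video stack (multi-page TIFF) as a VideoClip.

    Multi-channel frames are converted to grayscale by luminance
    average; 8/16-bit integer data is scaled into [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        try:
            frames = tifffile.imread(path)
        except Exception as exc:
            raise FormatError(f"undecodable TIFF: {path}: {exc}") from exc
    elif suffix == ".avi":
        raise FormatError(
            f"AVI container is not supported without a codec stack: {path}; "
            "convert to multi-page TIFF"
        )
    else:
        try:
            frames = iio.imread(path)
        except Exception as exc:
            raise FormatError(
                f"undecodable container {suffix or '(none)'}: {path}"
            ) from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:  # (T, H, W, C) -> luminance average
        frames = frames.mean(axis=-1).astype(frames.dtype)
    if frames.ndim != 3:
        raise FormatError(f"expected a frame stack, got shape {frames.shape}")
    return VideoClip(_to_unit_float(frames), fps=fps, pixel_size=pixel_size)


def write_video(path, frames: np.ndarray) -> None:
    """Write a float [0, 1] frame stack as 8-bit multi-page TIFF."""
    frames = np.asarray(frames)
    data = np.clip(frames, 0.0, 1.0) if frames.dtype.kind == "f" else frames / 255.0
    tifffile.imwrite(path, (data * 255).astype(np.uint8))


def write_masks(path, masks: np.ndarray) -> None:
    """Write binary masks as 0/255 multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(masks, dtype=bool).astype(np.uint8) * 255)


def read_masks(path) -> np.ndarray:
    return tifffile.imread(path) > 127


def write_png(path, image: np.ndarray) -> None:
    """Write a float [0, 1] (H, W) or (H, W, 3) image as 8-bit PNG."""
    iio.imwrite(path, (np.clip(image, 0, 1) * 255).astype(np.uint8))


@dataclass
class RunConfig:
    """Analysis configuration, serialized verbatim into output folders."""

    pixel_size: float = 1.0
    fps: float = 200.0
    roi: Optional[tuple[int, int]] = None       # column range, None = full
    threshold: float = 0.5
    tachy_threshold_s: float = 0.5
    brady_threshold_s: float = 1.0
    smooth_window: int = 5
    v_thr_frac: float = 0.2
    seed: int = 0
    out_dir: str = "."

    def validate(self) -> None:
        if self.pixel_size <= 0 or self.fps <= 0:
            raise ParameterError("pixel_size and fps must be positive")
        if not (0.0 <= self.threshold <= 1.0):
            raise ParameterError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.tachy_threshold_s <= 0 or self.brady_threshold_s <= 0:
            raise ParameterError("arrhythmia thresholds must be positive")
        if self.smooth_window < 1:
            raise ParameterError("smooth_window must be >= 1")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if d["roi"] is not None:
            d["roi"] = list(d["roi"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if d.get("roi") is not None:
            d["roi"] = tuple(d["roi"])
        return cls(**d)
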