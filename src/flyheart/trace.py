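"""Lumen-diameter trace extraction from per-frame wall masks.

The heart tube appears as two horizontal wall bands; in every mask
column the lumen diameter is the number of non-wall rows strictly
between the uppermost and lowermost wall runs. Per-frame diameter is
the mean over valid ROI columns, calibrated to µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ExtractionError, ParameterError

__all__ = [
    "ROI",
    "DiameterTrace",
    "MModeImage",
    "column_lumen_diameter",
    "frame_diameter",
    "stack_diameters",
    "extract_trace",
    "make_mmode",
]


@dataclass(frozen=True)
class ROI:
    """Half-open pixel column range [c0, c1) (0-based), optional rows.

    Selected by the operator through visual confirmation of the
    segmentation overlay, or defaulted to the full frame width.
    """

    c0: int
    c1: int
    r0: Optional[int] = None
    r1: Optional[int] = None

    def check(self, height: int, width: int) -> None:
        if not (0 <= self.c0 < self.c1 <= width):
            raise ParameterError(
                f"ROI columns [{self.c0}, {self.c1}) outside image width {width}"
            )
        if self.r0 is not None or self.r1 is not None:
            r0 = 0 if self.r0 is None else self.r0
            r1 = height if self.r1 is None else self.r1
            if not (0 <= r0 < r1 <= height):
                raise ParameterError(
                    f"ROI rows [{r0}, {r1}) outside image height {height}"
                )

    @classmethod
    def full(cls, width: int) -> "ROI":
        return cls(0, width)

    @property
    def width(self) -> int:
        return self.c1 - self.c0

    def length_um(self, pixel_size: float) -> float:
        """ROI length along the tube axis in µm (for stroke volume)."""
        return self.width * pixel_size


@dataclass
class DiameterTrace:
    """Per-frame mean lumen diameter in µm with validity flags."""

    values: np.ndarray
    valid: np.ndarray
    fps: float
    pixel_size: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ParameterError("values and valid must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(len(self.values)),
            "time_s": self.times,
            "diameter_um": self.values,
            "valid": self.valid.astype(int),
        })

    @classmethod
    def from_waveform(cls, waveform, fps, pixel_size=1.0) -> "DiameterTrace":
        """Wrap a ground-truth waveform as an all-valid trace."""
        w = np.asarray(waveform, dtype=np.float64)
        return cls(w, np.ones(len(w), dtype=bool), fps, pixel_size)


@dataclass
class MModeImage:
    """One pixel column over time with wall tint and DI boundary markers."""

    image: np.ndarray          # (H, T, 3) float RGB in [0, 1]
    column: int
    di_start_frames: np.ndarray
    di_end_frames: np.ndarray


def _wall_runs(column: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of wall pixels as (first_row, last_row) pairs."""
    idx = np.flatnonzero(column)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def column_lumen_diameter(mask_column: np.ndarray) -> Optional[int]:
    """Lumen diameter of one mask column in px, or None if undefined.

    Requires at least two wall runs; with more than two (speckle), the
    uppermost and lowermost runs bound the lumen. The diameter is the
    count of non-wall rows strictly between the uppermost run's last
    row and the lowermost run's first row.
    """
    col = np.asarray(mask_column, dtype=bool)
    runs = _wall_runs(col)
    if len(runs) < 2:
        return None
    top_last = runs[0][1]
    bottom_first = runs[-1][0]
    between = col[top_last + 1: bottom_first]
    return int((~between).sum())


def frame_diameter(mask: np.ndarray, roi: ROI, pixel_size: float,
                   min_valid_frac: float = 0.25) -> Optional[float]:
    """Mean lumen diameter of a frame over valid ROI columns, in µm.

    Returns None (invalid frame) when fewer than ``min_valid_frac`` of
    the ROI columns yield a diameter.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    roi.check(h, w)
    sub = mask
    if roi.r0 is not None or roi.r1 is not None:
        sub = mask[roi.r0 or 0: roi.r1 if roi.r1 is not None else h]
    diameters = [column_lumen_diameter(sub[:, c]) for c in range(roi.c0, roi.c1)]
    valid = [d for d in diameters if d is not None]
    if len(valid) < min_valid_frac * roi.width:
        return None
    return float(np.mean(valid)) * pixel_size


def _stack_column_diameters(masks: np.ndarray) -> np.ndarray:
    """Vectorized per-column lumen diameters of a (T, H, W) mask stack.

    Equivalent to column_lumen_diameter applied to every column of
    every frame; returns (T, W) floats with NaN where undefined.
    """
    m = masks
    H = m.shape[1]
    any_wall = m.any(axis=1)
    run_ends = np.concatenate([m[:, :-1] & ~m[:, 1:], m[:, -1:]], axis=1)
    run_starts = np.concatenate([m[:, :1], ~m[:, :-1] & m[:, 1:]], axis=1)
    up_end = run_ends.argmax(axis=1)                       # uppermost run's last row
    low_start = H - 1 - run_starts[:, ::-1].argmax(axis=1)  # lowermost run's first row
    first_wall = m.argmax(axis=1)
    last_wall = H - 1 - m[:, ::-1].argmax(axis=1)
    wall_count = m.sum(axis=1)
    top_len = up_end - first_wall + 1
    bot_len = last_wall - low_start + 1
    # non-wall rows strictly between the outermost runs (speckle subtracted)
    diam = (low_start - up_end - 1) - (wall_count - top_len - bot_len)
    valid = any_wall & (up_end < low_start)
    return np.where(valid, diam.astype(np.float64), np.nan)


def stack_diameters(masks: np.ndarray, roi: ROI, pixel_size: float,
                    min_valid_frac: float = 0.25) -> np.ndarray:
    """Per-frame mean lumen diameter (µm) of a mask stack; NaN = invalid."""
    masks = np.asarray(masks, dtype=bool)
    T, H, W = masks.shape
    roi.check(H, W)
    sub = masks
    if roi.r0 is not None or roi.r1 is not None:
        sub = masks[:, roi.r0 or 0: roi.r1 if roi.r1 is not None else H]
    cols = _stack_column_diameters(sub[:, :, roi.c0: roi.c1])
    n_valid = (~np.isnan(cols)).sum(axis=1)
    sums = np.nansum(cols, axis=1)
    mean = np.divide(sums, n_valid, out=np.full(len(sums), np.nan),
                     where=n_valid > 0)
    return np.where(n_valid >= min_valid_frac * roi.width, mean * pixel_size, np.nan)


def extract_trace(masks: np.ndarray, roi: ROI, pixel_size: float, fps: float,
                  max_gap: int = 5) -> DiameterTrace:
    """Per-frame diameter trace from a (T, H, W) mask stack.

    Interior invalid frames in gaps of at most ``max_gap`` frames are
    filled by linear interpolation between the nearest valid neighbours
    and flagged valid; longer gaps are filled (so the series stays
    finite) but flagged invalid. Leading/trailing invalid frames are
    never extrapolated and stay invalid.
    """
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim != 3 or masks.shape[0] < 1:
        raise ParameterError("masks must be a (T, H, W) stack")
    raw = stack_diameters(masks, roi, pixel_size)
    valid = ~np.isnan(raw)
    if not valid.any():
        raise ExtractionError("no frame yields a valid diameter in this ROI")
    values = raw.copy()
    vidx = np.flatnonzero(valid)
    first, last = vidx[0], vidx[-1]
    inner = np.arange(first, last + 1)
    values[inner] = np.interp(inner, vidx, raw[vidx])
    out_valid = valid.copy()
    # short interior gaps become valid after interpolation
    gap_start = None
    for i in range(first, last + 1):
        if not valid[i]:
            if gap_start is None:
                gap_start = i
        elif gap_start is not None:
            if i - gap_start <= max_gap:
                out_valid[gap_start:i] = True
            gap_start = None
    # outside [first, last]: hold edge values but stay invalid
    values[:first] = values[first]
    values[last + 1:] = values[last]
    return DiameterTrace(values, out_valid, fps, pixel_size)


def make_mmode(clip: np.ndarray, masks: np.ndarray, column: int,
               beat_table=None, wall_tint=(1.0, 0.2, 0.2)) -> MModeImage:
    """Render the annotated M-mode image of one pixel column.

    The chosen column of every frame becomes one image column; wall
    pixels are tinted red; vertical green/red lines mark each DI start
    (end of relaxation) and DI end (next contraction onset).
    """
    clip = np.asarray(clip, dtype=np.float64)
    masks = np.asarray(masks, dtype=bool)
    T, H, W = clip.shape
    if not (0 <= column < W):
        raise ParameterError(f"column {column} outside image width {W}")
    gray = clip[:, :, column].T          # (H, T)
    img = np.repeat(gray[:, :, None], 3, axis=2)
    wall = masks[:, :, column].T
    for ch, tint in enumerate(wall_tint):
        img[:, :, ch][wall] = tint
    di_start = np.array([], dtype=int)
    di_end = np.array([], dtype=int)
    if beat_table is not None and len(beat_table) > 0:
        df = beat_table.to_frame() if hasattr(beat_table, "to_frame") else beat_table
        fps = getattr(beat_table, "fps", None)
        if fps is None:
            raise ParameterError("beat table must carry fps for M-mode markers")
        di_start = np.clip(np.rint(df["rel_end_t"] * fps).astype(int), 0, T - 1)
        di_end = np.clip(
            np.rint((df["onset_t"] + df["hp"]) * fps).astype(int), 0, T - 1
        )
        img[:, di_start] = (0.0, 0.9, 0.0)
        img[:, di_end] = (0.9, 0.0, 0.0)
    return MModeImage(np.clip(img, 0, 1), column, di_start, di_end)
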