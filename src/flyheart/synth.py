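"""Seeded synthetic beating-heart simulator.

Emulates a semi-intact Drosophila heart tube imaged side-on: two
horizontal wall bands whose inner-edge separation (the lumen diameter)
oscillates between a diastolic plateau and a systolic dip. Each beat is
a smoothed trapezoid — cosine-ramped contraction and relaxation edges
(ramp time fixed at 10% of the heart period) around a systolic plateau,
followed by a diastolic plateau — so diastolic intervals and systolic
dips are unambiguous. Per-beat heart periods are drawn from a truncated
normal (HP > 2 frame intervals) to model arrhythmia.

Every sample carries its ground truth: the per-frame diameter waveform,
per-frame binary wall masks, and a per-beat table (onset, SI, DI, DD,
SD, HP), which downstream beat analysis must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import GeometryError, ParameterError

__all__ = [
    "SyntheticHeartSpec",
    "CohortSample",
    "generate_waveform",
    "render_frames",
    "make_cohort",
    "young_spec",
    "old_spec",
]

_RAMP_FRAC = 0.1  # contraction/relaxation ramp, fraction of HP


@dataclass(frozen=True)
class SyntheticHeartSpec:
    """Parameters of one synthetic heart recording.

    Diameters are in µm, times in seconds, geometry in pixels.
    ``si_frac`` is the fraction of each heart period spent in the
    systolic interval (contraction onset to relaxation end) and must
    exceed 0.2 to leave room for the two 10%-of-HP ramps.
    """

    dd_true: float = 60.0
    sd_true: float = 40.0
    hp_mean: float = 0.5
    hp_cv: float = 0.05
    si_frac: float = 0.4
    wall_thickness: int = 4
    noise_sigma: float = 0.05
    fps: float = 200.0
    duration: float = 10.0
    height: int = 96
    width: int = 80
    pixel_size: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (self.dd_true > self.sd_true > 0):
            raise ParameterError(
                f"require dd_true > sd_true > 0, got dd_true={self.dd_true}, "
                f"sd_true={self.sd_true}"
            )
        if not (2 * _RAMP_FRAC < self.si_frac < 1):
            raise ParameterError(
                f"require {2 * _RAMP_FRAC} < si_frac < 1 "
                f"(two 10%-of-HP ramps must fit), got {self.si_frac}"
            )
        if self.hp_cv < 0:
            raise ParameterError(f"require hp_cv >= 0, got {self.hp_cv}")
        if self.fps <= 0:
            raise ParameterError(f"require fps > 0, got {self.fps}")
        if self.duration <= 0:
            raise ParameterError(f"require duration > 0, got {self.duration}")
        if self.hp_mean <= 2.0 / self.fps:
            raise ParameterError(
                f"require hp_mean > 2 frame intervals, got {self.hp_mean}"
            )
        for name in ("wall_thickness", "height", "width"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"require {name} > 0")
        if self.pixel_size <= 0:
            raise ParameterError(f"require pixel_size > 0, got {self.pixel_size}")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration))


@dataclass
class CohortSample:
    """One labeled heart of a synthetic cohort."""

    spec: SyntheticHeartSpec
    waveform: np.ndarray
    true_beats: pd.DataFrame
    label: int  # 0 = young, 1 = old
    clip: Optional[np.ndarray] = None
    masks: Optional[np.ndarray] = None


def _draw_heart_periods(spec: SyntheticHeartSpec, rng: np.random.Generator):
    """Sequential truncated-normal HP draws filling the recording."""
    hp_min = 2.0 / spec.fps
    sigma = spec.hp_cv * spec.hp_mean
    periods = []
    total = 0.0
    while total + spec.hp_mean * 0.1 < spec.duration:
        hp = spec.hp_mean if sigma == 0 else rng.normal(spec.hp_mean, sigma)
        while hp <= hp_min:
            hp = rng.normal(spec.hp_mean, sigma)
        if total + hp > spec.duration + 1e-9:
            break
        periods.append(hp)
        total += hp
    return periods


def _beat_diameter(phase: np.ndarray, hp: float, dd: float, sd: float,
                   si_frac: float) -> np.ndarray:
    """Diameter at times ``phase`` (s) into a beat starting at onset."""
    ramp = _RAMP_FRAC * hp
    si = si_frac * hp
    sys_plateau_end = si - ramp
    d = np.full_like(phase, dd, dtype=np.float64)
    amp = dd - sd
    # contraction ramp: dd -> sd over [0, ramp)
    m = phase < ramp
    d[m] = sd + amp * (1 + np.cos(np.pi * phase[m] / ramp)) / 2
    # systolic plateau [ramp, si - ramp)
    m = (phase >= ramp) & (phase < sys_plateau_end)
    d[m] = sd
    # relaxation ramp: sd -> dd over [si - ramp, si)
    m = (phase >= sys_plateau_end) & (phase < si)
    u = (phase[m] - sys_plateau_end) / ramp
    d[m] = sd + amp * (1 - np.cos(np.pi * u)) / 2
    # diastolic plateau [si, hp) is the dd fill
    return d


def generate_waveform(spec: SyntheticHeartSpec):
    """Generate the per-frame diameter waveform and its true beat table.

    Returns
    -------
    waveform : (T,) float array of lumen diameters in µm
    true_beats : DataFrame with columns beat, onset_t, rel_end_t, si,
        di, dd, sd, hp (times in s, diameters in µm)

    Each beat occupies [onset, onset + hp): the systolic interval
    (si_frac x hp: ramp down, systolic plateau, ramp up) followed by the
    diastolic interval at dd_true. Time left over after the last full
    beat is filled with diastole and not listed as a beat.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    periods = _draw_heart_periods(spec, rng)
    t = np.arange(spec.n_frames) / spec.fps
    waveform = np.full(spec.n_frames, spec.dd_true, dtype=np.float64)
    rows = []
    onset = 0.0
    for k, hp in enumerate(periods):
        si = spec.si_frac * hp
        m = (t >= onset) & (t < onset + hp)
        waveform[m] = _beat_diameter(t[m] - onset, hp, spec.dd_true,
                                     spec.sd_true, spec.si_frac)
        rows.append({
            "beat": k,
            "onset_t": onset,
            "rel_end_t": onset + si,
            "si": si,
            "di": hp - si,
            "dd": spec.dd_true,
            "sd": spec.sd_true,
            "hp": hp,
        })
        onset += hp
    true_beats = pd.DataFrame(
        rows, columns=["beat", "onset_t", "rel_end_t", "si", "di", "dd", "sd", "hp"]
    )
    return waveform, true_beats


def render_frames(waveform: np.ndarray, spec: SyntheticHeartSpec):
    """Render a waveform into a grayscale clip and binary wall masks.

    Walls are two horizontal bands of ``wall_thickness`` px; the
    inner-edge gap at frame t is round(waveform[t] / pixel_size) px,
    centred vertically. Masks mark wall pixels only (lumen excluded).
    Gaussian intensity noise (sigma ``noise_sigma``) is seeded from the
    spec seed, so identical specs render bitwise-identical clips.
    """
    waveform = np.asarray(waveform, dtype=np.float64)
    if not np.all(np.isfinite(waveform)) or np.any(waveform <= 0):
        raise ParameterError("waveform must be finite and positive")
    gaps = np.rint(waveform / spec.pixel_size).astype(int)
    wall = spec.wall_thickness
    center = spec.height // 2
    r0 = center - gaps // 2  # first lumen row per frame
    if np.any(r0 - wall < 0) or np.any(r0 + gaps + wall > spec.height):
        raise GeometryError(
            f"lumen gap {gaps.max()} px + 2x{wall} px walls does not fit "
            f"height {spec.height}"
        )
    T = len(waveform)
    rows = np.arange(spec.height)[None, :]  # (1, H)
    top_lo = (r0 - wall)[:, None]
    top_hi = r0[:, None]
    bot_lo = (r0 + gaps)[:, None]
    bot_hi = (r0 + gaps + wall)[:, None]
    wall_rows = ((rows >= top_lo) & (rows < top_hi)) | \
                ((rows >= bot_lo) & (rows < bot_hi))        # (T, H)
    lumen_rows = (rows >= top_hi) & (rows < bot_lo)
    masks = np.repeat(wall_rows[:, :, None], spec.width, axis=2)
    img_col = np.full((T, spec.height), 0.15)
    img_col[wall_rows] = 0.85
    img_col[lumen_rows] = 0.35
    clip = np.repeat(img_col[:, :, None], spec.width, axis=2)
    if spec.noise_sigma > 0:
        noise_rng = np.random.default_rng([1, spec.seed % (2**31)])
        clip = clip + noise_rng.normal(0.0, spec.noise_sigma, size=clip.shape)
    clip = np.clip(clip, 0.0, 1.0).astype(np.float32)
    return clip, masks


def young_spec(**overrides) -> SyntheticHeartSpec:
    """Default 1-week-like heart: large FS, short regular heart period."""
    base = dict(dd_true=60.0, sd_true=40.0, hp_mean=0.4, hp_cv=0.05)
    base.update(overrides)
    return SyntheticHeartSpec(**base)


def old_spec(**overrides) -> SyntheticHeartSpec:
    """Default 5-week-like heart: reduced FS, longer and more variable HP."""
    base = dict(dd_true=58.0, sd_true=46.0, hp_mean=0.7, hp_cv=0.12)
    base.update(overrides)
    return SyntheticHeartSpec(**base)


def make_cohort(young: SyntheticHeartSpec, old: SyntheticHeartSpec,
                n_each: int, seed: int = 0, perturb_cv: float = 0.05,
                render: bool = True) -> list[CohortSample]:
    """Generate a labeled two-class cohort of 2 x n_each synthetic hearts.

    Per-heart dd_true, sd_true and hp_mean are perturbed around their
    cohort spec by multiplicative factors with coefficient of variation
    ``perturb_cv``, so within-cohort variance is nonzero. With
    ``render=False`` only waveforms and beat tables are produced (clips
    and masks left None), which is much faster when only cardiac
    statistics are needed.
    """
    if n_each < 1:
        raise ParameterError(f"require n_each >= 1, got {n_each}")
    young.validate()
    old.validate()
    rng = np.random.default_rng(seed)
    samples: list[CohortSample] = []
    for label, cohort in ((0, young), (1, old)):
        for _ in range(n_each):
            factors = np.maximum(1.0 + perturb_cv * rng.normal(size=3), 0.5)
            dd = cohort.dd_true * factors[0]
            sd = cohort.sd_true * factors[1]
            if sd >= dd:
                sd = 0.9 * dd
            heart = replace(
                cohort,
                dd_true=dd,
                sd_true=sd,
                hp_mean=cohort.hp_mean * factors[2],
                seed=int(rng.integers(2**31)),
            )
            waveform, beats = generate_waveform(heart)
            clip = masks = None
            if render:
                clip, masks = render_frames(waveform, heart)
            samples.append(CohortSample(heart, waveform, beats, label, clip, masks))
    return samples
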