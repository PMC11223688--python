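"""Pixel-wise motility imaging, spatial filtering and region aggregation.

A stack of B-mode magnitude frames (time-major: T x axial x lateral) is
reduced to a per-pixel motility-amplitude map by applying the scheme's
lag-ts estimator and the mean-signal estimate at every pixel.  Pixel-wise
scatter analyses use a small spatial mean filter (default 4 lateral x 2
axial pixels, roughly one resolution cell); spheroid averages are taken over
the *unfiltered* map inside segmentation masks.  A synthetic stack
generator places elliptical "spheroids" of elevated motile weight over a
stationary background to provide ground truth for end-to-end validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .schedules import Method, SamplingSchedule, full_schedule
from . import estimators


@dataclass
class ImageStack:
    """Time-resolved magnitude frames plus the schedule they were acquired on.

    ``frames`` has shape (T, axial, lateral) with T equal to the schedule's
    retained-sample count; for a compressed stack the frames are the retained
    slots in slot order.
    """

    frames: np.ndarray
    ts: float
    schedule: SamplingSchedule

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x axial x lateral, got shape {self.frames.shape}")
        if self.frames.shape[0] != self.schedule.n_samples:
            raise ValueError(
                f"{self.frames.shape[0]} frames but schedule retains {self.schedule.n_samples}"
            )
        if not np.isfinite(self.frames).all():
            raise ValueError("frames contain non-finite values")
        if not self.ts > 0:
            raise ValueError(f"frame interval ts must be > 0, got {self.ts}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class MotilityImage:
    """Per-pixel motility amplitude, mean signal and clamp/NaN bookkeeping."""

    m: np.ndarray
    mean_image: np.ndarray
    clamp_mask: np.ndarray


def restrict_stack(stack: ImageStack, schedule: SamplingSchedule) -> ImageStack:
    """Sub-sample a fully sampled stack to a schedule's retained slots."""
    if stack.schedule.method is not Method.FULL:
        raise ValueError("can only restrict a fully sampled stack")
    if schedule.n_frames != stack.schedule.n_frames:
        raise ValueError(
            f"schedule N={schedule.n_frames} inconsistent with stack N={stack.schedule.n_frames}"
        )
    return ImageStack(stack.frames[np.asarray(schedule.indices)], stack.ts, schedule)


def motility_image(stack: ImageStack) -> MotilityImage:
    """Apply the scheme's Gamma(ts) and Sbar estimators at every pixel.

    Vectorized over pixels; equivalent to running the single-series
    estimation path per pixel.  Zero-mean pixels get NaN (flagged
    not-a-value) and are excluded from downstream region statistics.
    """
    v = stack.frames
    sched = stack.schedule
    if sched.method is Method.FULL or sched.r == 1:
        gamma = np.mean(v[1:] * v[:-1], axis=0)
    elif sched.method is Method.UTS:
        gamma = np.mean(v[1:] * v[:-1], axis=0)  # decimated frames: lag r*ts products
    else:
        gamma = np.mean(v[0::2] * v[1::2], axis=0)
    mean_img = v.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        radicand = (gamma - mean_img**2) / mean_img**2
    radicand = np.where(mean_img == 0, np.nan, radicand)
    clamp = radicand < 0
    m = np.sqrt(np.where(clamp, 0.0, radicand))
    return MotilityImage(m=m, mean_image=mean_img, clamp_mask=clamp)


def mean_filter(m: np.ndarray, window_lateral: int = 4, window_axial: int = 2) -> np.ndarray:
    """Moving-window arithmetic mean of an (axial, lateral) map.

    At image borders the window shrinks to its in-bounds intersection, so a
    constant map stays exactly constant and no data are invented beyond the
    edge.  NaN pixels are treated as missing: excluded from every window,
    NaN in the output only where a window contains no finite pixel.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D (axial, lateral) map")
    if window_axial < 1 or window_lateral < 1:
        raise ValueError("window dimensions must be >= 1")
    if window_axial > m.shape[0] or window_lateral > m.shape[1]:
        raise ValueError(f"window {(window_axial, window_lateral)} exceeds image {m.shape}")
    if window_axial == 1 and window_lateral == 1:
        return m.copy()
    kernel = np.ones((window_axial, window_lateral))
    finite = np.isfinite(m)
    total = ndimage.correlate(np.where(finite, m, 0.0), kernel, mode="constant", cval=0.0)
    count = ndimage.correlate(finite.astype(float), kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = total / count
    return np.where(count > 0, out, np.nan)


def region_mean(m: np.ndarray, mask: np.ndarray) -> pd.Series:
    """Mean (unfiltered) motility amplitude per labeled region.

    ``mask`` is an integer label map (0 = background, k = region k).
    Not-a-value pixels are excluded; a region with no usable pixel is an
    error (bad mask).
    """
    m = np.asarray(m, dtype=float)
    mask = np.asarray(mask)
    if mask.shape != m.shape:
        raise ValueError(f"mask shape {mask.shape} does not match map shape {m.shape}")
    labels = np.unique(mask[mask > 0])
    if labels.size == 0:
        raise ValueError("mask contains no labeled region")
    means = {}
    for lab in labels:
        vals = m[(mask == lab) & np.isfinite(m)]
        if vals.size == 0:
            raise ValueError(f"region {lab} has no usable pixel")
        means[int(lab)] = float(vals.mean())
    return pd.Series(means, name="mean_M").rename_axis("region")


@dataclass(frozen=True)
class Spheroid:
    """Elliptical region of elevated motile weight in a synthetic scene.

    ``center`` and ``semi_axes`` are (axial, lateral) in pixels.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    cm: float


@dataclass(frozen=True)
class StackGeometry:
    """Scene layout for the synthetic stack generator."""

    shape: tuple[int, int] = (40, 40)
    spheroids: tuple[Spheroid, ...] = field(default=())


def synthesize_stack(
    geometry: StackGeometry,
    cn: float,
    p: int,
    n_frames: int,
    ts: float = 1.0,
    seed: int = 0,
) -> tuple[ImageStack, np.ndarray]:
    """Synthetic fully sampled stack with known per-region motile weights.

    Every pixel's series follows the additive three-component pixel model
    with the shared noise weight ``cn`` and its region's motile weight
    (``cm = 0`` background); pixel streams are drawn from one seeded
    generator, vectorized over the scene.  Returns the stack and the
    ground-truth label mask (1-based, in spheroid order; later spheroids
    overwrite earlier ones where they overlap).
    """
    h, w = geometry.shape
    mask = np.zeros((h, w), dtype=np.uint8)
    cm_map = np.zeros((h, w))
    ax, lat = np.ogrid[:h, :w]
    for k, s in enumerate(geometry.spheroids, start=1):
        inside = ((ax - s.center[0]) / s.semi_axes[0]) ** 2 + (
            (lat - s.center[1]) / s.semi_axes[1]
        ) ** 2 <= 1.0
        mask[inside] = k
        cm_map[inside] = s.cm

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fn = rng.standard_normal((n_frames, h, w))
    x = rng.standard_normal((n_frames + p - 1, h, w))
    # Length-p moving average along time via cumulative sums, sqrt(p)-scaled.
    cs = np.concatenate([np.zeros((1, h, w)), np.cumsum(x, axis=0)])
    fm = np.sqrt(p) / p * (cs[p:] - cs[:-p])
    frames = cn * fn + cm_map[None] * fm + 1.0
    stack = ImageStack(frames, ts=ts, schedule=full_schedule(n_frames))
    return stack, mask
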