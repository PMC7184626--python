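"""Light-sheet stack fusion and cleanup.

A macrozoom light-sheet microscope illuminates the sample with a thin sheet
whose beam waist covers only part of the field of view, so each z position
is acquired several times with the waist (focus) shifted along x and from
the left and right illumination sides. These utilities reassemble such
acquisitions: per-frame mean equalization, contrast-driven selection of the
tiling seams, column tiling, voxelwise max fusion of opposed stacks, 16-to-
8-bit conversion, and a median-based outlier (hot/dark pixel) filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "FocusShiftedSet",
    "BoundaryResult",
    "equalize_mean",
    "column_contrast",
    "select_tile_boundaries",
    "tile",
    "fuse_max",
    "to_8bit",
    "remove_outliers",
]


@dataclass
class FocusShiftedSet:
    """Ordered focus-shifted frames of one z position (same shape), with
    optional per-frame ground-truth focus column and illumination side."""

    frames: list[np.ndarray]
    focus_x: Optional[tuple[float, ...]] = None
    illumination_side: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("need >= 2 frames")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise ValueError("frames must share one shape")


@dataclass
class BoundaryResult:
    """Tiling seams between adjacent frames; ``indeterminate[i]`` is True
    when the contrast curves of pair i never cross and the midpoint fallback
    was used."""

    boundaries: list[int]
    indeterminate: list[bool]


def equalize_mean(frames: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Scale every frame to the grand mean intensity (multiplicative).

    The grand mean (mean of the frame means) is preserved; idempotent up to
    float rounding.
    """
    if len(frames) == 0:
        raise ValueError("no frames")
    means = [float(np.mean(f)) for f in frames]
    if any(m <= 0 for m in means):
        raise ValueError("frames must have positive mean intensity")
    grand = float(np.mean(means))
    return [f * (grand / m) for f, m in zip(frames, means)]


def column_contrast(frame: np.ndarray, window: int = 32,
                    smooth: int = 16) -> np.ndarray:
    """Per-column contrast: standard deviation of the pixels in a vertical
    strip of ``window`` columns centered on each column, then smoothed with
    a ``smooth``-column moving average.

    Sheet defocus suppresses high-frequency content, so the sharper frame
    has the larger strip SD.
    """
    f = np.asarray(frame, dtype=float)
    m1 = ndimage.uniform_filter1d(f.mean(axis=0), window, mode="nearest")
    m2 = ndimage.uniform_filter1d((f * f).mean(axis=0), window,
                                  mode="nearest")
    var = np.clip(m2 - m1 * m1, 0.0, None)
    sd = np.sqrt(var)
    if smooth > 1:
        sd = ndimage.uniform_filter1d(sd, smooth, mode="nearest")
    return sd


def select_tile_boundaries(fset: FocusShiftedSet, window: int = 32,
                           smooth: int = 16) -> BoundaryResult:
    """Choose one seam column between each pair of adjacent frames.

    Frames must be ordered by nominal focus position (increasing x). For a
    pair (i, i+1) the seam is the first column, searched left to right
    within (previous seam, width), where the next frame's smoothed contrast
    exceeds the current frame's. If the curves never cross the pair is
    flagged indeterminate and the midpoint between the pair's surrounding
    span is used.
    """
    w = fset.frames[0].shape[1]
    contrasts = [column_contrast(f, window, smooth) for f in fset.frames]
    boundaries: list[int] = []
    flags: list[bool] = []
    prev = 0
    n = len(fset.frames)
    for i in range(n - 1):
        diff = contrasts[i + 1] - contrasts[i]
        cross = np.nonzero(diff[prev + 1:] > 0)[0]
        if len(cross) and not np.allclose(diff, 0.0, atol=1e-9):
            b = int(cross[0] + prev + 1)
            flags.append(False)
        else:
            # equal-contrast fallback: even split of the remaining width
            b = int(round((i + 1) * w / n))
            b = max(b, prev + 1)
            flags.append(True)
        boundaries.append(min(b, w - (n - 1 - i)))
        prev = boundaries[-1]
    return BoundaryResult(boundaries=boundaries, indeterminate=flags)


def tile(fset: FocusShiftedSet, boundaries: Sequence[int]) -> np.ndarray:
    """Assemble one image: columns [0, b1) from frame 1, [b1, b2) from
    frame 2, ... Frames should be mean-equalized first."""
    w = fset.frames[0].shape[1]
    if len(boundaries) != len(fset.frames) - 1:
        raise ValueError("need exactly one boundary per adjacent frame pair")
    bs = list(boundaries)
    if any(b2 <= b1 for b1, b2 in zip(bs, bs[1:])) or any(
            not 0 < b < w for b in bs):
        raise ValueError("boundaries must be strictly increasing within "
                         "(0, width)")
    out = np.empty_like(np.asarray(fset.frames[0], dtype=float))
    edges = [0] + bs + [w]
    for frame, lo, hi in zip(fset.frames, edges[:-1], edges[1:]):
        out[:, lo:hi] = frame[:, lo:hi]
    return out


def fuse_max(stack_a: np.ndarray, stack_b: np.ndarray) -> np.ndarray:
    """Voxelwise maximum of two equally shaped stacks (opposed acquisitions)."""
    if stack_a.shape != stack_b.shape:
        raise ValueError("shape mismatch")
    return np.maximum(stack_a, stack_b)


def to_8bit(stack: np.ndarray, range_policy: str = "global_minmax",
            fixed_range: Optional[tuple[float, float]] = None) -> np.ndarray:
    """Linear 8-bit conversion: [lo, hi] -> [0, 255], clamped, rounded
    half-to-even.

    ``range_policy`` is 'global_minmax' (lo/hi from the whole stack) or
    'fixed' with an explicit (lo, hi). A constant stack under global_minmax
    yields all zeros (there is no contrast to preserve).
    """
    stack = np.asarray(stack, dtype=float)
    if range_policy == "global_minmax":
        lo, hi = float(stack.min()), float(stack.max())
        if hi <= lo:
            return np.zeros(stack.shape, dtype=np.uint8)
    elif range_policy == "fixed":
        if fixed_range is None:
            raise ValueError("fixed policy requires fixed_range")
        lo, hi = fixed_range
        if hi <= lo:
            raise ValueError("fixed range must have hi > lo")
    else:
        raise ValueError(f"unknown range_policy {range_policy!r}")
    scaled = (stack - lo) / (hi - lo) * 255.0
    return np.rint(np.clip(scaled, 0.0, 255.0)).astype(np.uint8)


def remove_outliers(img: np.ndarray, radius: float = 10.0,
                    threshold: float = 50.0, polarity: str = "bright"
                    ) -> np.ndarray:
    """Replace pixels deviating from their neighborhood median by more than
    ``threshold``.

    The neighborhood is a disk of the given radius; ``polarity`` selects
    bright outliers (pixel - median > threshold), dark ones, or both.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if polarity not in ("bright", "dark", "both"):
        raise ValueError("polarity must be bright, dark or both")
    img = np.asarray(img, dtype=float)
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    footprint = (yy * yy + xx * xx) <= radius * radius
    med = ndimage.median_filter(img, footprint=footprint, mode="reflect")
    diff = img - med
    if polarity == "bright":
        bad = diff > threshold
    elif polarity == "dark":
        bad = diff < -threshold
    else:
        bad = np.abs(diff) > threshold
    return np.where(bad, med, img)
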