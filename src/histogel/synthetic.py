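"""Seeded synthetic-data generators for every pipeline in the package.

Each generator emulates one class of raw input of a cleared-tissue 3D
staining study and records the exact ground truth used to build it, so that
every downstream quantification can be scored against a known answer:

* cylindrical-gel cross sections with a controlled radial staining profile
  (uniform / rimmed / gradual), Gaussian noise and bright outlier speckles;
* multi-channel 3D stacks of Gaussian-blob "cells" at known coordinates
  with background gradients and noise, for the detection pipelines;
* isotropic SAXS detector images (power law + optional Bragg ring + flat
  background, optional Poisson counting noise) and 1D profiles;
* series of disks with prescribed area ratios for the swelling assay;
* sets of focus-shifted light-sheet frames whose sharpness varies with the
  distance to a per-frame focus column.

All generators are bit-reproducible for a fixed seed and spec. Coordinates
are 0-based voxel indices in (z, y, x) order; a blob "center" is the
continuous Gaussian mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .stack_ops import FocusShiftedSet
from .saxs import ScatteringGeometry, detector_q_map

__all__ = [
    "GelImageSpec",
    "CellStackSpec",
    "SAXSSpec",
    "FocusSpec",
    "gen_gel_image",
    "gen_cell_stack",
    "saxs_intensity",
    "gen_saxs_pattern",
    "gen_saxs_profile",
    "gen_swelling_series",
    "gen_focus_shifted_images",
]


# --------------------------------------------------------------------------
# gel cross-section images

@dataclass(frozen=True)
class GelImageSpec:
    """A stained cylindrical-gel cross section seen as a disk in a 2D image.

    ``radial_profile_kind`` selects the noise-free staining profile as a
    function of the normalized radius rho = r / disk_radius:

    * ``uniform``: amplitude everywhere in the disk;
    * ``rimmed``: amplitude only in the outer band of width
      ``edge_band_fraction`` (stain trapped at the surface);
    * ``gradual``: amplitude * exp(-(1 - rho) / decay_length), a smooth
      near-uniform penetration profile (decay_length in fractions of the
      radius; the default 4.0 keeps the center above 78%% of the edge);
    * ``custom``: a user-supplied callable rho -> intensity.
    """

    image_size: tuple[int, int] = (420, 420)
    disk_center: tuple[float, float] = (210.0, 210.0)
    disk_radius: float = 180.0
    radial_profile_kind: str = "uniform"
    amplitude: float = 1000.0
    edge_band_fraction: float = 0.1
    decay_length: float = 4.0
    background_level: float = 50.0
    noise_sd: float = 10.0
    outlier_density: float = 0.0
    outlier_amplitude: float = 5000.0
    custom_profile: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        for name in ("image_size", "disk_center"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        cy, cx = self.disk_center
        h, w = self.image_size
        if (cy - self.disk_radius < 0 or cy + self.disk_radius >= h
                or cx - self.disk_radius < 0 or cx + self.disk_radius >= w):
            raise ValueError("disk does not fit inside the image")
        if not (0 < self.edge_band_fraction < 1):
            raise ValueError("edge_band_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.radial_profile_kind not in ("uniform", "rimmed", "gradual",
                                            "custom"):
            raise ValueError(f"unknown kind {self.radial_profile_kind!r}")
        if self.radial_profile_kind == "custom" and self.custom_profile is None:
            raise ValueError("custom kind requires custom_profile")

    def radial_function(self) -> Callable[[np.ndarray], np.ndarray]:
        """The noise-free staining intensity as a function of rho in [0, 1]."""
        a = self.amplitude
        if self.radial_profile_kind == "uniform":
            return lambda rho: np.full_like(np.asarray(rho, float), a)
        if self.radial_profile_kind == "rimmed":
            edge = 1.0 - self.edge_band_fraction
            return lambda rho: np.where(np.asarray(rho) >= edge, a, 0.0)
        if self.radial_profile_kind == "gradual":
            lam = self.decay_length
            return lambda rho: a * np.exp(-(1.0 - np.asarray(rho)) / lam)
        return self.custom_profile


def _render_gel(spec: GelImageSpec) -> np.ndarray:
    h, w = spec.image_size
    cy, cx = spec.disk_center
    yy, xx = np.indices((h, w))
    rho = np.hypot(yy - cy, xx - cx) / spec.disk_radius
    img = np.full((h, w), spec.background_level, dtype=float)
    inside = rho <= 1.0
    img[inside] += spec.radial_function()(rho[inside])
    return img


def gen_gel_image(spec: GelImageSpec, seed: int
                  ) -> tuple[np.ndarray, Callable[[np.ndarray], np.ndarray]]:
    """Render a gel cross section; returns (image, generating radial function).

    The radial function is the noise-free in-disk intensity (above
    background) used to build the image, for oracle comparisons.
    """
    rng = np.random.default_rng(seed)
    img = _render_gel(spec)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    if spec.outlier_density > 0:
        n = int(round(spec.outlier_density * img.size))
        idx = rng.choice(img.size, size=n, replace=False)
        img.ravel()[idx] += spec.outlier_amplitude
    return np.clip(img, 0.0, None), spec.radial_function()


# --------------------------------------------------------------------------
# 3D cell stacks

@dataclass(frozen=True)
class CellStackSpec:
    """Multi-channel 3D stack of Gaussian-blob cells at known coordinates.

    ``n_cells_per_channel`` maps channel label -> count. Cells of one
    channel are placed by rejection sampling at pairwise distance
    >= ``min_separation`` (within-channel); ``colabel_fractions`` maps an
    ordered channel pair (a, b) to the fraction of b's cells that reuse a's
    coordinates (colabeled cells). Background is a constant plus a linear
    gradient per axis; noise is Gaussian (sd) or Poisson (on the noise-free
    intensity).
    """

    stack_shape: tuple[int, int, int] = (48, 96, 96)
    n_cells_per_channel: dict = field(
        default_factory=lambda: {"ch0": 50})
    min_separation: float = 10.0
    blob_sigma: float = 1.2
    amplitude_range: tuple[float, float] = (500.0, 1000.0)
    colabel_fractions: dict = field(default_factory=dict)
    background: float = 100.0
    background_gradient: tuple[float, float, float] = (0.0, 0.2, 0.2)
    noise_model: str = "gaussian"
    noise_param: float = 10.0
    edge_margin: float = 6.0
    attempt_budget_per_cell: int = 1000

    def __post_init__(self) -> None:
        for name in ("stack_shape", "amplitude_range",
                     "background_gradient"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        object.__setattr__(self, "colabel_fractions",
                           {tuple(k): v
                            for k, v in self.colabel_fractions.items()})
        if self.min_separation <= 0:
            raise ValueError("min_separation must be > 0")
        for pair, f in self.colabel_fractions.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"colabel fraction for {pair} outside [0, 1]")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")
        if min(self.stack_shape) <= 2 * self.edge_margin:
            raise ValueError("stack too small for the edge margin")


def _place_cells(rng: np.random.Generator, spec: CellStackSpec, n: int
                 ) -> np.ndarray:
    lo = np.full(3, spec.edge_margin)
    hi = np.asarray(spec.stack_shape, float) - 1 - spec.edge_margin
    placed: list[np.ndarray] = []
    budget = spec.attempt_budget_per_cell * max(n, 1)
    attempts = 0
    while len(placed) < n:
        if attempts >= budget:
            vol = np.prod(hi - lo)
            density = n / vol
            raise RuntimeError(
                f"placed only {len(placed)}/{n} cells at separation "
                f"{spec.min_separation} within {budget} attempts; requested "
                f"density {density:.2e} cells/voxel is too high for this "
                "stack, reduce n or min_separation")
        attempts += 1
        cand = rng.uniform(lo, hi)
        if all(np.linalg.norm(cand - p) >= spec.min_separation
               for p in placed):
            placed.append(cand)
    return np.asarray(placed).reshape(n, 3)


def gen_cell_stack(spec: CellStackSpec, seed: int
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a (channel, z, y, x) stack and its ground-truth table.

    The table has columns ``cell_id, channel, z, y, x`` (continuous voxel
    coordinates of the Gaussian means) plus ``amplitude``.
    """
    rng = np.random.default_rng(seed)
    channels = list(spec.n_cells_per_channel)
    coords: dict[str, np.ndarray] = {}
    for ch in channels:
        n = spec.n_cells_per_channel[ch]
        shared: list[np.ndarray] = []
        for (a, b), f in spec.colabel_fractions.items():
            if b == ch and a in coords:
                k = int(round(f * n))
                if k > len(coords[a]):
                    raise ValueError(
                        f"channel {a!r} has too few cells to colabel {k}")
                shared.append(coords[a][:k])
        shared_arr = (np.concatenate(shared) if shared
                      else np.empty((0, 3)))
        fresh = _place_cells(rng, spec, n - len(shared_arr))
        coords[ch] = (np.concatenate([shared_arr, fresh])
                      if len(shared_arr) else fresh)

    zz, yy, xx = np.indices(spec.stack_shape)
    gz, gy, gx = spec.background_gradient
    base = spec.background + gz * zz + gy * yy + gx * xx
    stack = np.empty((len(channels),) + spec.stack_shape, dtype=float)
    rows = []
    cell_id = 0
    sig = spec.blob_sigma
    reach = int(np.ceil(4 * sig))
    for ci, ch in enumerate(channels):
        img = base.copy()
        amps = rng.uniform(*spec.amplitude_range, size=len(coords[ch]))
        for (cz, cy, cx), amp in zip(coords[ch], amps):
            sl = tuple(slice(max(int(c) - reach, 0),
                             min(int(c) + reach + 1, s))
                       for c, s in zip((cz, cy, cx), spec.stack_shape))
            lz, ly, lx = np.meshgrid(*(np.arange(s.start, s.stop)
                                       for s in sl), indexing="ij")
            d2 = (lz - cz) ** 2 + (ly - cy) ** 2 + (lx - cx) ** 2
            img[sl] += amp * np.exp(-d2 / (2.0 * sig * sig))
            rows.append({"cell_id": cell_id, "channel": ch,
                         "z": cz, "y": cy, "x": cx, "amplitude": amp})
            cell_id += 1
        if spec.noise_model == "gaussian" and spec.noise_param > 0:
            img += rng.normal(0.0, spec.noise_param, img.shape)
        elif spec.noise_model == "poisson":
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        stack[ci] = np.clip(img, 0.0, None)
    truth = pd.DataFrame(rows, columns=["cell_id", "channel", "z", "y", "x",
                                        "amplitude"])
    return stack, truth


# --------------------------------------------------------------------------
# SAXS patterns

@dataclass(frozen=True)
class SAXSSpec:
    """Isotropic scattering pattern: power law I = amplitude * q^-D, an
    optional Gaussian Bragg ring (q0, width, height in 1/A, 1/A, counts),
    and a flat background. Poisson applies counting noise."""

    amplitude: float = 1.0
    fractal_exponent: float = 2.0
    bragg_peak: Optional[tuple[float, float, float]] = None
    flat_background: float = 0.0
    poisson: bool = False

    def __post_init__(self) -> None:
        if self.fractal_exponent <= 0:
            raise ValueError("fractal_exponent must be > 0")
        if self.bragg_peak is not None:
            q0, width, height = self.bragg_peak
            if q0 <= 0 or width <= 0 or height < 0:
                raise ValueError("invalid bragg_peak parameters")


def saxs_intensity(spec: SAXSSpec, q: np.ndarray) -> np.ndarray:
    """Noise-free model intensity I(q) for q > 0."""
    q = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore"):
        I = spec.amplitude * np.power(q, -spec.fractal_exponent)
    if spec.bragg_peak is not None:
        q0, width, height = spec.bragg_peak
        I = I + height * np.exp(-0.5 * ((q - q0) / width) ** 2)
    return I + spec.flat_background


def gen_saxs_pattern(spec: SAXSSpec, geometry: ScatteringGeometry, seed: int,
                     shape: tuple[int, int] = (256, 256),
                     beamstop_px: float = 3.0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Render an isotropic detector image; returns (image, beamstop mask).

    Intensity at each pixel is I(q(pixel)) of the spec; the mask (True =
    excluded) covers the beamstop region around the direct beam, where the
    power law diverges. With ``spec.poisson`` each pixel is Poisson-drawn
    with the model value as its mean.
    """
    if spec.bragg_peak is not None:
        qmax = detector_q_map(shape, geometry).max()
        if not (0 < spec.bragg_peak[0] < qmax):
            raise ValueError("bragg q0 outside the detector's q range")
    qmap = detector_q_map(shape, geometry)
    cy, cx = geometry.beam_center
    yy, xx = np.indices(shape)
    mask = np.hypot(yy - cy, xx - cx) <= beamstop_px
    img = np.where(mask, 0.0, saxs_intensity(spec, np.where(mask, 1.0, qmap)))
    if spec.poisson:
        rng = np.random.default_rng(seed)
        img = rng.poisson(img).astype(float)
    return img, mask


def gen_saxs_profile(spec: SAXSSpec, q: np.ndarray,
                     noise_fraction: float = 0.0, seed: int = 0
                     ) -> np.ndarray:
    """1D profile I(q) with multiplicative lognormal noise of the given
    relative magnitude (0.01 = 1%%)."""
    I = saxs_intensity(spec, q)
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_fraction ** 2))
        I = I * rng.lognormal(-0.5 * sigma ** 2, sigma, size=I.shape)
    return I


# --------------------------------------------------------------------------
# swelling series

def gen_swelling_series(area_ratios: list[float], base_radius: float,
                        spec: GelImageSpec, seed: int = 0
                        ) -> list[np.ndarray]:
    """Uniform disks whose areas are prescribed multiples of the base area.

    Disk i has area ratio_i * pi * base_radius^2 (radius scales with the
    square root of the ratio). Rendering parameters (amplitude, background,
    noise) come from ``spec``; its own radius and profile kind are ignored.
    """
    out = []
    for i, ratio in enumerate(area_ratios):
        if ratio <= 0:
            raise ValueError("area ratios must be > 0")
        r = base_radius * np.sqrt(ratio)
        disk_spec = GelImageSpec(
            image_size=spec.image_size, disk_center=spec.disk_center,
            disk_radius=r, radial_profile_kind="uniform",
            amplitude=spec.amplitude, background_level=spec.background_level,
            noise_sd=spec.noise_sd)
        img, _ = gen_gel_image(disk_spec, seed + i)
        out.append(img)
    return out


# --------------------------------------------------------------------------
# focus-shifted light-sheet frames

@dataclass(frozen=True)
class FocusSpec:
    """Frames sharing latent content, blurred with sigma growing linearly
    with the column distance to each frame's focus position.

    ``focus_fractions`` are focus-column positions as fractions of the image
    width; ``base_sigma`` is the blur at the focus, ``defocus_slope`` the
    added sigma per pixel of distance. ``dot_density`` controls the latent
    high-frequency content the contrast metric feeds on.
    """

    shape: tuple[int, int] = (128, 256)
    focus_fractions: tuple[float, ...] = (0.25, 0.75)
    base_sigma: float = 0.5
    defocus_slope: float = 0.04
    dot_density: float = 0.02
    dot_amplitude: float = 1000.0
    background: float = 100.0
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("shape", "focus_fractions"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        if len(self.focus_fractions) < 2:
            raise ValueError("need >= 2 focus positions")
        if any(not 0 <= f <= 1 for f in self.focus_fractions):
            raise ValueError("focus fractions must be in [0, 1]")


def _variable_blur_x(img: np.ndarray, sigma_per_col: np.ndarray,
                     n_levels: int = 8) -> np.ndarray:
    """Approximate column-dependent Gaussian blur by interpolating between
    uniformly blurred copies at discrete sigma levels."""
    lo, hi = float(sigma_per_col.min()), float(sigma_per_col.max())
    if hi - lo < 1e-9:
        return ndimage.gaussian_filter(img, lo) if lo > 0 else img.copy()
    levels = np.linspace(lo, hi, n_levels)
    blurred = np.stack([ndimage.gaussian_filter(img, s) if s > 0 else img
                        for s in levels])
    pos = (sigma_per_col - lo) / (hi - lo) * (n_levels - 1)
    i0 = np.clip(pos.astype(int), 0, n_levels - 2)
    w = pos - i0
    cols = np.arange(img.shape[1])
    return (blurred[i0, :, cols] * (1 - w[:, None])
            + blurred[i0 + 1, :, cols] * w[:, None]).T


def gen_focus_shifted_images(spec: FocusSpec, seed: int) -> FocusShiftedSet:
    """Generate a set of focus-shifted frames with recorded focus columns."""
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    latent = np.full((h, w), spec.background, dtype=float)
    n_dots = int(round(spec.dot_density * h * w))
    idx = rng.choice(h * w, size=n_dots, replace=False)
    latent.ravel()[idx] += spec.dot_amplitude
    frames = []
    focus_x = []
    cols = np.arange(w, dtype=float)
    for frac in spec.focus_fractions:
        fx = frac * (w - 1)
        sigma = spec.base_sigma + spec.defocus_slope * np.abs(cols - fx)
        frame = _variable_blur_x(latent, sigma)
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, frame.shape)
        frames.append(np.clip(frame, 0.0, None))
        focus_x.append(fx)
    sides = tuple("left" if i % 2 == 0 else "right"
                  for i in range(len(frames)))
    return FocusShiftedSet(frames=frames, focus_x=tuple(focus_x),
                           illumination_side=sides)
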