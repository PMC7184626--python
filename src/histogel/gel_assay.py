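"""Quantification of staining penetration and swelling in gel cross sections.

The surrogate assay: a cylinder of fixed gelatin gel is stained, cryo-
sectioned through the middle, and imaged; the radial distribution of the
staining signal across the disk-shaped section tells whether the stain
penetrated ("gradual") or was trapped at the surface ("rimmed"). This
module reproduces that quantification: outlier removal, background
subtraction, cropping/rescaling of the gel to a standard 1500-px width,
intensity profiles along six diameters (1500 x 30 px bands), and the same
rimmed/gradual classification used for the reaction-diffusion simulation.

The swelling-shrinkage assay measures the disk area S of a gel under a
series of solvents relative to the mean reference area S0; an isotropic
area change by a factor a corresponds to a volume change by a^(3/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure, transform

from .stack_ops import remove_outliers
from .stain_sim import PatternClass, RadialProfile, classify_pattern

__all__ = [
    "GelSectionImage",
    "DiameterProfileSet",
    "AreaMeasurement",
    "preprocess_section",
    "diameter_profiles",
    "classify_section",
    "measure_area",
    "swelling_ratio",
    "area_to_volume_factor",
]

#: diameter orientations (degrees); six diameters at uniform angular coverage
DIAMETER_ANGLES_DEG = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)


@dataclass
class GelSectionImage:
    """A 2D gel-section image with optional acquisition metadata."""

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size_um: Optional[float] = None


@dataclass
class DiameterProfileSet:
    """Intensity profiles along the gel diameters: one row per diameter
    (averaged across a 30-px band), plus their mean and SD."""

    profiles: np.ndarray
    mean_profile: np.ndarray
    sd_profile: np.ndarray
    angles_deg: tuple[float, ...]


@dataclass
class AreaMeasurement:
    """Gel area S (px^2) relative to a reference area S0."""

    S: float
    S0: float

    @property
    def ratio(self) -> float:
        return self.S / self.S0


def _pixels(img) -> np.ndarray:
    return np.asarray(img.pixels if isinstance(img, GelSectionImage) else img,
                      dtype=float)


def _threshold(img: np.ndarray, method: str) -> np.ndarray:
    if method == "otsu":
        t = filters.threshold_otsu(img)
    elif method == "yen":
        t = filters.threshold_yen(img)
    elif method == "mean":
        t = filters.threshold_mean(img)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return img > t


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = measure.label(mask)
    if labels.max() == 0:
        raise ValueError("no foreground object found")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def preprocess_section(img, outlier_radius: float = 10.0,
                       outlier_threshold: float = 50.0,
                       background_level: float = 0.0,
                       target_width: int = 1500,
                       threshold_method: str = "otsu") -> np.ndarray:
    """Standardize a gel-section image for diameter profiling.

    Bright outlier speckles are replaced by their neighborhood median, the
    (scalar) background level measured on a nonstained gel is subtracted
    with clamping at zero, the image is cropped to the bounding box of the
    largest thresholded object (the gel disk), and rescaled so that the gel
    width equals ``target_width`` pixels with the aspect ratio preserved.
    """
    if background_level < 0:
        raise ValueError("background_level must be >= 0")
    px = remove_outliers(_pixels(img), outlier_radius, outlier_threshold,
                         polarity="bright")
    px = np.clip(px - background_level, 0.0, None)
    mask = _largest_component(_threshold(px, threshold_method))
    ys, xs = np.nonzero(mask)
    crop = px[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    scale = target_width / crop.shape[1]
    out_shape = (max(int(round(crop.shape[0] * scale)), 1), target_width)
    return transform.resize(crop, out_shape, order=1, mode="edge",
                            anti_aliasing=scale < 1, preserve_range=True)


def diameter_profiles(img, band_width: int = 30,
                      angles_deg: Sequence[float] = DIAMETER_ANGLES_DEG,
                      threshold_method: str = "otsu") -> DiameterProfileSet:
    """Mean intensity along each gel diameter, averaged across a band.

    Expects a preprocessed image whose gel width equals the image width
    (1500 px in the standard pipeline). Each profile samples a band of
    ``band_width`` px perpendicular to the diameter with bilinear
    interpolation, centered on the centroid of the thresholded disk; bands
    are averaged across their width to one profile per diameter.
    """
    px = _pixels(img)
    length = px.shape[1]
    mask = _largest_component(_threshold(px, threshold_method))
    cy, cx = ndimage.center_of_mass(mask)
    half = length / 2.0
    t = np.linspace(-half + 0.5, half - 0.5, length)
    offsets = np.arange(band_width) - (band_width - 1) / 2.0
    profiles = np.empty((len(angles_deg), length))
    for k, ang in enumerate(angles_deg):
        a = np.radians(ang)
        uy, ux = np.sin(a), np.cos(a)       # along the diameter
        vy, vx = ux, -uy                    # across the band
        yy = cy + t[None, :] * uy + offsets[:, None] * vy
        xx = cx + t[None, :] * ux + offsets[:, None] * vx
        if (yy.min() < -0.5 or xx.min() < -0.5
                or yy.max() > px.shape[0] - 0.5 or xx.max() > length - 0.5):
            raise ValueError(
                f"diameter band at {ang} deg exits the image; "
                "preprocess with the gel centered and sized to the width")
        band = ndimage.map_coordinates(px, [yy, xx], order=1, mode="nearest")
        profiles[k] = band.mean(axis=0)
    return DiameterProfileSet(profiles=profiles,
                              mean_profile=profiles.mean(axis=0),
                              sd_profile=profiles.std(axis=0, ddof=0),
                              angles_deg=tuple(angles_deg))


def classify_section(profiles: DiameterProfileSet,
                     thresholds: tuple[float, float] = (0.25, 0.75),
                     n_bins: int = 50) -> PatternClass:
    """Apply the rimmed/gradual criteria to a measured diameter profile.

    The mean diameter profile is folded at the gel center (the two half-
    profiles averaged) into a radial profile, which is binned and passed to
    the simulation-based classifier (center/edge [ST] ratio thresholds).
    """
    p = profiles.mean_profile
    half = len(p) // 2
    radial = 0.5 * (p[:half][::-1] + p[half:2 * half])
    rho = (np.arange(half) + 0.5) / half
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(rho, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    if (counts == 0).any():
        raise ValueError("radial bins empty; profile too short for n_bins")
    means = np.bincount(idx, weights=radial, minlength=n_bins) / counts
    prof = RadialProfile(radii=0.5 * (edges[:-1] + edges[1:]),
                         mean_ST=means, n_bins=n_bins)
    return classify_pattern(prof, thresholds)


def measure_area(img, threshold_method: str = "otsu") -> float:
    """Area (px^2) of the largest connected object after auto thresholding."""
    px = _pixels(img)
    return float(_largest_component(_threshold(px, threshold_method)).sum())


def swelling_ratio(series: Sequence[float],
                   reference: Sequence[float]) -> list[float]:
    """S/S0 per measurement: each area divided by the mean reference area."""
    if len(reference) == 0:
        raise ValueError("reference areas required")
    if any(a <= 0 for a in series) or any(a <= 0 for a in reference):
        raise ValueError("areas must be > 0")
    s0 = float(np.mean(reference))
    return [float(a) / s0 for a in series]


def area_to_volume_factor(area_factor: float) -> float:
    """Volume change factor for an isotropic deformation with the given
    area change factor: a^(3/2) (a fourfold area change is eightfold in
    volume)."""
    if area_factor <= 0:
        raise ValueError("area factor must be > 0")
    return float(area_factor) ** 1.5
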