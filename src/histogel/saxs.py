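"""Small-angle X-ray scattering (SAXS) reduction and structural readouts.

Converts 2D detector images to 1D I(q) profiles by azimuthal (circular or
sector) averaging around the beam center, and extracts the two structural
quantities used to characterize delipidated tissue as a heterogeneous gel:

* Bragg d-spacing, d = 2*pi/q, for discrete scattering peaks (e.g. the
  myelin phospholipid repeat near q ~ 0.08 1/A, d ~ 8 nm);
* the mass-fractal exponent D of the power law I ~ q^-D, obtained by a
  least-squares line fit in log10-log10 coordinates.

q convention: for a pixel at radial distance r (mm) from the beam center,
the full scattering angle is theta = arctan(r / L) and
q = (4*pi/lambda) * sin(theta / 2), the standard SAXS convention consistent
with Bragg's law d = 2*pi/q. In the small-angle limit q ~ 2*pi*r/(lambda*L).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "ScatteringGeometry",
    "ScatteringProfile",
    "PowerLawFit",
    "pixel_to_q",
    "q_to_pixel_radius",
    "detector_q_map",
    "circular_average",
    "sector_average",
    "subtract_background",
    "bragg_spacing",
    "fit_power_law",
]


@dataclass(frozen=True)
class ScatteringGeometry:
    """Detector geometry: sample-detector distance L (mm), wavelength (A),
    square pixel size (mm) and beam center in pixel coordinates (y, x)."""

    L_mm: float
    wavelength_A: float
    pixel_size_mm: float
    beam_center: tuple[float, float]

    def __post_init__(self) -> None:
        if self.L_mm <= 0 or self.wavelength_A <= 0 or self.pixel_size_mm <= 0:
            raise ValueError("L, wavelength and pixel size must be positive")


@dataclass
class ScatteringProfile:
    """1D scattering profile: q bin centers (1/A, increasing) and mean
    intensity per bin. Empty bins hold NaN. n_pixels counts contributing
    detector pixels per bin."""

    q: np.ndarray
    I: np.ndarray
    n_pixels: np.ndarray
    mode: str = "circular"
    sector_phi_deg: Optional[float] = None
    sector_width_deg: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.q) != len(self.I):
            raise ValueError("q and I must have the same length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")


@dataclass
class PowerLawFit:
    """Result of a log-log power-law fit I ~ q^-D over a q window."""

    D: float
    log_amplitude: float
    q_window: tuple[float, float]
    r_squared: float
    n_points: int
    n_excluded_nonpositive: int


def pixel_to_q(geometry: ScatteringGeometry, r_mm: float | np.ndarray
               ) -> float | np.ndarray:
    """Map radial detector distance (mm) to scattering-vector magnitude (1/A)."""
    r = np.asarray(r_mm, dtype=float)
    if np.any(r < 0):
        raise ValueError("detector radius must be >= 0")
    theta = np.arctan2(r, geometry.L_mm)
    q = (4.0 * np.pi / geometry.wavelength_A) * np.sin(theta / 2.0)
    return float(q) if np.isscalar(r_mm) else q


def q_to_pixel_radius(geometry: ScatteringGeometry, q: float) -> float:
    """Inverse of :func:`pixel_to_q`: detector radius (mm) for a given q."""
    s = q * geometry.wavelength_A / (4.0 * np.pi)
    if not 0 <= s < np.sin(np.pi / 4):
        raise ValueError("q outside the representable range of this geometry")
    theta = 2.0 * np.arcsin(s)
    return geometry.L_mm * np.tan(theta)


def detector_q_map(shape: tuple[int, int], geometry: ScatteringGeometry
                   ) -> np.ndarray:
    """q (1/A) at each pixel center of a detector image."""
    cy, cx = geometry.beam_center
    yy, xx = np.indices(shape)
    r = np.hypot(yy - cy, xx - cx) * geometry.pixel_size_mm
    return pixel_to_q(geometry, r)


def _azimuth_map(shape: tuple[int, int], geometry: ScatteringGeometry
                 ) -> np.ndarray:
    cy, cx = geometry.beam_center
    yy, xx = np.indices(shape)
    return np.degrees(np.arctan2(yy - cy, xx - cx))


def _binned_mean(q: np.ndarray, vals: np.ndarray, q_bins: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sums, edges, _ = stats.binned_statistic(q, vals, statistic="sum",
                                            bins=q_bins)
    counts, _, _ = stats.binned_statistic(q, np.ones_like(vals),
                                          statistic="sum", bins=q_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, mean, counts.astype(int)


def circular_average(img: np.ndarray, geometry: ScatteringGeometry,
                     q_bins: int | np.ndarray = 200,
                     mask: Optional[np.ndarray] = None) -> ScatteringProfile:
    """Azimuthally average a detector image around the beam center.

    ``q_bins`` is either a bin count (linear bins spanning the detector's q
    range) or an explicit array of bin edges. Masked (True) pixels are
    excluded; bins that end up with no pixels are flagged as NaN.
    """
    img = np.asarray(img, dtype=float)
    cy, cx = geometry.beam_center
    if not (0 <= cy < img.shape[0] and 0 <= cx < img.shape[1]):
        raise ValueError("beam center must lie inside the image")
    qmap = detector_q_map(img.shape, geometry)
    keep = np.isfinite(img)
    if mask is not None:
        keep &= ~np.asarray(mask, dtype=bool)
    if np.isscalar(q_bins):
        q_bins = np.linspace(0.0, qmap[keep].max(), int(q_bins) + 1)
    centers, mean, counts = _binned_mean(qmap[keep].ravel(),
                                         img[keep].ravel(), q_bins)
    return ScatteringProfile(q=centers, I=mean, n_pixels=counts)


def sector_average(img: np.ndarray, geometry: ScatteringGeometry,
                   phi_deg: float, width_deg: float,
                   q_bins: int | np.ndarray = 200,
                   mask: Optional[np.ndarray] = None,
                   mirror: bool = True) -> ScatteringProfile:
    """Average over an azimuthal sector [phi - w/2, phi + w/2] only.

    With ``mirror`` (default) the point-symmetric sector at phi + 180 deg is
    included as well (Friedel symmetry doubles the statistics). A width of
    360 degrees reduces to :func:`circular_average`.
    """
    if not (0 < width_deg <= 360):
        raise ValueError("sector width must be in (0, 360] degrees")
    img = np.asarray(img, dtype=float)
    az = _azimuth_map(img.shape, geometry)
    half = width_deg / 2.0

    def in_sector(center: float) -> np.ndarray:
        d = (az - center + 180.0) % 360.0 - 180.0
        return np.abs(d) <= half

    sel = in_sector(phi_deg)
    if mirror:
        sel |= in_sector(phi_deg + 180.0)
    keep = sel & np.isfinite(img)
    if mask is not None:
        keep &= ~np.asarray(mask, dtype=bool)
    qmap = detector_q_map(img.shape, geometry)
    if np.isscalar(q_bins):
        q_bins = np.linspace(0.0, qmap[keep].max(), int(q_bins) + 1)
    centers, mean, counts = _binned_mean(qmap[keep].ravel(),
                                         img[keep].ravel(), q_bins)
    return ScatteringProfile(q=centers, I=mean, n_pixels=counts,
                             mode="sector", sector_phi_deg=phi_deg,
                             sector_width_deg=width_deg)


def subtract_background(sample: ScatteringProfile,
                        background: ScatteringProfile,
                        scale: float = 1.0) -> tuple[ScatteringProfile, int]:
    """Subtract a scaled background profile, clamping at zero.

    Both profiles must share an identical q grid (interpolate beforehand if
    not). Returns the corrected profile and the number of clamped bins.
    """
    if len(sample.q) != len(background.q) or not np.allclose(
            sample.q, background.q, rtol=0, atol=1e-12):
        raise ValueError("sample and background q grids differ")
    diff = sample.I - scale * background.I
    clamped = int(np.sum(diff < 0))
    out = ScatteringProfile(q=sample.q.copy(), I=np.clip(diff, 0.0, None),
                            n_pixels=sample.n_pixels.copy(), mode=sample.mode,
                            sector_phi_deg=sample.sector_phi_deg,
                            sector_width_deg=sample.sector_width_deg)
    return out, clamped


def bragg_spacing(q_invA: float) -> float:
    """Real-space repeat distance d = 2*pi/q, returned in nm (q in 1/A)."""
    if q_invA <= 0:
        raise ValueError("q must be > 0")
    return 2.0 * np.pi / q_invA / 10.0


def fit_power_law(profile: ScatteringProfile,
                  q_window: tuple[float, float]) -> PowerLawFit:
    """Fit log10 I = log_amplitude - D * log10 q over a q window.

    Non-positive or NaN intensities inside the window are excluded (their
    count is reported); at least 5 usable points are required.
    """
    q_min, q_max = q_window
    if not (0 < q_min < q_max):
        raise ValueError("require 0 < q_min < q_max")
    in_win = (profile.q >= q_min) & (profile.q <= q_max)
    q = profile.q[in_win]
    I = profile.I[in_win]
    usable = np.isfinite(I) & (I > 0)
    n_excl = int(in_win.sum() - usable.sum())
    if usable.sum() < 5:
        raise ValueError(
            f"only {int(usable.sum())} positive points in window; need >= 5")
    lx = np.log10(q[usable])
    ly = np.log10(I[usable])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid ** 2) / ss_tot) if ss_tot > 0 else 1.0
    return PowerLawFit(D=float(-slope), log_amplitude=float(intercept),
                       q_window=(q_min, q_max), r_squared=r2,
                       n_points=int(usable.sum()),
                       n_excluded_nonpositive=n_excl)
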