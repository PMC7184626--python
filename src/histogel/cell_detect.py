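"""Labeled-cell detection in light-sheet stacks and its evaluation.

Two detection pipelines are provided, mirroring the two labeling regimes of
whole-brain staining data:

* ``detect_centroids_rv`` — for sparse, bright, cytoplasmic labels (e.g.
  rabies-virus GFP): per-slice 2D maxima of a Laplacian-of-Gaussian
  response on a 3x upscaled stack, maxima dilated and grouped into 3D
  components whose size-filtered centroids are the detections.
* ``detect_maxima_cfos`` — for dense nuclear labels (e.g. c-Fos): direct 3D
  local maxima with a prominence (noise-tolerance) criterion on a 3x
  upscaled, minimum-filtered and Gaussian-smoothed stack, computed on a
  partitioned grid of substacks with margins so arbitrarily large volumes
  stream through fixed memory.

Both report centroids in original (pre-expansion) voxel units, axis order
(z, y, x), 0-based. Detection quality against ground-truth coordinates is
scored as sensitivity (matched / ground truth) and positive predictive
value (matched / detected) under greedy one-to-one nearest matching within
a radius.

"Find Maxima" semantics: a retained maximum is a strict local maximum whose
value exceeds the highest saddle connecting it to any higher maximum by
more than the noise tolerance (the prominence / flood-fill contract of the
original ImageJ tool), emitting one pixel per maximum with ties broken in
lexicographic (z, y, x) order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import reconstruction

__all__ = [
    "CFOS_KERNEL",
    "DetectionParams",
    "CentroidSet",
    "EvaluationResult",
    "find_maxima_2d",
    "find_maxima_3d",
    "detect_centroids_rv",
    "detect_maxima_cfos",
    "enhance_cfos",
    "render_centroids",
    "evaluate",
    "evaluate_counts",
]

#: 5x5 unsharp-style convolution kernel used to enhance punctate nuclear
#: signals for display; entries sum to -1.
CFOS_KERNEL = np.array([
    [-1, -1, -1, -1, -1],
    [-1, -1,  3, -1, -1],
    [-1,  3,  7,  3, -1],
    [-1, -1,  3, -1, -1],
    [-1, -1, -1, -1, -1],
], dtype=float)


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the detection pipelines.

    ``threshold`` (the post-filter intensity cut separating signal from
    background) and, for the rv variant, ``maxima_noise_tolerance`` are
    data-dependent and must be supplied per channel; the remaining defaults
    follow the standard pipeline settings.
    """

    variant: str = "rv_centroid"
    threshold: Optional[float] = None
    use_gaussian_division: bool = False
    division_sigma: float = 1.0
    rolling_background_radius: int = 1
    expansion_factor: int = 3
    gaussian_sigma: float = 2.0           # 1.0 for the cfos variant
    laplacian_sigma: float = 2.0          # rv only
    use_min_filter: bool = True
    min_filter_radius: float = 1.5        # 1.0 for the cfos variant
    maxima_noise_tolerance: float = 1.0
    maxima_radius: float = 2.5            # cfos only
    dilation_radius: int = 2              # rv: grow 1-px maxima to 5-px width
    size_filter: tuple[int, int] = (6, 76)
    partition_grid: tuple[int, int] = (10, 10)   # cfos x-y partitioning
    partition_margin: int = 10
    z_chunk: int = 120
    z_margin: int = 5

    def __post_init__(self) -> None:
        if self.variant not in ("rv_centroid", "cfos_maxima"):
            raise ValueError("variant must be 'rv_centroid' or 'cfos_maxima'")
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")
        if self.size_filter[0] > self.size_filter[1]:
            raise ValueError("size_filter min must be <= max")
        if self.partition_margin < 0 or self.z_margin < 0:
            raise ValueError("margins must be >= 0")


@dataclass
class CentroidSet:
    """Detected cell coordinates (original voxel units, z/y/x columns) with
    the parameter snapshot that produced them."""

    records: pd.DataFrame
    params_used: DetectionParams

    def coordinates(self) -> np.ndarray:
        return self.records[["z", "y", "x"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class EvaluationResult:
    """Detection-quality scores. ``ppv`` is NaN when nothing was detected."""

    n_ground_truth: int
    n_detected: int
    n_matched: int
    match_radius: float

    @property
    def sensitivity(self) -> float:
        return self.n_matched / self.n_ground_truth

    @property
    def ppv(self) -> float:
        return (self.n_matched / self.n_detected if self.n_detected > 0
                else float("nan"))


# --------------------------------------------------------------------------
# maxima detection primitives

def _prominent_regions(img: np.ndarray, tolerance: float) -> np.ndarray:
    """Boolean mask of maxima plateaus with prominence strictly above
    ``tolerance`` (grayscale-reconstruction residue test)."""
    eps = 1e-9 * max(float(img.max()), 1.0)
    rec = reconstruction(img - (tolerance + eps), img, method="dilation")
    return (img - rec) > tolerance


def _one_pixel_per_region(img: np.ndarray, regions: np.ndarray
                          ) -> np.ndarray:
    """One pixel per labeled region: the maximum, ties broken by smallest
    (z, y, x) in lexicographic (raster) order."""
    labels, n = ndimage.label(regions)
    if n == 0:
        return np.empty((0, img.ndim), dtype=int)
    maxima = ndimage.maximum(img, labels, np.arange(1, n + 1))
    pos = []
    for lab, mx in enumerate(np.atleast_1d(maxima), start=1):
        flat = np.flatnonzero((labels == lab) & (img == mx))[0]
        pos.append(np.unravel_index(flat, img.shape))
    return np.asarray(pos, dtype=int).reshape(n, img.ndim)


def _prominent_points(img: np.ndarray, tolerance: float) -> np.ndarray:
    """Maxima points (prominence > tolerance, one per plateau, img > 0).

    Maxima of different connected positive islands are separated by the
    zero floor, so their saddles never exceed zero: prominence can be
    evaluated exactly per island on its padded bounding box, which keeps
    the grayscale reconstruction off the (large, zero) background.
    """
    img = np.asarray(img, dtype=float)
    structure = np.ones((3,) * img.ndim, dtype=int)
    labels, n = ndimage.label(img > 0, structure=structure)
    if n == 0:
        return np.empty((0, img.ndim), dtype=int)
    points = []
    for idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        crop = np.where(labels[sl] == idx, img[sl], 0.0)
        pad = np.pad(crop, 1)
        regions = _prominent_regions(pad, tolerance) & (pad > 0)
        pts = _one_pixel_per_region(pad, regions)
        if len(pts):
            offs = np.array([s.start - 1 for s in sl])
            points.append(pts + offs)
    if not points:
        return np.empty((0, img.ndim), dtype=int)
    return np.concatenate(points)


def find_maxima_2d(img: np.ndarray, tolerance: float) -> np.ndarray:
    """2D maxima (one pixel each) with prominence > tolerance; only strictly
    positive pixels qualify (the zeroed background is never a maximum).
    Returns (n, 2) integer (y, x) coordinates."""
    return _prominent_points(img, tolerance)


def _ball_footprint(radius: float, ndim: int) -> np.ndarray:
    r = int(np.floor(radius))
    grids = np.meshgrid(*([np.arange(-r, r + 1)] * ndim), indexing="ij")
    return sum(g * g for g in grids) <= radius * radius


def find_maxima_3d(img: np.ndarray, tolerance: float, radius: float
                   ) -> np.ndarray:
    """3D maxima: prominence > tolerance and largest within a ball of the
    given radius. Returns (n, 3) integer (z, y, x) coordinates."""
    img = np.asarray(img, dtype=float)
    pts = _prominent_points(img, tolerance)
    if len(pts) == 0:
        return pts
    fp = _ball_footprint(radius, 3)
    r = fp.shape[0] // 2
    keep = np.ones(len(pts), dtype=bool)
    for k, p in enumerate(pts):
        sl = tuple(slice(max(c - r, 0), c + r + 1) for c in p)
        fsl = tuple(slice(max(r - c, 0), r + (s - c)) for c, s
                    in zip(p, img.shape))
        neigh = img[sl][fp[fsl]]
        keep[k] = img[tuple(p)] >= neigh.max()
    return pts[keep]


# --------------------------------------------------------------------------
# shared pipeline steps

def _subtract_background_rolling(stack: np.ndarray, radius: int
                                 ) -> np.ndarray:
    """Per-slice rolling-ball background subtraction, realized as a white
    top-hat: image minus its grayscale opening with a disk of the given
    radius."""
    fp = _ball_footprint(radius, 2)[None, :, :]
    opened = ndimage.grey_opening(stack, footprint=fp, mode="nearest")
    return stack - opened


def _divide_by_blur(stack: np.ndarray, sigma: float) -> np.ndarray:
    """Flat-field-style normalization: the stack divided by a blurred copy,
    rescaled back to the input's intensity range."""
    blur = ndimage.gaussian_filter(stack, sigma)
    ratio = stack / np.maximum(blur, 1e-12)
    lo, hi = float(ratio.min()), float(ratio.max())
    if hi <= lo:
        return np.zeros_like(stack)
    span = float(stack.max()) - float(stack.min())
    return (ratio - lo) / (hi - lo) * span + float(stack.min())


def _zoom_up(stack: np.ndarray, factors: tuple[float, ...]) -> np.ndarray:
    return ndimage.zoom(stack, factors, order=1, grid_mode=True,
                        mode="nearest")


def _downscale_coords(coords: np.ndarray, factors: np.ndarray) -> np.ndarray:
    """Map grid_mode zoomed-voxel coordinates back to original units."""
    return (coords + 0.5) / factors - 0.5


# --------------------------------------------------------------------------
# rv-centroid pipeline

def detect_centroids_rv(stack: np.ndarray, params: DetectionParams
                        ) -> CentroidSet:
    """Detect labeled cells as size-filtered 3D component centroids.

    Steps, in order: optional divide-by-blur normalization; per-slice
    rolling-ball background subtraction; x-y upscaling by the expansion
    factor; per-slice Gaussian blur; per-slice Laplacian response (negated
    so blob centers are bright); optional minimum filter; zeroing of
    sub-threshold pixels; per-slice 2D maxima with the noise tolerance;
    dilation of each maximum to a small disk; 26-connected 3D components
    with the size filter; centroids mapped back to original voxel units.
    """
    if params.threshold is None:
        raise ValueError("params.threshold is required")
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a single-channel (z, y, x) stack")
    if min(stack.shape[1:]) < 8:
        raise ValueError("stack too small for the filter chain")
    f = params.expansion_factor

    work = stack
    if params.use_gaussian_division:
        work = _divide_by_blur(work, params.division_sigma)
    work = _subtract_background_rolling(work,
                                        params.rolling_background_radius)
    work = _zoom_up(work, (1, f, f))
    sig = params.gaussian_sigma
    work = ndimage.gaussian_filter(work, (0, sig, sig))
    lap = np.empty_like(work)
    ls = params.laplacian_sigma
    for z in range(work.shape[0]):
        lap[z] = -ndimage.gaussian_laplace(work[z], ls)
    if params.use_min_filter:
        fp = _ball_footprint(params.min_filter_radius, 2)[None, :, :]
        lap = ndimage.minimum_filter(lap, footprint=fp, mode="nearest")
    lap[lap < params.threshold] = 0.0

    points = np.zeros(lap.shape, dtype=bool)
    for z in range(lap.shape[0]):
        for y, x in find_maxima_2d(lap[z], params.maxima_noise_tolerance):
            points[z, y, x] = True
    disk = _ball_footprint(params.dilation_radius, 2)[None, :, :]
    blobs = ndimage.binary_dilation(points, structure=disk)
    labels, n = ndimage.label(blobs, structure=np.ones((3, 3, 3), dtype=int))
    rows = []
    if n:
        sizes = ndimage.sum_labels(blobs, labels, np.arange(1, n + 1))
        centroids = ndimage.center_of_mass(blobs, labels, np.arange(1, n + 1))
        lo, hi = params.size_filter
        for (cz, cy, cx), size in zip(centroids, sizes):
            if lo <= size <= hi:
                cy, cx = _downscale_coords(np.array([cy, cx]),
                                           np.array([f, f], dtype=float))
                rows.append({"channel": 0, "z": cz, "y": cy, "x": cx,
                             "size_px": int(size)})
    records = pd.DataFrame(rows, columns=["channel", "z", "y", "x",
                                          "size_px"])
    return CentroidSet(records=records, params_used=params)


# --------------------------------------------------------------------------
# cfos 3D-maxima pipeline

def _cfos_process_substack(sub: np.ndarray, params: DetectionParams
                           ) -> np.ndarray:
    """The per-partition filter chain; returns maxima in original-unit
    coordinates relative to the substack origin."""
    f = params.expansion_factor
    work = _subtract_background_rolling(np.asarray(sub, dtype=float),
                                        params.rolling_background_radius)
    work = _zoom_up(work, (f, f, f))
    work = ndimage.minimum_filter(
        work, footprint=_ball_footprint(params.min_filter_radius, 3),
        mode="nearest")
    work = ndimage.gaussian_filter(work, params.gaussian_sigma)
    work[work < params.threshold] = 0.0
    pts = find_maxima_3d(work, params.maxima_noise_tolerance,
                         params.maxima_radius)
    if len(pts) == 0:
        return np.empty((0, 3))
    return _downscale_coords(pts.astype(float),
                             np.array([f, f, f], dtype=float))


def _partition_edges(extent: int, n_parts: int) -> list[tuple[int, int]]:
    cuts = np.linspace(0, extent, n_parts + 1).round().astype(int)
    return [(int(a), int(b)) for a, b in zip(cuts[:-1], cuts[1:]) if b > a]


def detect_maxima_cfos(stack: np.ndarray, params: DetectionParams
                       ) -> CentroidSet:
    """Detect labeled nuclei as prominent 3D local maxima.

    The stack is processed as an x-y grid of substacks with margins and in
    z chunks with margin slices (a streaming device: results are identical
    to an unpartitioned run). A maximum belongs to the partition in whose
    core (margin-stripped) region its coordinate lies; core regions are
    half-open, so a boundary coordinate belongs to the lower-index
    partition and every maximum is reported exactly once.
    """
    if params.threshold is None:
        raise ValueError("params.threshold is required")
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a single-channel (z, y, x) stack")
    nz, ny, nx = stack.shape
    gy, gx = params.partition_grid
    m, mz = params.partition_margin, params.z_margin
    y_parts = _partition_edges(ny, gy)
    x_parts = _partition_edges(nx, gx)
    z_parts = [(z0, min(z0 + params.z_chunk, nz))
               for z0 in range(0, nz, params.z_chunk)]
    if any(b - a <= 0 for a, b in y_parts + x_parts + z_parts):
        raise ValueError("partition smaller than one voxel")

    all_pts: list[np.ndarray] = []
    for z0, z1 in z_parts:
        for y0, y1 in y_parts:
            for x0, x1 in x_parts:
                zl, yl, xl = max(z0 - mz, 0), max(y0 - m, 0), max(x0 - m, 0)
                sub = stack[zl:min(z1 + mz, nz),
                            yl:min(y1 + m, ny),
                            xl:min(x1 + m, nx)]
                pts = _cfos_process_substack(sub, params)
                if len(pts) == 0:
                    continue
                pts = pts + np.array([zl, yl, xl], dtype=float)
                core = ((pts[:, 0] >= z0) & (pts[:, 0] < z1)
                        & (pts[:, 1] >= y0) & (pts[:, 1] < y1)
                        & (pts[:, 2] >= x0) & (pts[:, 2] < x1))
                all_pts.append(pts[core])
    coords = (np.concatenate(all_pts) if all_pts else np.empty((0, 3)))
    # stable output order regardless of the partition layout
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    coords = coords[order]
    records = pd.DataFrame({"channel": 0, "z": coords[:, 0],
                            "y": coords[:, 1], "x": coords[:, 2],
                            "size_px": 1},
                           columns=["channel", "z", "y", "x", "size_px"])
    return CentroidSet(records=records, params_used=params)


# --------------------------------------------------------------------------
# enhancement, rendering, evaluation

def enhance_cfos(stack: np.ndarray, threshold: float,
                 kernel: np.ndarray = CFOS_KERNEL,
                 max_filter_radius: int = 1, gaussian_sigma: float = 1.0,
                 skip_filters: bool = False, clamp: bool = True
                 ) -> np.ndarray:
    """Display enhancement for punctate nuclear staining.

    Per slice: zero sub-threshold pixels, 2D maximum filter, 2D Gaussian
    blur, then an unnormalized convolution with the 5x5 kernel; the output
    is clamped to the input stack's intensity range. ``skip_filters``
    bypasses the max/blur steps (pure thresholded convolution); ``clamp``
    disables the final range clamp.
    """
    if kernel.shape != (5, 5):
        raise ValueError("kernel must be 5x5")
    stack = np.asarray(stack, dtype=float)
    single = stack.ndim == 2
    work = stack[None] if single else stack.copy()
    work = np.where(work < threshold, 0.0, work)
    if not skip_filters:
        fp = np.ones((1, 2 * max_filter_radius + 1,
                      2 * max_filter_radius + 1), dtype=bool)
        work = ndimage.maximum_filter(work, footprint=fp, mode="nearest")
        work = ndimage.gaussian_filter(work, (0, gaussian_sigma,
                                              gaussian_sigma))
    out = ndimage.convolve(work, kernel[None], mode="constant", cval=0.0)
    if clamp:
        out = np.clip(out, float(stack.min()), float(stack.max()))
    return out[0] if single else out


def render_centroids(centroids: CentroidSet, shape: tuple[int, int, int],
                     sigma: float = 2.0) -> np.ndarray:
    """Render detections as unit-peak Gaussian spots summed into a stack."""
    out = np.zeros(shape, dtype=float)
    coords = centroids.coordinates()
    if len(coords) and ((coords < 0).any()
                        or (coords >= np.array(shape)).any()):
        raise ValueError("centroid outside the requested shape")
    reach = int(np.ceil(4 * sigma))
    for cz, cy, cx in coords:
        sl = tuple(slice(max(int(c) - reach, 0), min(int(c) + reach + 1, s))
                   for c, s in zip((cz, cy, cx), shape))
        zz, yy, xx = np.meshgrid(*(np.arange(s.start, s.stop) for s in sl),
                                 indexing="ij")
        d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        out[sl] += np.exp(-d2 / (2.0 * sigma * sigma))
    return out


def _as_coords(obj) -> np.ndarray:
    if isinstance(obj, CentroidSet):
        return obj.coordinates()
    if isinstance(obj, pd.DataFrame):
        return obj[["z", "y", "x"]].to_numpy(dtype=float)
    return np.asarray(obj, dtype=float).reshape(-1, 3)


def evaluate(detected, truth, match_radius: float = 5.0) -> EvaluationResult:
    """Score detections against ground truth coordinates.

    Greedy one-to-one matching by ascending pairwise distance; pairs beyond
    ``match_radius`` are never matched. Sensitivity = matched / ground
    truth; PPV = matched / detected (NaN when nothing was detected).
    """
    det = _as_coords(detected)
    gt = _as_coords(truth)
    n_matched = 0
    if len(det) and len(gt):
        d = np.linalg.norm(det[:, None, :] - gt[None, :, :], axis=2)
        pairs = np.argwhere(d <= match_radius)
        order = np.argsort(d[tuple(pairs.T)], kind="stable")
        used_d = np.zeros(len(det), dtype=bool)
        used_g = np.zeros(len(gt), dtype=bool)
        for i, j in pairs[order]:
            if not used_d[i] and not used_g[j]:
                used_d[i] = used_g[j] = True
                n_matched += 1
    return EvaluationResult(n_ground_truth=len(gt), n_detected=len(det),
                            n_matched=n_matched, match_radius=match_radius)


def evaluate_counts(n_matched: int, n_ground_truth: int, n_detected: int,
                    match_radius: float = float("nan")) -> EvaluationResult:
    """Build an evaluation from raw counts (worked-example use)."""
    if n_matched > min(n_ground_truth, n_detected):
        raise ValueError("matched count exceeds ground truth or detections")
    return EvaluationResult(n_ground_truth=n_ground_truth,
                            n_detected=n_detected, n_matched=n_matched,
                            match_radius=match_radius)
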