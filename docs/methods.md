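# Methods

This note documents the models, numerical choices, and synthetic-data
conditions behind `histogel`, and what the test suite does and does not
establish about real data.

## Staining reaction–diffusion model (`stain_sim`)

A reactive solute S (dye or antibody) diffuses through a 2D square domain
holding a circular gel; inside the gel an immobile target T binds it
reversibly:

    ∂[S]/∂t  = D_diff ∇²[S] + k_off [ST] − k_on [S][T]
    ∂[T]/∂t  =               k_off [ST] − k_on [S][T]
    ∂[ST]/∂t =             − k_off [ST] + k_on [S][T]

[T] and [ST] are not transported; only [S] diffuses, over the whole
domain. All quantities are unitless. The reference scenario is a radius-1
gel centered in a 20 × 20 bath with D_diff = 1, k_on = 1, k_off = 0.01,
initial [S] = 100 outside / 0 inside, [T] = 100 inside / 0 outside,
[ST] = 0, integrated to t = 1; these parameters are tuned such that the
bound complex is almost homogeneous inside the gel at t = 1.

**Discretization.** Uniform Cartesian grid (default spacing 0.05, i.e.
400 × 400 over the reference domain, ≥ 20 cells per gel radius), 5-point
Laplacian, gel membership by cell-center test, zero-flux walls (the bath is
~125× the gel area, so the wall condition is immaterial on the simulated
time scale; a doubled-domain check changes the pattern readout by < 0.1%).

**Time stepping.** Operator splitting per step: an explicit-Euler diffusion
substep under the CFL limit dt ≤ 0.25 h²/D_diff, then an *exact* local
reaction substep — with a = S + ST and b = T + ST conserved per cell, the
reaction reduces to the Riccati equation du/dt = k_on(a−u)(b−u) − k_off u,
integrated in closed form between the roots of its quadratic. The split
scheme is therefore stable for arbitrarily stiff binding. The global step
is additionally capped at max_step_fraction × t_end (default 0.003).
Because the reaction update conserves b per cell exactly, ∑(T + ST) over
the gel is invariant to round-off; the suite checks 1e-6 relative.

**Pattern classification.** The radial [ST] profile (mean per radial bin)
is summarized by the center/edge ratio: mean over ρ ≤ 0.2 divided by mean
over ρ ≥ 0.8 (ρ in gel radii). Ratio < 0.25 → *rimmed*, > 0.75 →
*gradual*, else *intermediate*. The 0.25/0.75 thresholds and the 0.9
"near-uniform" criterion for the reference scenario are calibration
choices of this package ("almost homogeneous" is not otherwise
quantified). A zero edge mean leaves the ratio undefined; such profiles
are labelled gradual with an explicit flag.

**Saturation and parameter sweeps.** At the reference parameters the gel
binds to completion well before t = 1 for every k_on ≥ 1 (equilibrium
[ST] ≈ T everywhere, and supply and transport suffice), so pattern
comparisons across binding strength degenerate at t = 1: all saturated
runs are equally uniform. The qualitative statement "stronger binding
retains the stain at the gel edge" is a statement about the penetration
transient, so sweep-based comparisons of k_on use a sub-saturation
snapshot (t = 0.25 in the tests), where the center/edge ratio is cleanly
monotone decreasing in k_on. Sweeps over the outside solute concentration
do not saturate at the low end and are evaluated at t = 1.

## Gel-section assay (`gel_assay`)

Cross-section images are standardized by (1) median-replacing bright
outliers (disk radius 10, threshold 50), (2) subtracting a scalar
background measured on a nonstained gel, clamped at zero, (3) cropping to
the largest thresholded object and rescaling the gel width to 1500 px
(aspect preserved, bilinear). Six diameter profiles are sampled at
0°, 30°, …, 150° (uniform angular coverage; the angles are this package's
choice) as 1500 × 30 px bands through the centroid of the thresholded
disk, bilinear interpolation, averaged across the band; classification
folds the mean profile at the center and applies the simulation
thresholds. Automatic thresholding defaults to Otsu and is exposed as a
parameter (the original workflow allowed manual adjustment, which a
non-interactive pipeline cannot reproduce).

Swelling: S/S0 with S0 the mean reference-state area (n = 8 in the
original assay; any reference list is accepted). Isotropic deformation
maps an area factor a to a volume factor a^(3/2) (4 → 8).

## SAXS reduction (`saxs`)

q convention: θ = arctan(r/L) is the full scattering angle and
q = (4π/λ) sin(θ/2), consistent with Bragg's law d = 2π/q; over the
relevant range (q ≲ 0.3 Å⁻¹ at λ = 1 Å, L = 4 m) this differs from the
small-angle form 2πr/(λL) by < 0.1%. Azimuthal averages use linear q bins
(count configurable); empty bins are NaN, never silent zeros. Sector
averages include the point-mirrored sector by default (Friedel symmetry).
Background subtraction requires an identical q grid, scales by a free
factor (the transmission correction of the original measurement is not
recoverable; default 1), clamps at zero and counts clamp events. The
mass-fractal exponent is −slope of an ordinary least-squares line through
(log₁₀ q, log₁₀ I) in a stated window, with non-positive intensities
excluded and counted.

At low q, the mean q of the pixels inside a bin differs noticeably from
the bin center (few, discrete radii per bin); oracle comparisons of
averaged profiles therefore evaluate the generating I(q) at the per-bin
mean q.

## Stack assembly (`stack_ops`)

Column contrast for seam selection is the standard deviation of the pixels
in a 32-px-wide vertical strip around each column, smoothed with a 16-px
moving average; the seam between two adjacent focus-shifted frames is the
first column (left to right, after the previous seam) where the next
frame's contrast exceeds the current frame's. The metric and window are
this package's choices — the original acquisition software used an
unspecified contrast comparison. When the curves never cross (e.g.
identical frames) the seam falls back to an even split and is flagged
indeterminate, mirroring the original manual fallback. Equalization is
multiplicative to the grand mean (appropriate for non-negative intensity
data). 8-bit conversion maps [lo, hi] → [0, 255] linearly with
round-half-to-even (so 127.5 → 128). The outlier filter replaces a pixel
by its disk-neighborhood median iff it deviates beyond the threshold in
the chosen polarity; boundaries are handled by reflection.

## Cell detection (`cell_detect`)

*rv_centroid* (sparse, bright labels): optional divide-by-Gaussian-blur
normalization (ratio rescaled to the input range); per-slice rolling-ball
background subtraction realized as a white top-hat (image minus grayscale
opening, ball radius 1); 3× x–y upscaling (linear); per-slice Gaussian
(σ = 2) and negated Laplacian-of-Gaussian (σ = 2) so blob centers are
bright; optional minimum filter (radius 1.5); zeroing below the per-channel
threshold; per-slice 2D maxima; dilation of maxima to 5-px disks;
26-connected 3D components filtered to 6–76 px; centroids divided by the
expansion factor. *cfos_maxima* (dense nuclear labels): rolling-ball
(radius 1), 3× x–y–z upscaling, 3D minimum filter (radius 1), 3D Gaussian
(σ = 1), threshold, prominent 3D maxima within a ball radius (default
2.5 expanded voxels) — computed on an x–y partition grid (default 10 × 10
with 10-px margins) and z chunks (120 slices, 5 margin slices) purely as a
streaming device; a maximum is owned by the partition whose half-open core
contains it, so results are identical to an unpartitioned run (verified).

"Find Maxima" semantics: a retained maximum exceeds the highest saddle
toward any higher maximum by strictly more than the noise tolerance
(prominence, via grayscale reconstruction), one pixel per plateau, ties to
the lexicographically smallest (z, y, x). The zeroed background never
counts as a maximum. For efficiency the reconstruction runs per connected
suprathreshold island (exact: islands are separated by the zero floor).

Thresholds and noise tolerances are data-dependent inputs (they were tuned
manually per channel in the original workflow and never published); the
suite calibrates them once for the synthetic stacks (LoG threshold 4,
tolerance 2 for rv; threshold 40, tolerance 1 for cfos). The cfos maxima
radius is likewise cell-size-dependent: the suite uses 7.5 expanded voxels
(= 2.5 original ≈ the synthetic cell radius), since the 2.5-expanded-voxel
default suits nuclei spanning ~1 voxel and can pass twin noise peaks on
wider somata.

Evaluation: greedy one-to-one matching by ascending pairwise distance
within a match radius (default 5 voxels); sensitivity = matched / ground
truth, PPV = matched / detected (NaN when nothing is detected). Greedy
matching never exceeds the maximum bipartite matching and attains it in
generic geometries (checked against an exact oracle); it is deterministic,
which an optimal matcher with ties need not be.

## Synthetic data (`synthetic`)

All generators take a seed and are bit-reproducible. The cell-stack
defaults define the detection test condition: a 48 × 96 × 96 voxel stack,
50 cells per channel at pairwise separation ≥ 10 voxels (rejection
sampling, budget 1000 attempts per cell), isotropic Gaussian blobs of
σ = 1.2 voxels — at light-sheet sampling of 8–9 µm voxels a 10–20 µm soma
spans roughly one voxel σ — amplitudes 500–1000 over a background of 100
with a mild linear gradient and Gaussian noise of SD 10 (SNR ≥ 50, the
"bright, well-separated" regime). Gel sections default to a radius-180 px
disk in a 420 × 420 image, amplitude 1000, background 50, noise SD 10;
"rimmed" is a step confined to the outer 10% of the radius, "gradual" an
exponential approach to full penetration with decay length 4 radii
(center/edge ratio ≈ 0.84, safely on the gradual side of 0.75). SAXS
patterns place I(q) = A·q⁻ᴰ (+ optional Gaussian ring + flat term) on an
ideal detector with an excluded beamstop disk; Poisson noise draws each
pixel with the model value as mean. Focus-shifted frames blur a shared
dot field with σ growing linearly in the column distance to each frame's
focus.

What the generators deliberately omit: anisotropic PSFs, scattering and
vignetting, tissue autofluorescence, detector distortions, non-spherical
or touching cells, and intensity-dependent noise mixtures. Passing tests
therefore demonstrate algorithmic correctness under controlled conditions
(exact ground truth, idealized optics), not field performance on real
stacks, where thresholds, tolerances, and the maxima radius must be tuned
to the data as in any real deployment.

## Degenerate inputs and edge policies

Empty radial or q bins raise (or are NaN-flagged) rather than silently
zeroed; a blank gel image ("no foreground") raises; zero detections give
NaN PPV with zero matched; a constant stack maps to all-zero 8-bit output;
placement budgets exhausted raise with the achievable density named. The
linear-ramp profile has center/edge ratio 1/9, which the default
thresholds label rimmed — threshold pairs straddling 1/9 yield
intermediate, and both behaviors are pinned by tests.

## Problem sizes

The test suite runs the reference simulation at the full 400 × 400 grid;
sweeps, convergence, and limit checks use smaller baths (side 4–8) at the
same gel radius. Detection acceptance uses ten seeded 48 × 96 × 96 stacks
per pipeline with a 3 × 3 partition grid for the cfos variant (the 10 × 10
default is exercised once for partition invariance on the same stack
size). The whole suite completes in a few minutes on one CPU.
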