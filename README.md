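# histogel

Quantitative tools for whole-organ 3D staining and light-sheet imaging of
cleared tissue.

Fixed, delipidated tissue behaves as an electrolyte gel of cross-linked
polypeptides: it swells and shrinks with ionic strength and pH, scatters
X-rays like a heterogeneous mass-fractal network, and takes up dyes and
antibodies by diffusion coupled to reversible binding. `histogel`
implements the computational side of a workflow built on that picture, for
researchers who design, troubleshoot, or quantify volumetric staining
experiments:

* **`histogel.stain_sim`** — a reaction–diffusion simulator of stain
  penetration into a circular gel. The solute S diffuses (coefficient
  D_diff) and binds an immobile target T reversibly, S + T ⇌ ST with rates
  k_on / k_off; the bound complex [ST] is the staining signal. The staining
  pattern is classified from the center/edge ratio of the radial [ST]
  profile as *rimmed* (stain trapped at the surface), *gradual* (uniform
  penetration), or intermediate.
* **`histogel.gel_assay`** — quantification of stained gel cross sections:
  outlier removal, background subtraction, resizing to a standard 1500-px
  gel width, mean ± SD intensity along six diameters (1500 × 30 px bands),
  the same rimmed/gradual classification, plus disk-area measurement and
  S/S0 swelling ratios (an isotropic area factor *a* is a volume factor
  *a*^(3/2)).
* **`histogel.saxs`** — small-angle X-ray scattering reduction: circular
  and sector averaging of detector images into I(q), Bragg d-spacings
  d = 2π/q, and the mass-fractal exponent D of the power law I ∝ q⁻ᴰ from
  a least-squares fit of log₁₀ I against log₁₀ q.
* **`histogel.stack_ops`** — light-sheet stack assembly: mean-intensity
  equalization, contrast-driven selection of tiling seams between
  focus-shifted frames, column tiling, voxelwise max fusion of opposed
  acquisitions, 16→8-bit conversion, and a median-based outlier filter.
* **`histogel.cell_detect`** — two labeled-cell detection pipelines
  (per-slice Laplacian-of-Gaussian maxima with 3D component centroids for
  sparse cytoplasmic labels; partitioned 3D prominence maxima for dense
  nuclear labels), the 5×5 enhancement kernel for punctate signals,
  centroid rendering, and sensitivity / positive-predictive-value scoring
  against ground-truth coordinates.
* **`histogel.synthetic`** — seeded generators for every input class
  (gel sections, cell stacks, SAXS patterns, swelling series, focus-shifted
  frames) with exact ground truth, so all pipelines run and are tested
  without any experimental data.

## Worked example

Simulate staining of a radius-1 gel in a 20 × 20 bath (D_diff = 1,
k_on = 1, k_off = 0.01, [S]ₒᵤₜ = [T]ᵢₙ = 100) and classify the pattern at
t = 1; then detect cells in a synthetic two-channel-free stack and score
them:

```python
import numpy as np
from histogel import stain_sim, synthetic, cell_detect, saxs

cfg = stain_sim.SimulationConfig()
final = stain_sim.simulate(cfg)[-1]
pattern = stain_sim.classify_pattern(stain_sim.radial_profile(final, cfg, 10))
print(pattern.label, round(pattern.center_edge_ratio, 4))
# gradual 0.9999      <- near-uniform interior [ST] at t = 1

stack, truth = synthetic.gen_cell_stack(synthetic.CellStackSpec(), seed=1)
params = cell_detect.DetectionParams(variant="rv_centroid", threshold=4.0,
                                     maxima_noise_tolerance=2.0)
detected = cell_detect.detect_centroids_rv(stack[0], params)
ev = cell_detect.evaluate(detected, truth[["z", "y", "x"]], match_radius=5)
print(f"{ev.n_matched}/{ev.n_ground_truth} cells, "
      f"sensitivity {100*ev.sensitivity:.1f}%, PPV {100*ev.ppv:.1f}%")
# 50/50 cells, sensitivity 100.0%, PPV 100.0%

print(round(saxs.bragg_spacing(0.08), 2), "nm")
# 7.85 nm             <- d-spacing of a q = 0.08 1/A scattering peak
```

A command-line interface mirrors the library
(`histogel --help`): `synth gel|cells|saxs|swelling|focus`, `simulate`,
`sweep`, `gel-profile`, `swelling`, `saxs-average`, `saxs-fit`,
`saxs-bragg`, `detect`, `enhance-cfos`, `evaluate`, `tile`, `fuse-max`,
`to8bit`, `remove-outliers`.

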