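# ecmkit

Quantification of fibrous extracellular-matrix (ECM) microstructure and
3D cell motility from reflection-confocal images and cell-tracking
tables.

Cell migration through 3D collagen is shaped by intertwined matrix
properties — pore size, fiber alignment, crosslinking, stiffness — that
cannot be varied independently in a self-assembling gel. Asking *which*
property predicts motility therefore requires measuring each one
quantitatively in every condition and cross-correlating matrix
descriptors with motility statistics. `ecmkit` implements that
measurement pipeline for researchers working with label-free reflection
confocal images of collagen gels and manually or automatically tracked
cells:

* **Fiber-alignment index** α: the image is background-normalized,
  fiber-enhanced by an oriented 5×5 line-filter bank, binarized, and
  Fourier-transformed; the DFT magnitude is integrated along diameter
  lines at angles θ ∈ [0, π) to give the angular power F_I(θ), and the
  eigenvalues λ₁ ≥ λ₂ of the second-moment matrix of the points
  (F_I cos θ, F_I sin θ) give **α = 1 − λ₂/λ₁** (0 = isotropic,
  1 = fully aligned).
* **Pore-size spectrum**: granulometry of the binary mask's pore space
  by sequential morphological opening with digital disks of increasing
  radius r; the decrements of the retained area I(r) give the pore
  frequency distribution f(r) and the mean pore diameter in μm.
* **Motility statistics**: cell speed (mean step per 2-min interval),
  net invasion distance (max displacement from origin), protrusion rate
  per 90 min, eight-partition protrusion orientation fractions, and the
  **polarization index (C1 − C2)/(C1 + C2)** contrasting
  anteroposterior (partitions 1, 5) with lateral (3, 7) protrusions.
* **Correlation reports**: min-max-normalized condition means regressed
  pair-by-pair (slope, r², slope p-value).
* A **synthetic-data generator** (fiber fields with controllable
  orientation concentration, width, length, density; interference-style
  backgrounds; persistent random walks; biased protrusion streams) with
  exact ground truth, so the full pipeline runs and validates with no
  microscope data.

## Worked example

Generate an aligned and an isotropic synthetic matrix and measure both:

```python
from ecmkit import (FiberFieldParams, MicrostructureConfig,
                    analyze_microstructure, generate_fiber_image)

cfg = MicrostructureConfig(crop_um=None, max_radius_px=20)
for kappa in (0.0, 16.0):
    params = FiberFieldParams(image_size_px=(192, 192), n_fibers=120,
                              orientation_kappa=kappa, seed=3)
    img, truth = generate_fiber_image(params)
    rep = analyze_microstructure(img, cfg)
    print(f"kappa={kappa:4.0f}  alpha={rep.alignment.alpha:.3f}  "
          f"mean pore diameter={rep.pore.mean_diameter_um:.2f} um")
```

```
kappa=   0  alpha=0.173  mean pore diameter=2.00 um
kappa=  16  alpha=0.834  mean pore diameter=2.37 um
```

The isotropic field (κ = 0) scores a low alignment index while the
concentrated field (κ = 16) scores high; pore diameters are similar
because both fields contain the same number of fibers at the same
pixel size (0.2 μm/px).

The `analysis/` directory runs a complete simulated study: six matrix
conditions emulating increasing collagen density
(`01_simulate.py`), microstructure measurement per condition
(`02_matrix_microstructure.py`), motility summaries
(`03_cell_motility.py`), and cross-metric correlations
(`04_correlations.py`), writing tables under `results/`. On the
bundled conditions the alignment index correlates significantly with
speed, protrusion rate and polarization (r² = 0.71–0.82, p < 0.05),
while mean pore size does not (r² ≤ 0.19) — the correlation structure
the pipeline is designed to resolve.

## Layout

```
src/ecmkit/        library: synthetic, preprocess, microstructure,
                   motility, stats, io, config, pipeline
analysis/          numbered study drivers (simulate -> measure ->
                   correlate), writing results/
tests/             pytest suite incl. brute-force oracles
scripts/           acceptance script
docs/methods.md    models, parameters, design choices, limitations
```
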