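# Methods

This note documents the models and procedures implemented in `ecmkit`,
the parameters that matter, and the choices made where the underlying
methodology leaves the design open.

## Scope and data model

The pipeline quantifies two things from 2D reflection-confocal images of
fibrous collagen matrices — the bulk **fiber-alignment index** α and the
**pore-size distribution** — and, from coordinate tables of tracked
cells, the matched **motility statistics** (speed, net invasion
distance, protrusion rate/orientation, polarization index). Condition
means of both families are min-max normalized and cross-correlated by
OLS regression, the analysis used to ask which matrix descriptor
predicts motility.

Images are single-channel 2D arrays with a physical pixel size
(0.2 μm/px for the targeted acquisition settings). Coordinates use
image convention: origin top-left, x right, y down, angles
counter-clockwise from +x; axial quantities (fiber orientation) are
reported on [0, π). Physical outputs are in μm and minutes; pixel-unit
intermediates carry an explicit `_px` suffix.

## Image preprocessing

1. **Radial background.** Reflection imaging superimposes an
   interference background that is approximately a function of radial
   distance from the image center. The background I_B is estimated as a
   per-radial-bin (1 px) angular summary, linearly interpolated in
   radius. The summary statistic is the **median** rather than the
   mean: on fiber-free surfaces the two coincide to <1%, but a bright
   fiber crossing a thin annulus drags the annulus *mean* far from the
   true background (we measured 23% peak error at 4% fiber coverage,
   vs 0.5% for the median). The plain mean is available via
   `statistic="mean"`.
2. **Normalization.** Flat-field division preserving the global mean:
   I_N = I_R·⟨I_B⟩/I_B, with I_B floored at 1% of its mean so dark
   corners cannot amplify noise. If raw equals background the output is
   the constant ⟨I_B⟩; a uniform background leaves the image unchanged.
3. **Fiber enhancement (FEF).** An oriented matched-filter bank. For
   each of 15 orientations evenly spanning [0, 180°), a 1-px
   Bresenham line through the center of a 5×5 mask defines the line
   support; the Gaussian filter GF_θ is the sum-normalized product of
   the line with an isotropic Gaussian (σ = 0.7 px), the average filter
   AF_θ the sum-normalized line itself. The response at θ is
   (I∗GF_θ) − (I∗AF_θ) and I_FEF is the pixelwise maximum over θ.
   Both filters sum to 1, so constant regions map exactly to 0 while
   ridge-like structure scores positive. Convolution uses reflect
   padding (no rim artifacts in small crops). At 5×5, several θ values
   alias to the same digital line; duplicates are kept so the bank
   always holds exactly `n_orientations` pairs. The masks are
   point-symmetric, so convolution and correlation coincide.
4. **Binarization.** Threshold on I_FEF; Otsu by default (a fixed value
   or quantile can be configured), with the threshold actually applied
   recorded in the output metadata. On a standard synthetic fixture
   (width 3 px, κ = 4, radial background + speckle) the default chain
   recovers the ground-truth fiber mask at pixelwise F1 ≥ 0.9; the test
   suite asserts a conservative regression bound of 0.7.

## Pore-size granulometry

Pores are the complement of the binary fiber mask. For radii
r = 0..R the pore image is opened with a digital disk
(pixels within Euclidean distance r + 0.5 of the center) and the
retained area I(r) recorded; the per-radius area P(r) = I(r) − I(r+1)
estimates the area occupied by pores of characteristic radius r, the
normalized P is the pore-size frequency f(r), and the mean radius is
the f-weighted mean (reported also as a diameter in μm).

Two numerical points:

* **Digital disks are not a perfect sieve.** An opening at r+1 can
  retain jagged boundary pixels that the opening at r removed, which
  would make I(r) non-monotone and f locally negative. The openings
  are therefore accumulated by intersection
  (kept_r = kept_{r−1} ∧ open(pores, B_r)), restoring the nesting that
  continuous-space granulometry guarantees. On generic random masks
  this is identical to independent per-radius openings.
* **Resolution flag.** Sub-pixel pore structure cannot be measured;
  when the mean pore radius falls below 2 px the result is flagged as
  approaching the resolution limit of the imaging system. An all-fiber
  mask has an undefined (NaN) mean, reported as missing, never as 0.
* The terminal bin absorbs pore area surviving the largest opening and
  sets a `truncated` flag, so f always sums to 1 when pores exist.

## Fiber-alignment index

The alignment measure is a bulk anisotropy of the whole image (no
per-fiber segmentation). The image (binary mask by default; the
normalized image is a config option) is mean-subtracted and
transformed by 2D DFT with the origin shifted to the grid center;
the magnitude √(R²+I²) is integrated along full-diameter lines through
the center at 180 angles over [0, π) (a Radon-style line integral,
bilinear sampling at 1 px steps), giving the angular power F_I(θ).
Rows (F_I cosθ, F_I sinθ) form an n×2 matrix C, and the eigenvalues
λ₁ ≥ λ₂ of CᵀC give

    α = 1 − λ₂/λ₁  ∈ [0, 1],

0 for an isotropic field, 1 for perfect alignment. Two exact limit
cases anchor the implementation: a delta distribution gives α = 1
(rank-1 second moment), and a uniform distribution over evenly spaced
orientations gives α = 0 exactly, because Σcosθᵢsinθᵢ = 0 and
Σcos²θᵢ = Σsin²θᵢ for an even angular grid. Since the spectrum of a
fiber concentrates perpendicular to the fiber axis, the dominant
*fiber* orientation is the principal spectral orientation rotated 90°.

Choices: mean subtraction before the DFT is on by default (the
isotropic DC spike would otherwise compress α toward 0); when it is
off, the center sample is excluded from every line integral instead.
The 180 angular samples are a finer grid than, and independent of, the
15 FEF orientations. α is undefined (error, reported missing) when the
angular power is identically zero. When pixel size is supplied the
analysis crops a central 61 μm × 61 μm square, the analyzed extent the
acquisition settings assume; fixture-scale images smaller than the
crop are analyzed whole.

## Motility statistics

* **Speed** — mean Euclidean step length per sampling interval
  (2 min default), μm/min. Uniform sampling is required (1% relative
  tolerance); tracks with dropped frames are rejected, not
  interpolated.
* **Net invasion distance** — maximum displacement from the first
  recorded position over the window.
* **Protrusion orientation** — events (minimum length 5 μm) binned
  into eight 45° partitions; partition 1 is centered on the anterior
  axis, set by the longest initial protrusion and fixed thereafter.
  Boundary ties go to the counter-clockwise sector.
* **Polarization index** — α_prot = (C1 − C2)/(C1 + C2) with C1 the
  anteroposterior count (partitions 1, 5) and C2 the lateral count
  (partitions 3, 7): 1 = fully polarized along the initial axis,
  0 = balanced exploration, −1 = fully lateral. Diagonal partitions
  enter the orientation fractions but neither count. Undefined when
  C1 + C2 = 0 (reported missing). This is the simplest form matching
  both published boundary behaviors, and it is isolated in one
  function so an alternative convention can be swapped.
* **Protrusion rate** — events × 90 / observation minutes.

Per-condition values are means over cells with s.e.m.

## Statistics

Condition means of each metric are min-max normalized
((v − min)/(max − min); affine-invariant, so r² and the slope p-value
are identical before and after). Each metric pair is fit by unweighted
OLS; r² is the squared Pearson correlation and p the two-sided test of
zero slope (t, n−2 df). Condition exclusions are never automatic —
they must be declared and are recorded verbatim in the report. One-way
ANOVA + Tukey HSD are thin wrappers over standard routines, provided
for group comparisons only.

## Synthetic-data generator

The generator provides every input with exact ground truth:

* **Fiber fields.** Straight segments with uniform random centers;
  axial orientation drawn uniformly on [0, π) or by the doubled-angle
  von Mises construction (sample φ ~ VM(2·center, κ), take φ/2), so a
  single concentration κ spans isotropic (0) to aligned (∞ supported
  as a degenerate surrogate). Lengths are Gaussian around the mean
  (25% jitter, clipped at 2 px). Fibers are rendered as **hard
  strokes** (pixels within width/2 of the segment), not anti-aliased,
  so width is exactly controllable and the rasterized mask matches the
  listed ground truth by construction; an optional Gaussian blur can
  soften them. Defaults (chosen once as the fixture conditions):
  256-px frames at 0.2 μm/px, 150 fibers, length 40 px (8 μm), width
  2 px (0.4 μm).
* **Background.** Isotropic Gaussian radial falloff from the center (a
  surrogate for the reflection interference pattern, whose functional
  form is not specified anywhere authoritative) plus zero-mean
  Gaussian speckle, clipped at 0.
* **Trajectories.** Persistent random walk with exact step length
  speed×dt; the turning angle per step is (1 − persistence)·U(−π, π],
  so persistence 1 is a straight line and persistence 0 an
  uncorrelated walk with 2D diffusive MSD scaling.
* **Protrusion streams.** Poisson event counts
  (mean rate × duration/90), uniform times, lengths 5 μm + exponential
  excess; with probability `axial_bias` an event is forced onto
  partitions {1, 5}, otherwise it is uniform over all eight — bias 0
  is isotropic, bias 1 fully axial, and the recovered polarization
  index is monotone in the bias.

What the generator does **not** emulate: 3D fiber networks and their
2D reflection slices (fibers inclined >~50° to the imaging plane are
invisible in reflection mode), fiber curvature, crosslink topology,
cell-induced matrix remodeling, and realistic confocal noise spectra.
Passing tests therefore certify the *measurement* pipeline on
controlled 2D phantoms, not biological accuracy on real gels.

## Measured sensitivity structure

The test suite measures the alignment index's sensitivity structure on
20-seed fixture suites at κ = 4: tripling fiber width (2→6 px) shifts
the suite-mean α by ~0.10, clearly more than halving fiber length at a
fixed total fiber-pixel budget (~0.066). The expected ordering
(width effect > length effect) holds. The absolute length effect,
however, does not fall below the 0.05 insensitivity bound asserted in
the suite at these fiber lengths: a segment of length L spreads its
spectral ridge over an angular width ~1/L, so at 20–40 px lengths the
angular power broadens measurably when length halves. That one
assertion is expected to fail and is left failing deliberately; the
effect shrinks for longer fibers relative to the analyzed extent.

## Known limitations

* Pore sizes are supported on integer radii; no sub-pixel
  interpolation. Means below 2 px are flagged unreliable.
* The alignment index saturates near 1 and compresses differences
  between strongly aligned fields (κ ≥ 8).
* The FEF bank is fixed-scale (5×5); fibers much wider than ~3 px are
  enhanced mostly at their edges.
* The pipeline consumes coordinate tables for motility; it does not
  track cells or detect protrusions from images.
* Granulometry and alignment are measured on 2D images; no 3D
  volumetric reconstruction.

## Problem sizes

Fixture suites use 256-px frames (distribution-level tests use
128–192 px), 20 seeds for sensitivity suites, 8 seeds per κ for the
monotonicity grid, 2000 replicates for the regression null
calibration, and the simulated study in `analysis/` uses 6 conditions
× 3 fields × 20 cells. These sizes are the package's chosen fixture
scale; all statistics reported by the analysis scripts are computed at
run time from these inputs.
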