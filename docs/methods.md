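# Methods

## The reconstruction problem

A diffusion-weighted acquisition trades spatial resolution for scan time and
SNR; the resulting partial-volume mixing biases every downstream quantity
(tensor fits, FA, fiber directions).  `hosvdsr` treats resolution
enhancement as single-image superresolution: the observed low-resolution
(LR) volume `y` is modeled as a decimated version of an unknown
high-resolution (HR) volume `x`,

    y = D H x + n,

with `H` the acquisition blur (taken as identity here), `D` an
integer-factor decimator, and `n` acquisition noise.  Each gradient volume
of the 4D dataset is reconstructed by alternating two steps:

1. **HOSVD patch regularization.**  For every reference patch (cubic,
   `n = 5` voxels per edge by default) the engine collects up to `k_max`
   similar patches — candidates within a Chebyshev window (radius 5) whose
   squared Euclidean distance is strictly below `tau_d = 3 sigma^2 n^3` —
   into a stack `Z` of order 4 (`n x n x n x K`).  The stack's high-order
   SVD `Z = S x_1 U1 x_2 U2 x_3 U3 x_4 U4` gives an orthonormal, *adaptive*
   basis; coefficients with magnitude at or below the universal-style
   threshold `tau = sigma sqrt(2 ln(n^3 K))` are annihilated and the stack
   is re-synthesized with the original factors.  Overlapping patch
   estimates are averaged; the averaged field is blended with the current
   estimate using `lambda_eff = lambda / (1 + lambda)` (weight on the
   current estimate), which reduces to the plain estimator at `lambda = 0`.
2. **Subsampling-consistency correction.**  The estimate's decimation
   residual is lifted back to the HR grid by nearest-neighbour replication
   and subtracted: `x <- x - NN(D x - y)`.  With the block-mean decimator
   this enforces mean consistency *exactly*: every LR voxel equals the mean
   of its HR block to round-off after every iteration.  With the
   point-sampling ("nn") decimator the sampled voxels match the observation
   exactly.

The multi-direction variant (HOSVD-M) enlarges the candidate search to the
current estimates of the `m` preceding and `m` following gradient volumes
in acquisition order (window `M = 2m + 1`, clamped at the ends).  Patches
from adjacent directions shape the adaptive basis and the threshold but are
never scattered into the volume being reconstructed, so per-direction data
consistency is preserved.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `factor` | 2 | isotropic upsampling factor |
| `n` | 5 | patch edge (HR voxels); 5 is the standard patch size in nonlocal MRI denoising and was robust here |
| `lambda_` | 0.01 | fidelity blend; reconstruction is nearly insensitive over [0.001, 0.2] (measured spread < 0.01 dB) |
| `sigma` | "auto" | threshold scale, LR intensity units; see below |
| `m` | 0 | adjacent-direction half-width (HOSVD-M when >= 1) |
| `k_max` | 32 | stack-size cap; bounds the K mode and the SVD cost |
| `search_radius` | 5 | Chebyshev window (11^3 HR voxels), common nonlocal practice |
| `stride` | 1 | reference-patch stride; corners always cover [0, dim - n] |
| `decimator` | "blockmean" | consistency operator; use the operator that matches how the LR data was actually produced |
| `max_iter`, `tol` | 20, 1e-4 | stop when the relative L2 change falls below `tol` |
| `init` | "bspline" | cubic interpolating spline, offset-0 aligned |
| `tau_d_exponent` | 3 | patch-voxel-count scaling of `tau_d`; 2 reproduces the printed 2D rule |

**What sigma means here.**  The hard threshold must annihilate the error of
the *current estimate*, which is not the same thing as the scanner noise: a
noiseless decimated volume still carries interpolation/aliasing error, and
a spline initialization attenuates sample noise between the observed
voxels.  `sigma="auto"` therefore applies the pseudo-residual estimator
(Laplacian MAD, scaled so i.i.d. Gaussian noise is estimated unbiasedly) to
the *initial HR estimate* of each direction.  On the bundled phantom this
yields 0.6–1.1 intensity units for the noiseless dataset and 1.1–1.4 at
SNR 30 (s0 = 100).  Two standalone estimators are also exposed:
`estimate_sigma` (spatial pseudo-residuals of one volume) and
`estimate_sigma_dwi` (acquisition noise from the per-voxel spread across
equal-b directions, lower-quartile calibrated against the chi-square
distribution; returns 0 exactly on noiseless data and is within ~10% at
SNR 30 and SNR 10 on the phantom).  The dedicated DWI estimator measures
acquisition noise; the loop deliberately does not use it as the threshold
scale.

**Alignment convention.**  Voxel indices are 0-based; decimation keeps
offset 0 of every block; a patch with corner `c` covers `[c, c + n)`.  The
B-spline upsampler maps HR voxel `j` to LR coordinate `j / factor`, so the
interpolant passes exactly through the LR samples — a half-voxel-shifted
(center-aligned) interpolation would handicap both the initialization and
the baseline against point-sampled data.

**Semi-convergence and the study protocol.**  Iterating regularization
against exact consistency is semi-convergent on noisy data: reconstruction
quality peaks within the first few iterations and then drifts down, because
the consistency step re-injects the sample noise which the next
regularization pass spreads through patch averages.  The bundled study
protocol (`make_study_config()`) therefore stops at `max_iter = 3` and uses
`decimator = "nn"` — the operator that actually produced the phantom's LR
data.  The package defaults keep the mean-consistency operator and the
`tol`-based stop for general use.

## The synthetic phantom

`make_fiber_phantom` emulates a structured crossing-fiber slab: five
parametric Bezier tubes (bending, crossing, and kissing geometry, one
out-of-plane) defined on a 16 x 16 x 5 structural reference frame and
rasterized onto any grid.  Each voxel inside a tube gains a fiber
compartment whose axis is the local centerline tangent; overlapping tubes
split the volume fraction equally (at most three populations per voxel).
Every tract is homogeneous: one FA target per tract, drawn uniformly from
[0.75, 0.90], realized by an axially symmetric tensor solved analytically
for the eigenvalue ratio at fixed mean diffusivity (0.7e-3 mm^2/s, also the
isotropic background ADC).

The forward signal is the multi-tensor Gaussian model
`S = S0 sum_c f_c exp(-b g^T D_c g)` on a 15-direction, b = 700 s/mm^2
hemisphere scheme (electrostatic repulsion from a seeded start, plus one
b = 0 volume).  Directions are ordered along a greedy nearest-angle path so
that volumes adjacent in acquisition order have correlated contrast — the
redundancy premise of the multi-direction search.  Magnitude noise is
Rician, `sqrt((S + e1)^2 + e2^2)` with `sd = S0 / SNR`.

Because a 16 x 16 x 5 grid cannot be halved along z, the ground-truth HR
volume is rasterized from the continuous fiber field at the factor-2
refined grid (32 x 32 x 10); nearest-neighbour decimation of it (after
optional Rician corruption) yields the observed 16 x 16 x 5 dataset.  The
reconstruction is scored against the 32 x 32 x 10 truth.

**What the phantom does not emulate:** spatially varying coil noise, EPI
distortion and motion, non-Gaussian diffusion (restriction, exchange),
partial-volume CSF, curved-tract fanning, or realistic anatomy-scale
self-similarity.  Passing tests therefore demonstrate the algebraic and
statistical correctness of the pipeline and its behavior under the stated
degradation model — not clinical image quality.

## Evaluation suite

* **PSNR** `20 log10(peak / rms error)`; `peak="auto"` uses the reference
  maximum.  Study summaries average over the weighted (b > 0) volumes only,
  because the unweighted volume of a noiseless phantom is constant and its
  PSNR infinite.
* **SSIM** with `c1 = (0.01 L)^2`, `c2 = (0.03 L)^2`; default 7 x 7 uniform
  sliding windows per axial slice (sample-normalized moments, matching the
  canonical reference implementation), plus a global-statistics variant.
* **Angular accuracy** `(180/pi) arccos |d_true . d_est|` per true fiber
  population against the closest estimated direction (a single-tensor fit
  yields one per voxel; crossing-voxel errors are means over populations).
  Distributions are summarized box-whisker style with the worst 2% set
  aside as outliers (floor(0.02 N) values).
* **DTI fit**: unweighted log-linear least squares for the six tensor
  entries plus ln S0, all voxels in one pseudo-inverse; voxels with any
  nonpositive measurement are flagged, never silently zeroed.  On the
  noiseless phantom the fit recovers single-fiber FA and axes essentially
  exactly (< 1e-6 relative / < 1e-6 degrees), which anchors the rest of the
  evaluation.  WLS/NLLS variants are deliberate non-goals; the fit is
  documented as swappable.

## Numerical choices

* HOSVD factors come from eigendecompositions of the mode Gram matrices
  (descending order); all correctness statements are about reconstructions
  and subspaces, never factor entries, since singular-vector signs and
  degenerate orders are conventions.
* Hard thresholding keeps coefficients strictly greater than `tau` (zero at
  equality), so `tau = 0` is the exact identity.
* `tau_d` uses strict inequality; at `sigma = 0` only exact duplicates are
  admitted, and the reference patch is always force-included first.
  Members are ordered by distance with a deterministic (volume, corner)
  tie-break.
* The production sweep groups stacks by size K and runs batched
  linear algebra plus bincount aggregation; a naive per-corner composition
  of the public operations is kept and tested as its oracle (agreement to
  1e-10).
* Uncovered voxels (possible only at stride > n) fall back to the input
  estimate.  Negative intensities created by the consistency correction are
  clipped to zero only at the final 4D assembly, since magnitude data is
  nonnegative.
* Determinism: gradient schemes, phantoms and noise are seeded; the loop
  itself has no randomness, so identical configs give bit-identical
  outputs.

## Findings recorded for transparency

* With block-mean consistency applied to point-sampled data the
  reconstruction is ~2 dB worse than with the matching operator — enforcing
  a constraint the truth does not satisfy is costly.  Choose the decimator
  that matches the actual degradation.
* On this phantom the multi-direction variant performs identically to the
  per-direction method: same-direction self-similarity saturates the
  `k_max = 32` stacks before any cross-direction candidate comes close
  enough.  The pooling machinery is exercised separately by tests with
  duplicated-direction datasets, where stacks demonstrably grow and
  accuracy does not degrade.  Gains from direction pooling are expected on
  data with weaker within-volume redundancy (real anatomy), not on a small
  self-similar phantom.

## Problem sizes

The bundled experiments run the full 16-volume, 32 x 32 x 10 reconstruction
(stride 1, ~4700 reference patches per volume-pass).  One study-protocol
run takes ~20-30 s on one CPU; the lambda sweep, the SNR 30 runs and the
HOSVD-M run together stay within a few minutes.
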