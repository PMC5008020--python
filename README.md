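# hosvdsr — patch-based HOSVD superresolution for diffusion-weighted MRI

Diffusion-weighted imaging (DWI) acquires one 3D volume per gradient
direction, and scan-time limits keep the spatial resolution low; the
resulting partial-volume mixing biases diffusion-tensor estimates, FA maps
and fiber directions.  `hosvdsr` reconstructs a high-resolution DWI dataset
from a single low-resolution acquisition: it is a single-image
superresolution tool for researchers working with DWI phantoms and
small-animal / in-vivo protocols, with a built-in synthetic crossing-fiber
phantom so the whole pipeline is testable without any data download.

## The method

The observed LR volume is modeled as `y = D H x + n` (D a factor-`f`
decimator, H taken as identity, n acquisition noise).  The HR estimate of
each gradient volume is refined iteratively:

1. **Nonlocal HOSVD regularization.**  Every reference patch `P_i`
   (`n × n × n`, default n = 5) is grouped with similar patches
   (`‖P_i − P‖² < τ_d = 3σ²n³`, windowed search) into a stack
   `Z ∈ R^{n×n×n×K}`.  The stack's high-order SVD
   `Z = S ×₁ U⁽¹⁾ ×₂ U⁽²⁾ ×₃ U⁽³⁾ ×₄ U⁽⁴⁾`
   provides an image-adaptive orthonormal basis; core coefficients with
   `|S_i| ≤ τ = σ√(2 ln(n³K))` are zeroed and the stack is re-synthesized.
   Overlapping patch estimates are averaged and blended with the current
   estimate using the balancing parameter λ (default 0.01; results are
   insensitive over [0.001, 0.2]).
2. **Subsampling consistency.**  `x ← x − NN(D x − y)`, with NN
   nearest-neighbour upsampling.  With the block-mean decimator every LR
   voxel equals the mean of its HR block exactly after each iteration; with
   the point-sampling decimator the observed samples are matched exactly.

The multi-direction variant (**HOSVD-M**) additionally searches the current
estimates of the `m` preceding/following gradient volumes in acquisition
order (window `M = 2m + 1`), exploiting inter-direction redundancy; only
patches from the volume being reconstructed are written back.

The evaluation suite implements PSNR, windowed SSIM, axial angular error
`θ = (180/π) arccos |d_true · d_est|` with 2%-outlier box-whisker
summaries, and a log-linear least-squares DTI fit with FA and
direction-encoded colormaps.  See `docs/methods.md` for assumptions,
parameter rationale, and known limitations.

## Worked example

Generate the bundled crossing-fiber phantom (five bending/crossing/kissing
tracts on a 16 × 16 × 5 slab, 15 directions at b = 700 s/mm², SNR 30
Rician noise, ground truth rasterized at 32 × 32 × 10), superresolve the
decimated observation, and score it:

```python
import numpy as np
import hosvdsr as h

study = h.make_study_phantom(seed=7, snr=30.0)     # hr, lr, fiber field
recon = h.superresolve(study.lr, h.make_study_config())
bspline = h.upsample_init(study.lr, 2, "bspline")

w = study.scheme.weighted_mask
def mean_psnr(test):
    return np.mean([h.psnr(study.hr.volume(v), test.volume(v))
                    for v in range(study.hr.n_volumes) if w[v]])

def mean_ang(test):
    return np.nanmean(h.angular_error_field(study.field, h.fit_dti(test)))

print(f"PSNR  hosvd {mean_psnr(recon):.2f} dB   bspline {mean_psnr(bspline):.2f} dB")
print(f"angle hosvd {mean_ang(recon):.2f} deg  bspline {mean_ang(bspline):.2f} deg")
```

prints

```
PSNR  hosvd 24.54 dB   bspline 24.42 dB
angle hosvd 10.04 deg  bspline 10.16 deg
```

— the HOSVD reconstruction recovers the ground-truth HR dataset more
faithfully than cubic B-spline interpolation (higher PSNR), and the fiber
axes fitted from it are closer to the true tract directions (lower mean
angular error).  The same comparison on the noiseless phantom gives
26.23 vs 26.12 dB and 8.85 vs 8.88 degrees.

The same pipeline is available from the shell:

```bash
hosvdsr phantom --shape 16,16,5 --directions 15 --bval 700 --snr 30 --seed 7 --out-prefix ph
hosvdsr superresolve --in ph_lr.nii.gz --bval ph_lr.bval --bvec ph_lr.bvec \
    --method hosvd --decimator nn --max-iter 3 --out hr.nii.gz
hosvdsr evaluate --ref ph_hr.nii.gz --test hr.nii.gz --bval ph_lr.bval \
    --bvec ph_lr.bvec --truth-fibers ph_fibers.txt --out-prefix eval
```

Every command writes a JSON manifest (config, input digests, timings,
convergence traces) next to its outputs.

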