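"""Quantitative evaluation: PSNR, SSIM, angular accuracy, and DTI fitting.

Angular accuracy compares fiber axes, which are sign-free: the error is
(180/pi) * arccos(|d_true . d_estimated|), bounded in [0, 90] degrees.  The
distribution over fiber voxels is summarized box-whisker style with the
worst 2% set aside as outliers.

The diffusion tensor fit is ordinary log-linear least squares,
ln S = ln S0 - b g^T D g, solved per voxel for the six unique tensor entries
plus ln S0; fractional anisotropy, the principal eigenvector and the
direction-encoded color (DEC) map derive from the fitted tensors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .phantom import FiberField
from .volume import DWIVolume

__all__ = [
    "BoxStats",
    "TensorFit",
    "psnr",
    "ssim",
    "angular_error",
    "angular_error_field",
    "summarize_errors",
    "fit_dti",
    "fa",
    "principal_direction",
    "fa_colormap",
    "metric_table",
]

PSNR_INFINITE = math.inf


# --------------------------------------------------------------------------
# image metrics
# --------------------------------------------------------------------------

def psnr(reference: np.ndarray, test: np.ndarray, peak: float | str = "auto") -> float:
    """Peak signal-to-noise ratio in dB; identical inputs return math.inf."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    if peak == "auto":
        peak = float(reference.max())
    peak = float(peak)
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return PSNR_INFINITE
    return 20.0 * math.log10(peak / math.sqrt(mse))


def _ssim_stats(x: np.ndarray, y: np.ndarray, win: int):
    # local sample means/variances/covariance via uniform filters, cropped
    # to windows fully inside the image
    npx = win ** x.ndim
    cov_norm = npx / (npx - 1)
    ux = uniform_filter(x, win)
    uy = uniform_filter(y, win)
    uxx = uniform_filter(x * x, win)
    uyy = uniform_filter(y * y, win)
    uxy = uniform_filter(x * y, win)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    cxy = cov_norm * (uxy - ux * uy)
    pad = win // 2
    crop = tuple(slice(pad, s - pad) for s in x.shape)
    return ux[crop], uy[crop], vx[crop], vy[crop], cxy[crop]


def _ssim_map(x: np.ndarray, y: np.ndarray, c1: float, c2: float, win: int) -> np.ndarray:
    ux, uy, vx, vy, cxy = _ssim_stats(x, y, win)
    return ((2 * ux * uy + c1) * (2 * cxy + c2)) / (
        (ux**2 + uy**2 + c1) * (vx + vy + c2)
    )


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    dynamic_range: float,
    mode: str = "local",
    win: int = 7,
) -> float:
    """Structural similarity with c1 = (0.01 L)^2, c2 = (0.03 L)^2.

    "local" computes the index in uniform win x win sliding windows on each
    axial (z) slice and averages over windows and slices; "global" evaluates
    the formula once from whole-volume statistics.  Identical inputs score
    exactly 1 in both modes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be positive")
    c1 = (0.01 * dynamic_range) ** 2
    c2 = (0.03 * dynamic_range) ** 2
    if mode == "global":
        ux, uy = x.mean(), y.mean()
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        cxy = float(np.mean((x - ux) * (y - uy)) * x.size / (x.size - 1))
        return float(
            ((2 * ux * uy + c1) * (2 * cxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
        )
    if mode != "local":
        raise ValueError("mode must be 'local' or 'global'")
    if x.ndim == 2:
        return float(_ssim_map(x, y, c1, c2, win).mean())
    if x.ndim == 3:
        vals = [_ssim_map(x[:, :, z], y[:, :, z], c1, c2, win).mean() for z in range(x.shape[2])]
        return float(np.mean(vals))
    raise ValueError("ssim expects a 2D or 3D array")


# --------------------------------------------------------------------------
# angular accuracy
# --------------------------------------------------------------------------

def angular_error(d_true: np.ndarray, d_estimated: np.ndarray) -> float:
    """Axially symmetric angle between two fiber axes, in degrees [0, 90]."""
    d_true = np.asarray(d_true, dtype=float).reshape(3)
    d_estimated = np.asarray(d_estimated, dtype=float).reshape(3)
    for v in (d_true, d_estimated):
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValueError("angular_error expects unit vectors")
    dot = abs(float(d_true @ d_estimated))
    return math.degrees(math.acos(min(dot, 1.0)))


def angular_error_field(truth: FiberField, fit: "TensorFit") -> np.ndarray:
    """Per-voxel mean angular error over the true fiber populations.

    Each true compartment is scored against the closest estimated direction
    (a single-tensor fit yields one per voxel); background voxels are NaN.
    Voxels whose fit is invalid or degenerate are also NaN.
    """
    if tuple(truth.shape) != tuple(fit.tensor.shape[:3]):
        raise ValueError("fiber field and tensor fit shapes differ")
    out = np.full(truth.shape, np.nan)
    for voxel, comps in truth.compartments.items():
        if not fit.ok[voxel]:
            continue
        d_est, degenerate = principal_direction(fit.tensor[voxel], return_degenerate=True)
        if degenerate:
            continue
        errs = [angular_error(c.direction, d_est) for c in comps]
        out[voxel] = float(np.mean(errs))
    return out


@dataclass(frozen=True)
class BoxStats:
    """Box-whisker summary with the worst fraction excluded as outliers."""

    mean: float
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "median": self.median,
            "q25": self.q25,
            "q75": self.q75,
            "whisker_low": self.whisker_low,
            "whisker_high": self.whisker_high,
            "n_outliers": len(self.outliers),
        }


def summarize_errors(errors, outlier_fraction: float = 0.02) -> BoxStats:
    """Exclude the floor(fraction*N) largest values, summarize the rest."""
    values = np.asarray([e for e in np.ravel(errors) if np.isfinite(e)], dtype=float)
    if values.size == 0:
        raise ValueError("summarize_errors needs a nonempty list")
    if not 0.0 <= outlier_fraction < 1.0:
        raise ValueError("outlier_fraction must lie in [0, 1)")
    n_out = int(math.floor(outlier_fraction * values.size))
    ordered = np.sort(values)
    retained = ordered[: values.size - n_out] if n_out else ordered
    outliers = ordered[values.size - n_out :] if n_out else ordered[:0]
    q25, med, q75 = np.percentile(retained, [25, 50, 75])
    return BoxStats(
        mean=float(retained.mean()),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_low=float(retained.min()),
        whisker_high=float(retained.max()),
        outliers=tuple(float(v) for v in outliers),
    )


# --------------------------------------------------------------------------
# DTI fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TensorFit:
    """Per-voxel symmetric tensors (mm^2/s), fitted S0, and validity flags."""

    tensor: np.ndarray  # (X, Y, Z, 3, 3)
    s0_est: np.ndarray  # (X, Y, Z)
    ok: np.ndarray      # (X, Y, Z) bool


def _design_matrix(scheme) -> np.ndarray:
    g = scheme.directions
    b = scheme.b_values
    return np.column_stack(
        [
            np.ones(len(scheme)),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_dti(dwi: DWIVolume) -> TensorFit:
    """Ordinary log-linear least-squares single-tensor fit, all voxels at once.

    Requires at least six weighted directions plus one unweighted volume.
    Voxels with any nonpositive measurement are flagged invalid and skipped;
    the rest are solved in one pseudo-inverse application.
    """
    scheme = dwi.scheme
    if scheme.n_weighted < 6 or not np.any(~scheme.weighted_mask):
        raise ValueError(
            "DTI fit needs >= 6 weighted directions and an unweighted volume"
        )
    x = _design_matrix(scheme)
    shape = dwi.spatial_shape
    flat = dwi.signal.reshape(-1, len(scheme))
    ok = np.all(flat > 0, axis=1)
    coefs = np.zeros((flat.shape[0], 7))
    if ok.any():
        logs = np.log(flat[ok])
        beta, *_ = np.linalg.lstsq(x, logs.T, rcond=None)  # (7, n_ok)
        coefs[ok] = beta.T
    tensor = np.zeros((flat.shape[0], 3, 3))
    dxx, dyy, dzz, dxy, dxz, dyz = (coefs[:, i] for i in range(1, 7))
    tensor[:, 0, 0], tensor[:, 1, 1], tensor[:, 2, 2] = dxx, dyy, dzz
    tensor[:, 0, 1] = tensor[:, 1, 0] = dxy
    tensor[:, 0, 2] = tensor[:, 2, 0] = dxz
    tensor[:, 1, 2] = tensor[:, 2, 1] = dyz
    s0 = np.exp(coefs[:, 0])
    s0[~ok] = 0.0
    return TensorFit(
        tensor=tensor.reshape(shape + (3, 3)),
        s0_est=s0.reshape(shape),
        ok=ok.reshape(shape),
    )


def fa(tensor: np.ndarray) -> float:
    """Fractional anisotropy of a symmetric 3x3 tensor, clamped to [0, 1]."""
    t = np.asarray(tensor, dtype=float)
    if t.shape != (3, 3) or not np.allclose(t, t.T, atol=1e-12):
        raise ValueError("fa expects a symmetric 3x3 tensor")
    lam = np.linalg.eigvalsh(t)
    norm = np.linalg.norm(lam)
    if norm == 0:
        return 0.0
    value = math.sqrt(1.5) * np.linalg.norm(lam - lam.mean()) / norm
    return float(min(max(value, 0.0), 1.0))


def principal_direction(
    tensor: np.ndarray, return_degenerate: bool = False
) -> np.ndarray | tuple[np.ndarray, bool]:
    """Unit eigenvector of the largest eigenvalue, first nonzero component > 0.

    The fit is flagged degenerate when the top two eigenvalues coincide to
    relative precision 1e-12; the sign convention still makes the returned
    vector deterministic.
    """
    t = np.asarray(tensor, dtype=float)
    if t.shape != (3, 3) or not np.allclose(t, t.T, atol=1e-12):
        raise ValueError("principal_direction expects a symmetric 3x3 tensor")
    w, v = np.linalg.eigh(t)
    vec = v[:, 2].copy()
    scale = max(abs(w[2]), abs(w[0]), 1e-300)
    degenerate = (w[2] - w[1]) < 1e-12 * scale
    for comp in vec:
        if comp != 0.0:
            if comp < 0:
                vec = -vec
            break
    vec /= np.linalg.norm(vec)
    if return_degenerate:
        return vec, bool(degenerate)
    return vec


def fa_colormap(fit: TensorFit) -> np.ndarray:
    """Direction-encoded color map: RGB = FA * |principal axis|, in [0, 1]."""
    shape = fit.tensor.shape[:3]
    rgb = np.zeros(shape + (3,))
    for voxel in np.ndindex(shape):
        if not fit.ok[voxel]:
            continue
        t = fit.tensor[voxel]
        f = fa(t)
        if f == 0.0:
            continue
        rgb[voxel] = f * np.abs(principal_direction(t))
    return np.clip(rgb, 0.0, 1.0)


# --------------------------------------------------------------------------
# convenience tables
# --------------------------------------------------------------------------

def metric_table(reference: DWIVolume, test: DWIVolume, ssim_mode: str = "local"):
    """Per-direction PSNR/SSIM between two 4D datasets (pandas DataFrame)."""
    import pandas as pd

    if reference.spatial_shape != test.spatial_shape or reference.n_volumes != test.n_volumes:
        raise ValueError("reference and test datasets must share shape")
    rows = []
    for v in range(reference.n_volumes):
        ref, tst = reference.volume(v), test.volume(v)
        rng = float(ref.max() - ref.min()) or 1.0
        rows.append(
            {
                "direction": v,
                "b_value": float(reference.scheme.b_values[v]),
                "psnr": psnr(ref, tst),
                "ssim": ssim(ref, tst, dynamic_range=rng, mode=ssim_mode),
            }
        )
    return pd.DataFrame(rows)
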