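"""High-order SVD (Tucker) transform of patch stacks and hard thresholding.

A stack of K similar patches is an order-3 (2D patches, n x n x K) or order-4
(3D patches, n x n x n x K) tensor Z.  Its HOSVD writes

    Z = S x_1 U1 x_2 U2 ... x_d Ud

with one orthonormal square factor per mode (the left singular vectors of the
mode unfolding) and a core coefficient tensor S.  Denoising keeps only the
coefficients whose magnitude exceeds the universal-style threshold

    tau = sigma * sqrt(2 * ln(p^d_patch * K))

(natural logarithm; p^d_patch is the voxel count of one patch) and inverts
the transform with the original factors.

Mode numbering is 0-based internally; mode j here is the (j+1)-th mode of the
usual 1-based tensor-product notation.  Unfolding places the selected mode
first and cycles the remaining modes in their original order (row-major),
i.e. ``unfold(T, m) = moveaxis(T, m, 0).reshape(dim_m, -1)``; ``fold`` is its
exact inverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HOSVDFactors",
    "unfold",
    "fold",
    "mode_product",
    "hosvd",
    "reconstruct",
    "compute_tau",
    "hard_threshold",
    "denoise_stack",
]


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-`mode` unfolding: shape (dim_mode, prod(other dims))."""
    tensor = np.asarray(tensor)
    if not 0 <= mode < tensor.ndim:
        raise ValueError(f"mode {mode} out of range for order-{tensor.ndim} tensor")
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def fold(matrix: np.ndarray, mode: int, shape: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given full shape."""
    shape = tuple(shape)
    if not 0 <= mode < len(shape):
        raise ValueError(f"mode {mode} out of range for shape {shape}")
    rest = [s for i, s in enumerate(shape) if i != mode]
    moved = np.asarray(matrix).reshape(shape[mode], *rest)
    return np.moveaxis(moved, 0, mode)


def mode_product(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Multiply `tensor` by `matrix` along `mode` (the mode-n product)."""
    tensor = np.asarray(tensor)
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise ValueError("mode_product needs a 2D matrix")
    if not 0 <= mode < tensor.ndim:
        raise ValueError(f"mode {mode} out of range for order-{tensor.ndim} tensor")
    if matrix.shape[1] != tensor.shape[mode]:
        raise ValueError(
            f"matrix has {matrix.shape[1]} columns but tensor mode {mode} "
            f"has size {tensor.shape[mode]}"
        )
    new_shape = list(tensor.shape)
    new_shape[mode] = matrix.shape[0]
    return fold(matrix @ unfold(tensor, mode), mode, tuple(new_shape))


@dataclass(frozen=True)
class HOSVDFactors:
    """Core coefficient tensor plus one orthonormal factor matrix per mode."""

    core: np.ndarray
    factors: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.factors) != np.ndim(self.core):
            raise ValueError("need exactly one factor matrix per core mode")
        for j, u in enumerate(self.factors):
            if u.shape != (self.core.shape[j], self.core.shape[j]):
                raise ValueError(f"factor {j} must be square matching core mode {j}")


def hosvd(stack: np.ndarray) -> HOSVDFactors:
    """Full HOSVD of an order-3 or order-4 tensor.

    Each factor is the complete set of left singular vectors of the
    corresponding mode unfolding (computed as eigenvectors of the mode Gram
    matrix, descending eigenvalue order); the core is the stack multiplied by
    every factor transpose.  Reconstruction is exact to round-off.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim not in (3, 4):
        raise ValueError(f"hosvd requires an order-3 or order-4 tensor, got {stack.ndim}")
    factors = []
    for j in range(stack.ndim):
        a = unfold(stack, j)
        gram = a @ a.T
        _, u = np.linalg.eigh(gram)
        factors.append(np.ascontiguousarray(u[:, ::-1]))  # descending
    core = stack
    for j, u in enumerate(factors):
        core = mode_product(core, u.T, j)
    return HOSVDFactors(core=core, factors=tuple(factors))


def reconstruct(factors: HOSVDFactors) -> np.ndarray:
    """Invert the HOSVD: core multiplied by each factor in its mode."""
    out = np.asarray(factors.core)
    for j, u in enumerate(factors.factors):
        out = mode_product(out, u, j)
    return out


def compute_tau(sigma: float, patch_voxels: int, k: int) -> float:
    """Hard threshold sigma * sqrt(2 ln(patch_voxels * K)), natural log."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    total = int(patch_voxels) * int(k)
    if total < 2:
        raise ValueError("patch_voxels * K must be at least 2")
    return float(sigma) * math.sqrt(2.0 * math.log(total))


def hard_threshold(core: np.ndarray, tau: float) -> np.ndarray:
    """Keep coefficients with |S_i| > tau, zero the rest (zero at equality)."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    core = np.asarray(core)
    return np.where(np.abs(core) > tau, core, 0.0)


def denoise_stack(stack: np.ndarray, sigma: float) -> np.ndarray:
    """HOSVD-transform a patch stack, hard-threshold the core, invert.

    The last mode is the stack mode (K patches); the leading modes are the
    patch axes, so the threshold uses p^2*K or p^3*K as the order dictates.
    With sigma = 0 this is the identity to round-off.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim not in (3, 4):
        raise ValueError("denoise_stack requires an order-3 or order-4 stack")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    f = hosvd(stack)
    patch_voxels = int(np.prod(stack.shape[:-1]))
    tau = compute_tau(sigma, patch_voxels, stack.shape[-1])
    kept = hard_threshold(f.core, tau)
    return reconstruct(HOSVDFactors(core=kept, factors=f.factors))
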