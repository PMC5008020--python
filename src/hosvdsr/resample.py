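"""Array-level decimation and upsampling operators.

These realize the degradation operator of the observation model
``y = D H x + n`` (here H = identity; D is either pure subsampling or a
block-mean) and the nearest-neighbour interpolation ``NN`` used both for
initialization and for lifting low-resolution residuals back to the
high-resolution grid.

Conventions: 3D arrays, factor applied to every spatial axis, decimation
phase fixed at offset 0 (the first voxel of each block).
"""

from __future__ import annotations

import numpy as np

__all__ = ["decimate_array", "nn_upsample_array", "check_divisible"]


def check_divisible(shape: tuple[int, ...], factor: int) -> None:
    if any(s % factor for s in shape):
        raise ValueError(f"spatial shape {shape} not divisible by factor {factor}")


def decimate_array(vol: np.ndarray, factor: int, mode: str = "nn") -> np.ndarray:
    """Downsample a 3D array by an integer factor along every axis.

    mode "nn" keeps every factor-th voxel (offset 0); "blockmean" replaces
    each factor^3 block by its arithmetic mean.
    """
    vol = np.asarray(vol, dtype=float)
    if vol.ndim != 3:
        raise ValueError("decimate_array expects a 3D array")
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    check_divisible(vol.shape, factor)
    if mode == "nn":
        return vol[::factor, ::factor, ::factor].copy()
    if mode == "blockmean":
        nx, ny, nz = (s // factor for s in vol.shape)
        return vol.reshape(nx, factor, ny, factor, nz, factor).mean(axis=(1, 3, 5))
    raise ValueError(f"unknown decimation mode {mode!r}")


def nn_upsample_array(vol: np.ndarray, factor: int) -> np.ndarray:
    """Replicate each voxel into a factor^3 block (nearest-neighbour)."""
    vol = np.asarray(vol, dtype=float)
    if vol.ndim != 3:
        raise ValueError("nn_upsample_array expects a 3D array")
    out = np.repeat(vol, factor, axis=0)
    out = np.repeat(out, factor, axis=1)
    return np.repeat(out, factor, axis=2)
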