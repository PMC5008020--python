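"""Nonlocal patch grouping and overlap aggregation.

For a reference patch P_i (cubic, n^3 voxels) the engine scans a Chebyshev
window around its corner — in the volume being reconstructed and optionally
in adjacent diffusion-direction volumes — and admits every candidate whose
squared Euclidean distance to P_i is strictly below

    tau_d = 3 * sigma^2 * n^e        (e = 3 for cubic patches by default)

The reference patch is always a member of its own stack.  Admitted patches
are stacked along a trailing mode (n x n x n x K) for the HOSVD estimator;
overlapping per-patch estimates are merged back by unweighted averaging.

Coordinates: voxel indices are 0-based; a patch with corner c covers the
half-open block [c, c + n) in every axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "PatchStack",
    "AggregationBuffer",
    "find_similar",
    "scatter_add",
    "finalize",
]


@dataclass(frozen=True)
class PatchStack:
    """K grouped patches: data (n, n, n, K), source locations, reference index.

    ``locations[k]`` is (volume_index, corner); the slice ``data[..., k]``
    equals the voxel content at that location.
    """

    data: np.ndarray
    locations: tuple[tuple[int, tuple[int, int, int]], ...]
    reference_index: int = 0

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[3] != len(self.locations):
            raise ValueError("data must be (n, n, n, K) matching locations")
        if not 0 <= self.reference_index < len(self.locations):
            raise ValueError("reference_index out of range")

    @property
    def k(self) -> int:
        return self.data.shape[3]


def tau_d(sigma: float, n: int, exponent: int = 3) -> float:
    """Similarity threshold 3 sigma^2 n^exponent (squared-distance scale)."""
    if exponent not in (2, 3):
        raise ValueError("tau_d exponent must be 2 or 3")
    return 3.0 * sigma * sigma * float(n) ** exponent


def find_similar(
    volumes: list[np.ndarray],
    center_volume: int,
    corner: tuple[int, int, int],
    n: int,
    sigma: float,
    search_radius: int = 5,
    k_max: int = 32,
    tau_d_exponent: int = 3,
) -> PatchStack:
    """Group up to k_max patches similar to the reference patch.

    Candidates are every in-bounds corner within Chebyshev distance
    ``search_radius`` of ``corner`` in every listed volume; a candidate is
    admitted when its squared distance to the reference is strictly below
    tau_d.  The reference patch is always first; the rest are sorted by
    distance ascending with a deterministic (volume, corner) tie-break, then
    truncated to ``k_max`` members total.
    """
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    if not 0 <= center_volume < len(volumes):
        raise ValueError("center_volume out of range")
    shape = volumes[center_volume].shape
    if any(n > s for s in shape):
        raise ValueError(f"patch edge {n} exceeds volume shape {shape}")
    corner = tuple(int(c) for c in corner)
    if any(c < 0 or c + n > s for c, s in zip(corner, shape)):
        raise ValueError(f"reference corner {corner} out of bounds for {shape}")

    ref = np.ascontiguousarray(volumes[center_volume][
        corner[0] : corner[0] + n,
        corner[1] : corner[1] + n,
        corner[2] : corner[2] + n,
    ])
    threshold = tau_d(sigma, n, tau_d_exponent)

    cand_dist: list[np.ndarray] = []
    cand_vol: list[np.ndarray] = []
    cand_corner: list[np.ndarray] = []
    for vi, vol in enumerate(volumes):
        if vol.shape != shape:
            raise ValueError("all searched volumes must share one shape")
        windows = sliding_window_view(vol, (n, n, n))
        lo = [max(0, c - search_radius) for c in corner]
        hi = [min(s - n, c + search_radius) for c, s in zip(corner, shape)]
        sub = windows[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
        d = ((sub - ref) ** 2).sum(axis=(3, 4, 5))
        keep = d < threshold
        if vi == center_volume:
            # the reference itself is force-included separately
            ri = tuple(c - l for c, l in zip(corner, lo))
            keep[ri] = False
        if not keep.any():
            continue
        w = np.argwhere(keep)
        cand_dist.append(d[keep])
        cand_vol.append(np.full(len(w), vi))
        cand_corner.append(w + np.array(lo))

    locations: list[tuple[int, tuple[int, int, int]]] = [(center_volume, corner)]
    patches: list[np.ndarray] = [ref]
    if cand_dist:
        dist = np.concatenate(cand_dist)
        vols_idx = np.concatenate(cand_vol)
        corners = np.concatenate(cand_corner)
        # candidates were generated in (volume, corner) row-major order, so a
        # stable sort on distance realizes the (distance, volume, corner) rule
        order = np.argsort(dist, kind="stable")
        for j in order[: k_max - 1]:
            vi = int(vols_idx[j])
            c = tuple(int(x) for x in corners[j])
            locations.append((vi, c))
            patches.append(
                volumes[vi][c[0] : c[0] + n, c[1] : c[1] + n, c[2] : c[2] + n]
            )
    data = np.stack(patches, axis=-1).astype(float)
    return PatchStack(data=data, locations=tuple(locations), reference_index=0)


@dataclass
class AggregationBuffer:
    """Sum and hit-count grids for averaging overlapping patch estimates."""

    accumulator: np.ndarray
    weight: np.ndarray

    @classmethod
    def zeros(cls, shape: tuple[int, int, int]) -> "AggregationBuffer":
        return cls(np.zeros(shape), np.zeros(shape))


def scatter_add(
    buffer: AggregationBuffer, patch: np.ndarray, corner: tuple[int, int, int]
) -> AggregationBuffer:
    """Accumulate one patch estimate over its footprint (weight += 1)."""
    n = patch.shape
    shape = buffer.accumulator.shape
    if any(c < 0 or c + e > s for c, e, s in zip(corner, n, shape)):
        raise ValueError(f"patch at {corner} with shape {n} out of bounds for {shape}")
    sl = tuple(slice(c, c + e) for c, e in zip(corner, n))
    buffer.accumulator[sl] += patch
    buffer.weight[sl] += 1.0
    return buffer


def finalize(buffer: AggregationBuffer, fallback: np.ndarray) -> np.ndarray:
    """Average accumulated estimates; uncovered voxels fall back unchanged."""
    if fallback.shape != buffer.accumulator.shape:
        raise ValueError("fallback shape must match the buffer")
    covered = buffer.weight > 0
    out = np.array(fallback, dtype=float, copy=True)
    out[covered] = buffer.accumulator[covered] / buffer.weight[covered]
    return out
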