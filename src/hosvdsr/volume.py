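"""Core in-memory containers for diffusion-weighted data.

A diffusion-weighted acquisition is a 4D signal grid (three spatial axes plus
one axis per applied gradient) together with the gradient table that produced
it: per volume, a unit gradient direction ``g`` and a diffusion weighting
``b`` (s/mm^2).  An unweighted (b = 0) volume carries no direction; its table
entry is the zero vector by the usual FSL convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GradientScheme", "DWIVolume"]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class GradientScheme:
    """Gradient table: unit directions and b-values, one entry per volume.

    Parameters
    ----------
    directions
        (N, 3) array.  Rows with b > 0 must be unit vectors (norm 1 within
        1e-9); rows with b = 0 may be the zero vector (unweighted volume).
    b_values
        (N,) nonnegative array, s/mm^2.
    includes_b0
        True when the scheme carries a leading unweighted volume.
    """

    directions: np.ndarray
    b_values: np.ndarray
    includes_b0: bool = False

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        b = np.atleast_1d(np.asarray(self.b_values, dtype=float))
        if d.shape != (b.size, 3):
            raise ValueError(
                f"directions shape {d.shape} inconsistent with {b.size} b-values"
            )
        if np.any(b < 0):
            raise ValueError("b-values must be nonnegative")
        norms = np.linalg.norm(d, axis=1)
        weighted = b > 0
        if np.any(np.abs(norms[weighted] - 1.0) > _UNIT_TOL):
            raise ValueError("weighted gradient directions must have unit norm")
        # b = 0 rows: zero vector or unit vector, nothing in between.
        zero_ok = (norms[~weighted] < _UNIT_TOL) | (
            np.abs(norms[~weighted] - 1.0) <= _UNIT_TOL
        )
        if not np.all(zero_ok):
            raise ValueError("b=0 directions must be zero or unit vectors")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "b_values", b)

    def __len__(self) -> int:
        return int(self.b_values.size)

    @property
    def weighted_mask(self) -> np.ndarray:
        """Boolean mask of diffusion-weighted (b > 0) volumes."""
        return self.b_values > 0

    @property
    def n_weighted(self) -> int:
        return int(np.count_nonzero(self.weighted_mask))


@dataclass(frozen=True)
class DWIVolume:
    """4D diffusion-weighted signal grid with geometry and gradient table.

    ``signal`` has axes (x, y, z, volume); the last axis length must equal the
    gradient scheme length and every sample is nonnegative (magnitude data).
    """

    signal: np.ndarray
    voxel_size: np.ndarray
    scheme: GradientScheme = field(repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.signal, dtype=float)
        if s.ndim != 4:
            raise ValueError(f"signal must be 4D, got ndim={s.ndim}")
        if s.shape[3] != len(self.scheme):
            raise ValueError(
                f"signal has {s.shape[3]} volumes but scheme has {len(self.scheme)}"
            )
        if np.any(s < 0):
            raise ValueError("signal must be nonnegative")
        vs = np.asarray(self.voxel_size, dtype=float).reshape(3)
        if np.any(vs <= 0):
            raise ValueError("voxel size must be positive")
        object.__setattr__(self, "signal", s)
        object.__setattr__(self, "voxel_size", vs)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[3]

    def volume(self, index: int) -> np.ndarray:
        """3D view of one gradient volume."""
        return self.signal[..., index]

    def with_signal(self, signal: np.ndarray) -> "DWIVolume":
        """New DWIVolume sharing geometry/scheme with replaced signal."""
        return DWIVolume(signal=signal, voxel_size=self.voxel_size, scheme=self.scheme)
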