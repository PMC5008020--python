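"""Synthetic crossing-fiber DWI phantoms and degradation operators.

The generator emulates a structured fiber field in the style of the 2012
HARDI reconstruction challenge: a small slab (16 x 16 x 5 structural frame)
crossed by several fiber bundles with bending, crossing and kissing
geometry.  Bundles are parametric Bezier tubes; every voxel inside a tube
receives one fiber compartment whose direction is the local centerline
tangent and whose axially symmetric diffusion tensor is solved to hit a
target fractional anisotropy drawn uniformly from a configured range
(default [0.75, 0.90]).

The forward signal is the standard multi-tensor Gaussian model

    S(g, b) = S0 * sum_c f_c * exp(-b g^T D_c g)

with isotropic background diffusion outside the bundles.  Magnitude noise is
Rician: S -> sqrt((S + e1)^2 + e2^2) with Gaussian e1, e2 of standard
deviation S0 / SNR.  The degradation operator is integer-factor decimation,
either pure subsampling (offset 0) or block means.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.spatial.distance import cdist

from .resample import decimate_array
from .volume import DWIVolume, GradientScheme

__all__ = [
    "FiberCompartment",
    "FiberField",
    "BundleSpec",
    "default_bundles",
    "make_gradient_scheme",
    "make_fiber_phantom",
    "tensor_from_fa",
    "fa_of_eigenvalues",
    "simulate_dwi",
    "add_rician_noise",
    "decimate",
    "StudyPhantom",
    "make_study_phantom",
]

_REFERENCE_SHAPE = (16.0, 16.0, 5.0)


# --------------------------------------------------------------------------
# gradient scheme
# --------------------------------------------------------------------------

def make_gradient_scheme(
    n_directions: int,
    b_value: float,
    seed: int = 0,
    include_b0: bool = False,
) -> GradientScheme:
    """Approximately uniform hemisphere directions by electrostatic repulsion.

    Directions are parametrized by spherical angles and the antipodally
    symmetric Coulomb-type energy sum_{i<j} 1/|di-dj|^2 + 1/|di+dj|^2 is
    minimized (L-BFGS-B) from a seeded random start, so the scheme is
    deterministic given the seed.  All directions are mapped to the upper
    hemisphere.  With ``include_b0`` a leading unweighted volume (zero
    vector, b = 0) is prepended.
    """
    if n_directions < 6:
        raise ValueError("need at least 6 directions for a tensor fit downstream")
    if b_value <= 0:
        raise ValueError("b_value must be positive")
    rng = np.random.default_rng(seed)
    v0 = rng.normal(size=(n_directions, 3))
    v0 /= np.linalg.norm(v0, axis=1, keepdims=True)
    theta0 = np.arccos(np.clip(v0[:, 2], -1, 1))
    phi0 = np.arctan2(v0[:, 1], v0[:, 0])

    def _points(x: np.ndarray) -> np.ndarray:
        th, ph = x[:n_directions], x[n_directions:]
        st = np.sin(th)
        return np.column_stack([st * np.cos(ph), st * np.sin(ph), np.cos(th)])

    def _energy(x: np.ndarray) -> float:
        p = _points(x)
        diff = p[:, None, :] - p[None, :, :]
        summ = p[:, None, :] + p[None, :, :]
        d2 = (diff**2).sum(-1)
        s2 = (summ**2).sum(-1)
        iu = np.triu_indices(n_directions, 1)
        return float((1.0 / d2[iu]).sum() + (1.0 / s2[iu]).sum())

    res = minimize(
        _energy,
        np.concatenate([theta0, phi0]),
        method="L-BFGS-B",
        options={"maxiter": 500},
    )
    pts = _points(res.x)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    flip = pts[:, 2] < 0
    pts[flip] *= -1.0
    # order along a greedy nearest-angle path so that volumes adjacent in
    # acquisition order have similar diffusion contrast (the redundancy the
    # multi-direction search exploits); start from the most axial direction
    order = [int(np.argmax(pts[:, 2]))]
    remaining = set(range(n_directions)) - set(order)
    while remaining:
        last = pts[order[-1]]
        nxt = max(remaining, key=lambda i: (abs(float(pts[i] @ last)), -i))
        order.append(nxt)
        remaining.discard(nxt)
    directions = pts[order]
    b_values = np.full(n_directions, float(b_value))
    if include_b0:
        directions = np.vstack([np.zeros(3), directions])
        b_values = np.concatenate([[0.0], b_values])
    return GradientScheme(directions=directions, b_values=b_values, includes_b0=include_b0)


# --------------------------------------------------------------------------
# fiber field
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberCompartment:
    """One fiber population in a voxel: axis, volume fraction, tensor."""

    direction: np.ndarray
    fraction: float
    tensor: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or abs(n - 1.0) > 1e-9:
            raise ValueError("compartment direction must be a unit vector")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("volume fraction must lie in [0, 1]")
        if self.tensor is not None:
            t = np.asarray(self.tensor, dtype=float).reshape(3, 3)
            if not np.allclose(t, t.T, atol=1e-15):
                raise ValueError("diffusion tensor must be symmetric")
            w = np.linalg.eigvalsh(t)
            if np.any(w <= 0):
                raise ValueError("diffusion tensor must be positive definite")
            object.__setattr__(self, "tensor", t)
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class FiberField:
    """Per-voxel fiber compartments on a 3D grid; absent voxels are background."""

    shape: tuple[int, int, int]
    compartments: dict[tuple[int, int, int], list[FiberCompartment]] = dc_field(
        repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        for voxel, comps in self.compartments.items():
            if not 1 <= len(comps) <= 3:
                raise ValueError(f"voxel {voxel} has {len(comps)} compartments")
            total = sum(c.fraction for c in comps)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"voxel {voxel} fractions sum to {total}")
            if any(not 0 <= voxel[a] < self.shape[a] for a in range(3)):
                raise ValueError(f"voxel {voxel} outside grid {self.shape}")

    @property
    def fiber_voxels(self) -> list[tuple[int, int, int]]:
        return sorted(self.compartments)

    def n_compartments(self, voxel: tuple[int, int, int]) -> int:
        return len(self.compartments.get(voxel, ()))


@dataclass(frozen=True)
class BundleSpec:
    """A fiber bundle: Bezier centerline control points plus a tube radius.

    Control points and radius live in the 16 x 16 x 5 structural reference
    frame; rasterization rescales them to the target grid, so one spec
    produces the same continuous geometry at any resolution.
    """

    control_points: np.ndarray
    radius: float = 1.6

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.control_points, dtype=float))
        if p.shape[0] < 2 or p.shape[1] != 3:
            raise ValueError("control_points must be (P>=2, 3)")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        object.__setattr__(self, "control_points", p)

    def sample(self, n: int = 256) -> tuple[np.ndarray, np.ndarray]:
        """Densely sample the Bezier curve; returns (points, unit tangents)."""
        t = np.linspace(0.0, 1.0, n)
        pts = _bezier(self.control_points, t)
        dcp = self.control_points[1:] - self.control_points[:-1]
        tan = _bezier(dcp, t) if len(dcp) > 1 else np.broadcast_to(dcp[0], (n, 3)).copy()
        norms = np.linalg.norm(tan, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return pts, tan / norms


def _bezier(cp: np.ndarray, t: np.ndarray) -> np.ndarray:
    # de Casteljau, vectorized over t
    pts = np.broadcast_to(cp[None, :, :], (t.size, cp.shape[0], 3)).copy()
    while pts.shape[1] > 1:
        pts = (1 - t)[:, None, None] * pts[:, :-1] + t[:, None, None] * pts[:, 1:]
    return pts[:, 0, :]


def default_bundles() -> list[BundleSpec]:
    """Five bundles with bending, crossing and kissing geometry."""
    return [
        # in-plane bending arc
        BundleSpec(np.array([[0.5, 9.0, 2.5], [8.0, 16.5, 2.5], [15.5, 9.0, 2.5]])),
        # straight diagonal crossing the arc
        BundleSpec(np.array([[0.5, 0.5, 2.5], [15.5, 15.5, 2.5]])),
        # straight bundle along x in a lower slice
        BundleSpec(np.array([[0.5, 4.0, 1.2], [15.5, 4.0, 1.2]]), radius=1.4),
        # bending bundle dipping toward the straight one (kissing/crossing)
        BundleSpec(np.array([[0.5, 12.0, 1.2], [8.0, 0.0, 1.2], [15.5, 12.0, 1.2]]), radius=1.4),
        # out-of-plane bundle along y with varying depth
        BundleSpec(np.array([[11.5, 0.5, 0.8], [11.5, 8.0, 2.8], [11.5, 15.5, 4.2]]), radius=1.4),
    ]


def fa_of_eigenvalues(eigenvalues: np.ndarray) -> float:
    lam = np.asarray(eigenvalues, dtype=float)
    norm = np.linalg.norm(lam)
    if norm == 0:
        return 0.0
    dev = lam - lam.mean()
    return float(np.sqrt(1.5) * np.linalg.norm(dev) / norm)


@lru_cache(maxsize=4096)
def _perp_ratio(fa: float) -> float:
    def _gap(r: float) -> float:
        return fa_of_eigenvalues(np.array([1.0, r, r])) - fa

    return brentq(_gap, 1e-9, 1.0 - 1e-12, xtol=1e-15)


def tensor_from_fa(direction: np.ndarray, fa: float, md: float = 0.7e-3) -> np.ndarray:
    """Axially symmetric 3x3 tensor with given principal axis, FA and MD.

    Solves the perpendicular/parallel eigenvalue ratio r so that the
    analytic FA of (1, r, r) equals the target, then scales to the mean
    diffusivity (mm^2/s).
    """
    if not 0 < fa < 1:
        raise ValueError("target FA must lie strictly inside (0, 1)")
    d = np.asarray(direction, dtype=float).reshape(3)
    d = d / np.linalg.norm(d)
    r = _perp_ratio(float(fa))
    lam_par = 3.0 * md / (1.0 + 2.0 * r)
    lam_perp = r * lam_par
    return lam_perp * np.eye(3) + (lam_par - lam_perp) * np.outer(d, d)


def make_fiber_phantom(
    shape: tuple[int, int, int] = (16, 16, 5),
    bundle_specs: list[BundleSpec] | None = None,
    fa_range: tuple[float, float] = (0.75, 0.90),
    seed: int = 0,
    md: float = 0.7e-3,
) -> FiberField:
    """Rasterize parametric fiber bundles into a per-voxel compartment field.

    A voxel whose center lies within a bundle's tube radius gains one
    compartment with the local tangent as its axis; multiple overlapping
    bundles split the voxel's volume fraction equally.  Each tract is
    homogeneous: its FA is drawn once, uniformly from ``fa_range`` (i.i.d.
    per-voxel anisotropy would put noise-like texture into the ground truth
    that real tissue does not have).
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 4 for s in shape):
        raise ValueError("shape must be 3D with every dimension >= 4")
    lo, hi = fa_range
    if not 0.0 < lo < hi < 1.0:
        raise ValueError("fa_range must be an interval inside (0, 1)")
    specs = default_bundles() if bundle_specs is None else list(bundle_specs)
    if not specs:
        raise ValueError("need at least one bundle")
    rng = np.random.default_rng(seed)

    # voxel centers in the reference frame
    scale = np.array(_REFERENCE_SHAPE) / np.array(shape, dtype=float)
    idx = np.indices(shape).reshape(3, -1).T
    centers = (idx + 0.5) * scale

    bundle_fa = rng.uniform(lo, hi, size=len(specs))
    per_voxel: dict[tuple[int, int, int], list[tuple[np.ndarray, float]]] = {}
    for spec, fa in zip(specs, bundle_fa):
        pts, tans = spec.sample(max(256, 8 * max(shape)))
        d2 = cdist(centers, pts, "sqeuclidean")
        nearest = d2.argmin(axis=1)
        dist = np.sqrt(d2[np.arange(len(centers)), nearest])
        inside = dist < spec.radius
        if not inside.any():
            raise ValueError("a bundle lies entirely outside the grid")
        for flat in np.nonzero(inside)[0]:
            voxel = tuple(int(v) for v in idx[flat])
            per_voxel.setdefault(voxel, []).append((tans[nearest[flat]], float(fa)))

    compartments: dict[tuple[int, int, int], list[FiberCompartment]] = {}
    for voxel, entries in per_voxel.items():
        entries = entries[:3]  # at most three populations per voxel
        frac = 1.0 / len(entries)
        comps = []
        for tangent, fa in entries:
            t = tangent / np.linalg.norm(tangent)
            comps.append(
                FiberCompartment(direction=t, fraction=frac, tensor=tensor_from_fa(t, fa, md))
            )
        compartments[voxel] = comps
    return FiberField(shape=shape, compartments=compartments)


# --------------------------------------------------------------------------
# signal simulation and degradation
# --------------------------------------------------------------------------

def simulate_dwi(
    field: FiberField,
    scheme: GradientScheme,
    s0: float = 100.0,
    background_adc: float = 0.7e-3,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> DWIVolume:
    """Multi-tensor Gaussian forward model on the fiber field.

    Per voxel and gradient (g, b): S = s0 * sum_c f_c exp(-b g^T D_c g);
    background voxels diffuse isotropically with ``background_adc``.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    g = scheme.directions
    b = scheme.b_values
    n = len(scheme)
    bg = s0 * np.exp(-b * background_adc)  # b = 0 rows reduce to s0
    signal = np.empty(field.shape + (n,), dtype=float)
    signal[...] = bg
    for voxel, comps in field.compartments.items():
        s = np.zeros(n)
        for c in comps:
            quad = np.einsum("ni,ij,nj->n", g, c.tensor, g)
            s += c.fraction * np.exp(-b * quad)
        signal[voxel] = s0 * s
    return DWIVolume(signal=signal, voxel_size=voxel_size, scheme=scheme)


def add_rician_noise(dwi: DWIVolume, snr: float, seed: int = 0, s0: float | None = None) -> DWIVolume:
    """Corrupt magnitude data with Rician noise of sd = s0 / SNR.

    ``s0`` defaults to the mean of the unweighted (b = 0) volumes, falling
    back to the signal maximum when the scheme carries no b = 0 volume.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if s0 is None:
        b0 = ~dwi.scheme.weighted_mask
        s0 = float(dwi.signal[..., b0].mean()) if b0.any() else float(dwi.signal.max())
    sigma = s0 / snr
    rng = np.random.default_rng(seed)
    e1 = rng.normal(scale=1.0, size=dwi.signal.shape)
    e2 = rng.normal(scale=1.0, size=dwi.signal.shape)
    noisy = np.sqrt((dwi.signal + sigma * e1) ** 2 + (sigma * e2) ** 2)
    return dwi.with_signal(noisy)


def decimate(dwi: DWIVolume, factor: int, mode: str = "nn") -> DWIVolume:
    """Decimate every gradient volume spatially; voxel size scales by factor."""
    vols = [decimate_array(dwi.volume(i), factor, mode) for i in range(dwi.n_volumes)]
    return DWIVolume(
        signal=np.stack(vols, axis=-1),
        voxel_size=dwi.voxel_size * factor,
        scheme=dwi.scheme,
    )


# --------------------------------------------------------------------------
# the study phantom: ground-truth HR + decimated LR observation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyPhantom:
    """Ground-truth HR volume, LR observation, and the generating fiber field."""

    hr: DWIVolume
    lr: DWIVolume
    field: FiberField
    scheme: GradientScheme
    snr: float | None


def make_study_config(**overrides) -> "SRConfig":
    """Algorithm configuration of the crossing-fiber superresolution study.

    The observed dataset is produced by nearest-neighbour (point-sampling)
    decimation, so the consistency correction uses the matching "nn"
    decimator; the iteration is stopped after three rounds because the
    regularize/correct loop semi-converges (reconstruction quality peaks
    within the first few iterations, then drifts as the consistency step
    keeps re-injecting sample noise that the regularizer re-spreads).
    Everything else is at package defaults; keyword overrides win.
    """
    from .pipeline import SRConfig

    params = {"decimator": "nn", "max_iter": 3}
    params.update(overrides)
    return SRConfig(**params)


def make_study_phantom(
    seed: int = 7,
    structural_shape: tuple[int, int, int] = (16, 16, 5),
    n_directions: int = 15,
    b_value: float = 700.0,
    snr: float | None = None,
    factor: int = 2,
    s0: float = 100.0,
) -> StudyPhantom:
    """Build the crossing-fiber superresolution experiment.

    The fiber field is rasterized on the factor-refined grid (default
    32 x 32 x 10) to serve as ground truth; nearest-neighbour decimation of
    it (after optional Rician corruption at the given SNR) yields the
    observed dataset at the structural 16 x 16 x 5 scale.  The gradient
    scheme has ``n_directions`` weighted volumes plus one leading b = 0.
    """
    scheme = make_gradient_scheme(n_directions, b_value, seed=seed, include_b0=True)
    hr_shape = tuple(int(s) * factor for s in structural_shape)
    field = make_fiber_phantom(shape=hr_shape, seed=seed)
    hr = simulate_dwi(field, scheme, s0=s0, voxel_size=(1.0, 1.0, 1.0))
    observed = hr if snr is None else add_rician_noise(hr, snr, seed=seed + 1, s0=s0)
    lr = decimate(observed, factor, mode="nn")
    return StudyPhantom(hr=hr, lr=lr, field=field, scheme=scheme, snr=snr)
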