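"""Readers and writers: NIfTI-1 volumes, FSL bval/bvec tables, fiber tables.

Conventions: the NIfTI affine is diagonal in the voxel size (the package
carries no orientation information beyond that); .bval is one space-separated
row, .bvec three rows (x, y, z components per volume).  Signal data is
stored as float32.  A plain-text fiber table records ground-truth fiber
populations (voxel index, compartment number, axis components, fraction).
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import FiberCompartment, FiberField
from .volume import DWIVolume, GradientScheme

__all__ = [
    "read_dwi",
    "write_dwi",
    "read_gradients",
    "write_gradients",
    "write_fiber_table",
    "read_fiber_table",
    "write_manifest",
]


def read_gradients(bval_path, bvec_path) -> GradientScheme:
    b = np.atleast_1d(np.loadtxt(bval_path, dtype=float))
    g = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if g.shape[0] != 3 and g.shape[1] == 3:
        g = g.T
    if g.shape[0] != 3 or g.shape[1] != b.size:
        raise ValueError(
            f"gradient table mismatch: {b.size} b-values vs bvec shape {g.shape}"
        )
    directions = g.T.copy()
    norms = np.linalg.norm(directions, axis=1)
    weighted = b > 0
    bad = weighted & (np.abs(norms - 1.0) > 1e-6)
    if bad.any():
        warnings.warn(
            f"renormalizing {int(bad.sum())} non-unit gradient direction(s)",
            stacklevel=2,
        )
    renorm = weighted & (norms > 0)
    directions[renorm] /= norms[renorm, None]
    return GradientScheme(
        directions=directions, b_values=b, includes_b0=bool((~weighted).any())
    )


def write_gradients(scheme: GradientScheme, bval_path, bvec_path) -> None:
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in scheme.b_values) + "\n")
    with open(bvec_path, "w") as fh:
        for axis in range(3):
            fh.write(" ".join(f"{v:.12g}" for v in scheme.directions[:, axis]) + "\n")


def read_dwi(nifti_path, bval_path, bvec_path) -> DWIVolume:
    """Load a 4D NIfTI with its FSL-dialect gradient table."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{nifti_path}: expected 4D data, got ndim={data.ndim}")
    scheme = read_gradients(bval_path, bvec_path)
    if data.shape[3] != len(scheme):
        raise ValueError(
            f"{nifti_path} has {data.shape[3]} volumes but the gradient table "
            f"has {len(scheme)} entries"
        )
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return DWIVolume(
        signal=np.clip(data, 0.0, None), voxel_size=voxel_size, scheme=scheme
    )


def write_dwi(dwi: DWIVolume, prefix) -> dict[str, Path]:
    """Write {prefix}.nii.gz, {prefix}.bval, {prefix}.bvec; returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(dwi.voxel_size) + [1.0])
    img = nib.Nifti1Image(dwi.signal.astype(np.float32), affine)
    img.header.set_zooms(tuple(dwi.voxel_size) + (1.0,))
    paths = {
        "nifti": Path(str(prefix) + ".nii.gz"),
        "bval": Path(str(prefix) + ".bval"),
        "bvec": Path(str(prefix) + ".bvec"),
    }
    nib.save(img, str(paths["nifti"]))
    write_gradients(dwi.scheme, paths["bval"], paths["bvec"])
    return paths


def write_fiber_table(field: FiberField, path) -> None:
    """Ground-truth fiber table: i j k compartment dx dy dz fraction."""
    with open(path, "w") as fh:
        fh.write(f"# shape {field.shape[0]} {field.shape[1]} {field.shape[2]}\n")
        fh.write("# i j k compartment dx dy dz fraction\n")
        for voxel in field.fiber_voxels:
            for ci, comp in enumerate(field.compartments[voxel]):
                d = comp.direction
                fh.write(
                    f"{voxel[0]} {voxel[1]} {voxel[2]} {ci} "
                    f"{d[0]:.12g} {d[1]:.12g} {d[2]:.12g} {comp.fraction:.12g}\n"
                )


def read_fiber_table(path) -> FiberField:
    """Read a fiber table back (directions and fractions; no tensors)."""
    shape = None
    compartments: dict[tuple[int, int, int], list[FiberCompartment]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "shape":
                    shape = tuple(int(p) for p in parts[1:4])
                continue
            f = line.split()
            voxel = (int(f[0]), int(f[1]), int(f[2]))
            comp = FiberCompartment(
                direction=np.array([float(f[4]), float(f[5]), float(f[6])]),
                fraction=float(f[7]),
            )
            compartments.setdefault(voxel, []).append(comp)
    if shape is None:
        raise ValueError(f"{path}: missing '# shape' header line")
    return FiberField(shape=shape, compartments=compartments)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path,
    config: dict,
    inputs: dict[str, str | Path] | None = None,
    outputs: dict[str, str | Path] | None = None,
    timings: dict[str, float] | None = None,
    extra: dict | None = None,
) -> None:
    """Atomically write a reproducibility manifest next to CLI outputs."""
    from . import __version__

    manifest = {
        "package": "hosvdsr",
        "version": __version__,
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256": _digest(p)}
            for name, p in (inputs or {}).items()
        },
        "outputs": {name: str(p) for name, p in (outputs or {}).items()},
        "timings_s": timings or {},
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, path)
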