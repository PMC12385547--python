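"""NIfTI / FSL-style bvals+bvecs input-output for 2-D DWI stacks.

A stack is written as a single 3-D NIfTI with volumes along the third axis
and the 2-D slice geometry in the header, plus whitespace-separated
``bvals`` / ``bvecs`` text files in the FSL convention (bvecs: three rows of
x, y, z components; zero vectors for b0 volumes).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .stack import DWIStack, VolumeInfo
from .tensor import DiffusionScheme

__all__ = ["save_stack", "load_stack", "save_map"]


def save_stack(
    stack: DWIStack, scheme: DiffusionScheme, outdir, stem: str = "dwi"
) -> dict[str, Path]:
    """Write an uncompressed NIfTI plus bvals/bvecs text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([stack.spacing[1], stack.spacing[0], 1.0, 1.0])
    img = nib.Nifti1Image(stack.voxels.astype(np.float32), affine)
    img.header.set_zooms((stack.spacing[1], stack.spacing[0], 1.0))
    nii_path = outdir / f"{stem}.nii"
    nib.save(img, nii_path)

    units = scheme.unit_directions
    bvals, bvecs = [], []
    for v in stack.volumes:
        if v.direction_index == 0:
            bvals.append(0.0)
            bvecs.append((0.0, 0.0, 0.0))
        else:
            bvals.append(v.b)
            bvecs.append(tuple(units[v.direction_index - 1]))
    bvals_path = outdir / f"{stem}.bval"
    bvecs_path = outdir / f"{stem}.bvec"
    np.savetxt(bvals_path, np.asarray(bvals)[None, :], fmt="%.1f")
    np.savetxt(bvecs_path, np.asarray(bvecs).T, fmt="%.6f")
    return {"nifti": nii_path, "bvals": bvals_path, "bvecs": bvecs_path}


def load_stack(nifti_path, bvals_path, bvecs_path) -> tuple[DWIStack, DiffusionScheme]:
    """Read a stack written by :func:`save_stack` (or equivalent FSL layout)."""
    img = nib.load(str(nifti_path))
    voxels = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[1]), float(zooms[0]))
    bvals = np.atleast_1d(np.loadtxt(bvals_path)).ravel()
    bvecs = np.atleast_2d(np.loadtxt(bvecs_path))
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if voxels.shape[2] != bvals.size:
        raise ValueError("volume count mismatch between NIfTI and bvals")

    dwi_sel = bvals > 0
    uniq: list[tuple[float, ...]] = []
    dir_index = np.zeros(bvals.size, dtype=int)
    for i in np.nonzero(dwi_sel)[0]:
        key = tuple(np.round(bvecs[i], 6))
        if key not in uniq:
            uniq.append(key)
        dir_index[i] = uniq.index(key) + 1
    reps: dict[int, int] = {}
    volumes = []
    for i in range(bvals.size):
        j = dir_index[i]
        rep = reps.get(j, 0)
        reps[j] = rep + 1
        volumes.append(VolumeInfo(b=float(bvals[i]), direction_index=int(j), repetition=rep))
    b = float(bvals[dwi_sel].max()) if np.any(dwi_sel) else 0.0
    scheme = DiffusionScheme(
        b=b, raw_directions=np.asarray(uniq), n_b0=int(np.sum(~dwi_sel))
    )
    stack = DWIStack(
        voxels=voxels,
        spacing=spacing,
        volumes=volumes,
        provenance=[f"loaded({Path(nifti_path).name})"],
    )
    return stack, scheme


def save_map(arr: np.ndarray, spacing: tuple[float, float], path) -> Path:
    """Write a 2-D scalar map as NIfTI."""
    affine = np.diag([spacing[1], spacing[0], 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32)[..., None], affine)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, path)
    return path
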