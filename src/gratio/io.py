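"""NIfTI volume and FSL gradient-table I/O.

Volumes are stored float32 on disk (NIfTI-1 convention) and promoted to
float64 in memory.  The sform is written and, on read, takes precedence
over the qform when both are set (nibabel's default best-affine
behavior).  World coordinates follow RAS+; voxel indices are 0-based.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["read_volume", "write_volume", "read_gradient_table", "write_gradient_table"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _check_path(path: Path) -> None:
    name = path.name
    if not (name.endswith(".nii") or name.endswith(".nii.gz")):
        raise ValueError(
            f"expected a NIfTI-1 file (.nii or .nii.gz), got {path.name!r}"
        )


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3-D or 4-D NIfTI volume; returns (float64 data, affine)."""
    path = Path(path)
    _check_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path.name}: expected a 3-D or 4-D payload, got {data.ndim}-D")
    return data, np.asarray(img.affine, dtype=float)


def write_volume(volume: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write a volume as float32 NIfTI-1 with sform and qform set."""
    path = Path(path)
    _check_path(path)
    volume = np.asarray(volume)
    if volume.ndim not in (3, 4):
        raise ValueError("only 3-D or 4-D volumes are written")
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.astype(np.float32), np.asarray(affine, dtype=float))
    img.header.set_sform(affine, code=2)
    img.header.set_qform(affine, code=2)
    nib.save(img, str(path))
    return path


def read_gradient_table(
    bvals_path: str | Path, bvecs_path: str | Path, n_volumes: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-style whitespace ``bvals``/``bvecs`` text files.

    ``bvecs`` may be 3 rows x n columns (FSL convention) or n x 3.
    Non-unit vectors at b > 0 are normalized with a warning; zero
    vectors are admitted only for b = 0 rows.
    """
    for p in (bvals_path, bvecs_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    try:
        bvals = np.loadtxt(bvals_path, dtype=float).ravel()
        bvecs = np.loadtxt(bvecs_path, dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric token in gradient table: {exc}") from exc
    if bvecs.ndim != 2:
        raise ValueError("bvecs must be a 2-D table")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    if bvecs.shape[1] != 3:
        raise ValueError(f"bvecs must be 3 x n or n x 3, got {bvecs.shape}")
    if bvecs.shape[0] != bvals.size:
        raise ValueError(
            f"bvals ({bvals.size}) and bvecs ({bvecs.shape[0]}) counts differ"
        )
    if n_volumes is not None and bvals.size != n_volumes:
        raise ValueError(f"gradient table has {bvals.size} rows for {n_volumes} volumes")

    norms = np.linalg.norm(bvecs, axis=1)
    dw = bvals > 0
    if np.any(norms[dw] == 0):
        raise ValueError("zero gradient vector on a diffusion-weighted row")
    off = dw & (np.abs(norms - 1.0) > 1e-6)
    if np.any(off):
        warnings.warn(f"normalizing {int(off.sum())} non-unit gradient vectors")
        bvecs = bvecs.copy()
        bvecs[off] /= norms[off, None]
    return bvals, bvecs


def write_gradient_table(
    bvals: np.ndarray, bvecs: np.ndarray, bvals_path: str | Path, bvecs_path: str | Path
) -> None:
    """Write FSL-convention gradient tables (bvals: one row; bvecs: 3 rows)."""
    np.savetxt(bvals_path, np.atleast_2d(np.asarray(bvals).ravel()), fmt="%.6g")
    np.savetxt(bvecs_path, np.asarray(bvecs).T, fmt="%.8f")
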