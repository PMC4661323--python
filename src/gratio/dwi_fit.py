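"""Diffusion tensor fitting and the fiber-density (FVF proxy) map.

A single-shell diffusion series (60 directions at b = 1000 s/mm² plus
low-b volumes at b = 100 s/mm² in the reference protocol) is fit
voxel-wise with the log-linear diffusion tensor model

    ln S_i = ln S0 - b_i * g_i^T D g_i

by weighted least squares (one reweighting pass with weights equal to
the squared signals predicted by an initial OLS fit).  The low-b
volumes enter the design matrix with their true b-value; they are not
treated as b = 0.

Scalar invariants (FA, MD, AD, RD) follow from the sorted eigenvalues.
The fiber-density map — the fiber-volume-fraction proxy paired with the
MT map in the g-ratio — is the tensor's linear-anisotropy coefficient
``(l1 - l2) / (l1 + l2 + l3)``, normalized so its mean over the
white-matter mask is exactly 1.  Fiber density from diffusion data is
only defined up to one global per-subject factor; that factor (and the
proxy's own scale) is absorbed by the g-ratio calibration constant
alpha, so any fiber-density map on this convention — including
externally computed ones loaded from disk — can stand in the same
slot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DWISeries",
    "TensorFit",
    "TensorIndices",
    "DensityMap",
    "forward_tensor_signal",
    "fit_tensor_wls",
    "tensor_indices",
    "fiber_density_proxy",
    "load_external_density",
]

MIN_USABLE_MEASUREMENTS = 7  # 6 tensor components + ln S0


@dataclass
class DWISeries:
    """4-D diffusion stack with per-volume b-values and directions.

    ``bvals`` in s/mm²; ``bvecs`` as (n, 3) unit vectors (zero vectors
    allowed only where b = 0).
    """

    volumes: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be 4-D (x, y, z, volume)")
        n = self.volumes.shape[-1]
        if self.bvals.size != n or self.bvecs.shape != (n, 3):
            raise ValueError("bvals/bvecs must match the number of volumes")
        norms = np.linalg.norm(self.bvecs, axis=1)
        dw = self.bvals > 0
        if np.any(np.abs(norms[dw] - 1.0) > 1e-3):
            raise ValueError("gradient directions must be unit vectors where b > 0")
        if n < MIN_USABLE_MEASUREMENTS:
            raise ValueError(f"need at least {MIN_USABLE_MEASUREMENTS} volumes")

    @property
    def n_volumes(self) -> int:
        return self.volumes.shape[-1]


@dataclass
class TensorFit:
    """Per-voxel symmetric diffusion tensor and fit diagnostics.

    ``tensor`` has shape (x, y, z, 3, 3) in mm²/s; ``valid`` marks
    voxels with enough positive signals and a finite solution;
    ``negative_eigenvalues`` flags physically implausible fits (kept,
    not clipped).
    """

    tensor: np.ndarray
    s0: np.ndarray
    residual_variance: np.ndarray
    valid: np.ndarray
    affine: np.ndarray

    def eigenvalues(self) -> np.ndarray:
        """Sorted-descending eigenvalues, shape (x, y, z, 3); NaN where invalid."""
        evals = np.full(self.tensor.shape[:-1], np.nan)
        if np.any(self.valid):
            vals = np.linalg.eigvalsh(self.tensor[self.valid])
            evals[self.valid] = vals[..., ::-1]
        return evals

    @property
    def negative_eigenvalues(self) -> np.ndarray:
        evals = self.eigenvalues()
        with np.errstate(invalid="ignore"):
            return self.valid & np.any(evals < 0, axis=-1)


@dataclass
class TensorIndices:
    """Scalar tensor invariants: FA (dimensionless), MD/AD/RD (mm²/s)."""

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    eigenvalues: np.ndarray
    valid: np.ndarray
    affine: np.ndarray


@dataclass
class DensityMap:
    """Fiber-density map normalized to WM-mask mean 1.

    ``normalization_factor`` is the per-subject global factor the raw
    map was divided by; ``source`` records whether the map came from the
    internal tensor proxy or an external file.
    """

    density: np.ndarray
    normalization_factor: float
    source: str
    affine: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.isfinite(self.density)


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows [1, -b gx², -b gy², -b gz², -2b gxgy, -2b gxgz, -2b gygz]."""
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    b = bvals
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ]
    )


def _params_to_tensor(beta: np.ndarray) -> np.ndarray:
    """(n, 7) fit parameters -> (n, 3, 3) symmetric tensors."""
    dxx, dyy, dzz, dxy, dxz, dyz = (beta[:, i] for i in range(1, 7))
    t = np.empty(beta.shape[:1] + (3, 3))
    t[:, 0, 0] = dxx
    t[:, 1, 1] = dyy
    t[:, 2, 2] = dzz
    t[:, 0, 1] = t[:, 1, 0] = dxy
    t[:, 0, 2] = t[:, 2, 0] = dxz
    t[:, 1, 2] = t[:, 2, 1] = dyz
    return t


def forward_tensor_signal(
    s0: np.ndarray, tensor: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray
) -> np.ndarray:
    """Noiseless single-tensor signal ``S0 * exp(-b g^T D g)``.

    ``s0`` broadcastable over voxels, ``tensor`` shape (..., 3, 3);
    returns shape (..., n_volumes).
    """
    quad = np.einsum("ni,...ij,nj->...n", bvecs, tensor, bvecs)
    return np.asarray(s0)[..., None] * np.exp(-bvals * quad)


def _solve_weighted(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-voxel weighted LS: y (n_vox, n_meas), w weights >= 0."""
    xtw = x.T[None, :, :] * w[:, None, :]  # (n_vox, 7, n_meas)
    ata = xtw @ x  # (n_vox, 7, 7)
    atb = np.einsum("vpm,vm->vp", xtw, y)
    return np.linalg.solve(ata, atb[..., None])[..., 0]


def fit_tensor_wls(series: DWISeries, mask: np.ndarray | None = None) -> TensorFit:
    """Log-linear WLS tensor fit (OLS pass, one signal-squared reweighting).

    Non-positive signals are excluded per voxel via zero weight; voxels
    with fewer than 7 usable measurements are invalid.
    """
    shape = series.volumes.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape must match volume grid")

    x = _design_matrix(series.bvals, series.bvecs)
    sig = series.volumes[mask]  # (n_vox, n_meas)
    positive = sig > 0
    usable = positive.sum(axis=1) >= MIN_USABLE_MEASUREMENTS

    tensor = np.full(shape + (3, 3), np.nan)
    s0 = np.full(shape, np.nan)
    resvar = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)

    if np.any(usable):
        sig_u = sig[usable]
        pos_u = positive[usable]
        logs = np.where(pos_u, np.log(np.where(pos_u, sig_u, 1.0)), 0.0)
        # OLS pass (unit weights on usable measurements)
        beta = _solve_weighted(x, logs, pos_u.astype(float))
        # reweight with squared predicted signals
        pred = np.exp(np.clip(x @ beta.T, -700, 700)).T  # (n_vox, n_meas)
        w = np.where(pos_u, pred**2, 0.0)
        beta = _solve_weighted(x, logs, w)
        resid = np.where(pos_u, logs - beta @ x.T, 0.0)
        dof = np.maximum(pos_u.sum(axis=1) - 7, 1)
        finite = np.all(np.isfinite(beta), axis=1)

        idx = np.zeros(shape, dtype=bool)
        midx = np.where(mask)
        sel = tuple(c[usable] for c in midx)
        idx[sel] = True
        tensor[idx] = _params_to_tensor(beta)
        s0[idx] = np.exp(beta[:, 0])
        resvar[idx] = (resid**2).sum(axis=1) / dof
        valid[idx] = finite

    return TensorFit(
        tensor=tensor, s0=s0, residual_variance=resvar, valid=valid, affine=series.affine.copy()
    )


def tensor_indices(fit: TensorFit) -> TensorIndices:
    """FA/MD/AD/RD from sorted eigenvalues; invalid voxels propagate NaN."""
    evals = fit.eigenvalues()
    l1, l2, l3 = evals[..., 0], evals[..., 1], evals[..., 2]
    md = evals.mean(axis=-1)
    ad = l1
    rd = (l2 + l3) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.sqrt(((evals - md[..., None]) ** 2).sum(axis=-1))
        den = np.sqrt((evals**2).sum(axis=-1))
        fa = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
    fa = np.where(fit.valid, fa, np.nan)
    return TensorIndices(
        fa=fa, md=md, ad=ad, rd=rd, eigenvalues=evals, valid=fit.valid.copy(), affine=fit.affine.copy()
    )


def fiber_density_proxy(
    indices: TensorIndices, fit: TensorFit, wm_mask: np.ndarray
) -> DensityMap:
    """Linear-anisotropy fiber-density proxy, WM-mask mean normalized to 1.

    Raw density is Westin's linear coefficient ``(l1 - l2)/(l1+l2+l3)``
    clamped at 0.  Voxels with negative eigenvalues or invalid fits are
    excluded.  The WM-mask mean of the raw map is the per-subject global
    normalization factor.
    """
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if wm_mask.shape != indices.fa.shape:
        raise ValueError("wm_mask shape must match the index maps")
    if not wm_mask.any():
        raise ValueError("empty white-matter mask")

    evals = indices.eigenvalues
    with np.errstate(invalid="ignore", divide="ignore"):
        trace = evals.sum(axis=-1)
        raw = np.where(trace > 0, (evals[..., 0] - evals[..., 1]) / trace, np.nan)
    raw = np.maximum(raw, 0.0)
    ok = indices.valid & np.all(np.isfinite(evals), axis=-1) & np.all(evals >= 0, axis=-1)
    raw = np.where(ok, raw, np.nan)

    in_mask = raw[wm_mask]
    factor = float(np.nanmean(in_mask))
    if not np.isfinite(factor) or factor <= 0:
        raise ValueError("raw density mean over the WM mask is zero or undefined")
    density = raw / factor
    return DensityMap(
        density=density,
        normalization_factor=factor,
        source="internal proxy",
        affine=indices.affine.copy(),
        valid=ok,
    )


def load_external_density(
    path: str | Path,
    grid_reference: tuple[tuple[int, int, int], np.ndarray],
    wm_mask: np.ndarray | None = None,
    renormalize: bool = True,
    resample: bool = False,
) -> DensityMap:
    """Load an externally computed fiber-density map (e.g. a genuine
    tract-fiber-density solution) as a drop-in for the internal proxy.

    ``grid_reference`` is ``(shape, affine)`` of the diffusion grid.
    With ``renormalize`` (default) and a ``wm_mask``, the map is divided
    by its WM-mask mean; otherwise it is trusted as-is.  A grid or
    affine mismatch raises unless ``resample`` is enabled (trilinear,
    via :func:`gratio.gratio_map.resample_to_grid`).
    """
    from .io import read_volume

    ref_shape, ref_affine = grid_reference
    data, affine = read_volume(path)
    if data.shape != tuple(ref_shape) or not np.allclose(affine, ref_affine, atol=1e-4):
        if not resample:
            raise ValueError(
                f"density map grid {data.shape} / affine does not match the "
                "reference diffusion grid (pass resample=True to interpolate)"
            )
        from .gratio_map import resample_to_grid

        data = resample_to_grid(data, affine, tuple(ref_shape), ref_affine)
        affine = np.asarray(ref_affine, dtype=float)

    data = np.asarray(data, dtype=float)
    data = np.where(data >= 0, data, np.nan)
    factor = 1.0
    if renormalize:
        if wm_mask is None:
            raise ValueError("renormalization requires a WM mask")
        factor = float(np.nanmean(data[np.asarray(wm_mask, dtype=bool)]))
        if not np.isfinite(factor) or factor <= 0:
            raise ValueError("cannot normalize: WM-mask mean is zero or undefined")
        data = data / factor
    return DensityMap(
        density=data,
        normalization_factor=factor,
        source="external file",
        affine=np.asarray(affine, dtype=float),
        valid=np.isfinite(data),
    )
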