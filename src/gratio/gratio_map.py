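"""Calibrated voxel-wise g-ratio maps from MT and fiber-density inputs.

The aggregate g-ratio of a voxel is ``g = sqrt(1 - MVF/FVF)``.  With MT
saturation standing in for the myelin volume fraction and a fiber
density map for the fiber volume fraction, the map becomes

    g = sqrt(1 - alpha * MT / density)

where a single scaling constant ``alpha`` absorbs both proxies' unknown
global factors.  ``alpha`` is calibrated once, on a reference region —
conventionally the splenium of the corpus callosum, anchored to the
ex-vivo literature value g = 0.7 — and then held fixed for every
subject in a cohort.

Voxels where the radicand goes negative (alpha*MT/density > 1) or the
density is non-positive are masked invalid rather than clipped: such
voxels are diagnostic of misalignment between the MT and diffusion data
(most prominently EPI susceptibility distortion, which displaces tissue
along the phase-encode axis and produces implausible g ~ 1 rims at
structure edges).  A 1-D displacement-field warp with an approximate
inverse is included to demonstrate and correct that effect.

Maps are combined on the diffusion grid (the coarser of the two), with
the MT map resampled down to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .dwi_fit import DensityMap

__all__ = [
    "CalibrationRecord",
    "GRatioResult",
    "DisplacementField",
    "resample_to_grid",
    "apply_displacement",
    "calibrate_alpha",
    "compute_g_map",
]

DEFAULT_G_REFERENCE = 0.7  # ex-vivo splenium anchor
DEFAULT_SOLVER_TOL = 1e-10


@dataclass
class CalibrationRecord:
    """Result of solving for the MT/density scaling constant alpha."""

    alpha: float
    reference_roi: str
    g_reference: float = DEFAULT_G_REFERENCE
    solver_tolerance: float = DEFAULT_SOLVER_TOL
    calibration_mode: str = "mean-of-g"
    achieved: float = float("nan")
    n_roi_voxels: int = 0

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "reference_roi": self.reference_roi,
            "g_reference": self.g_reference,
            "solver_tolerance": self.solver_tolerance,
            "calibration_mode": self.calibration_mode,
            "achieved": self.achieved,
            "n_roi_voxels": self.n_roi_voxels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationRecord":
        return cls(**d)


@dataclass
class GRatioResult:
    """g-ratio volume with its validity mask and calibration record."""

    g_map: np.ndarray
    validity_mask: np.ndarray
    calibration: CalibrationRecord
    affine: np.ndarray


@dataclass
class DisplacementField:
    """Per-voxel displacement along one phase-encode axis, in mm.

    ``field`` has the shape of the volume it warps; ``axis`` names the
    phase-encode axis (0, 1 or 2 in voxel space).  A zero field is the
    identity warp.  ``jacobian_modulation`` additionally scales
    intensities by the warp's 1-D Jacobian, mimicking the signal
    pile-up/dilution of EPI distortion.
    """

    field: np.ndarray
    axis: int = 1
    voxel_size: float = 1.0
    jacobian_modulation: bool = False

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")
        if not np.all(np.isfinite(self.field)):
            raise ValueError("displacement field must be finite")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    def in_voxels(self) -> np.ndarray:
        return self.field / self.voxel_size


def resample_to_grid(
    volume: np.ndarray,
    source_affine: np.ndarray,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
    method: str = "trilinear",
) -> np.ndarray:
    """Resample a 3-D volume into a target grid through world space.

    Voxel centers of the target grid are mapped through
    ``inv(source_affine) @ target_affine`` and interpolated
    (``trilinear`` default, or ``nearest``).  Voxels falling outside the
    source field of view come back NaN.  Identical grids short-circuit
    to an exact copy.
    """
    volume = np.asarray(volume, dtype=float)
    source_affine = np.asarray(source_affine, dtype=float)
    target_affine = np.asarray(target_affine, dtype=float)
    if abs(np.linalg.det(source_affine[:3, :3])) < 1e-12:
        raise ValueError("singular source affine")
    if volume.shape == tuple(target_shape) and np.allclose(source_affine, target_affine, atol=1e-9):
        return volume.copy()

    order = {"trilinear": 1, "nearest": 0}.get(method)
    if order is None:
        raise ValueError(f"unknown interpolation method {method!r}")

    xform = np.linalg.inv(source_affine) @ target_affine
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in target_shape), indexing="ij")
    tgt_vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).reshape(4, -1)
    src_vox = (xform @ tgt_vox)[:3]

    out = ndimage.map_coordinates(
        np.nan_to_num(volume, nan=0.0), src_vox, order=order, mode="constant", cval=np.nan
    )
    # propagate NaNs from the source (map_coordinates cannot interpolate them)
    if np.any(~np.isfinite(volume)):
        bad = ndimage.map_coordinates(
            (~np.isfinite(volume)).astype(float), src_vox, order=order, mode="constant", cval=1.0
        )
        out[bad > 1e-6] = np.nan
    return out.reshape(target_shape)


def apply_displacement(
    volume: np.ndarray, disp: DisplacementField, invert: bool = False
) -> np.ndarray:
    """Warp a volume along the phase-encode axis by a displacement field.

    The warp is a pull-back with linear interpolation:
    ``out[x] = volume[x + d(x)]`` along ``disp.axis`` (d in voxels).
    ``invert=True`` applies the negated field — the first-order inverse,
    exact for spatially constant displacements.  With Jacobian
    modulation enabled, intensities are scaled by ``1 + dd/dx``.
    """
    volume = np.asarray(volume, dtype=float)
    if disp.field.shape != volume.shape:
        raise ValueError("displacement field must share the volume grid")
    d_vox = disp.in_voxels()
    if invert:
        d_vox = -d_vox
    n_axis = volume.shape[disp.axis]
    if np.any(np.abs(d_vox) >= n_axis):
        raise ValueError("displacement exceeds the field of view")

    coords = np.meshgrid(*(np.arange(n, dtype=float) for n in volume.shape), indexing="ij")
    coords = [c.copy() for c in coords]
    coords[disp.axis] += d_vox
    out = ndimage.map_coordinates(
        np.nan_to_num(volume, nan=0.0),
        np.stack(coords),
        order=1,
        mode="constant",
        cval=0.0,
    )
    if np.any(~np.isfinite(volume)):
        bad = ndimage.map_coordinates(
            (~np.isfinite(volume)).astype(float), np.stack(coords), order=1, mode="constant", cval=0.0
        )
        out[bad > 1e-6] = np.nan
    if disp.jacobian_modulation:
        jac = 1.0 + np.gradient(d_vox, axis=disp.axis)
        out = out * jac
    return out


def _roi_values(
    mt_map: np.ndarray, density_map: np.ndarray, reference_roi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    roi = np.asarray(reference_roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty reference ROI")
    mt = np.asarray(mt_map, dtype=float)[roi]
    den = np.asarray(density_map, dtype=float)[roi]
    ok = np.isfinite(mt) & np.isfinite(den) & (mt > 0) & (den > 0)
    if not ok.any():
        raise ValueError("reference ROI contains no valid positive voxels")
    if not ok.all():
        import warnings

        warnings.warn(
            f"excluding {np.count_nonzero(~ok)} invalid voxels from the reference ROI",
            stacklevel=3,
        )
    return mt[ok], den[ok]


def calibrate_alpha(
    mt_map: np.ndarray,
    density_map: np.ndarray | DensityMap,
    reference_roi: np.ndarray,
    g_reference: float = DEFAULT_G_REFERENCE,
    mode: str = "mean-of-g",
    roi_name: str = "reference",
    tol: float = DEFAULT_SOLVER_TOL,
) -> CalibrationRecord:
    """Solve for the alpha that pins the reference-ROI g to its anchor.

    In ``mean-of-g`` mode (default) alpha satisfies
    ``mean_ROI sqrt(1 - alpha*MT/density) = g_reference``; in
    ``ratio-of-means`` mode the ROI-mean MT and density are combined
    first and the closed form ``alpha = (1 - g_ref**2) * mean(density)/mean(MT)``
    applies.  The mean-of-g statistic is strictly decreasing in alpha on
    ``(0, alpha_max)`` with ``alpha_max = min(density/MT)`` (the largest
    alpha keeping every ROI radicand non-negative), so Brent's method on
    that bracket finds the unique root.
    """
    if isinstance(density_map, DensityMap):
        density_map = density_map.density
    if not 0 < g_reference <= 1:
        raise ValueError("g_reference must be in (0, 1]")
    mt, den = _roi_values(mt_map, density_map, reference_roi)
    n_vox = mt.size

    if g_reference == 1.0:
        alpha, achieved = 0.0, 1.0
    elif mode == "ratio-of-means":
        alpha = (1.0 - g_reference**2) * float(den.mean()) / float(mt.mean())
        achieved = float(np.sqrt(1.0 - alpha * float(mt.mean()) / float(den.mean())))
    elif mode == "mean-of-g":
        ratio = mt / den
        alpha_max = 1.0 / float(ratio.max())

        def roi_mean_g(alpha: float) -> float:
            return float(np.mean(np.sqrt(np.maximum(1.0 - alpha * ratio, 0.0))))

        if roi_mean_g(alpha_max) > g_reference:
            raise ValueError(
                "no feasible alpha: even the largest admissible alpha leaves "
                f"the ROI mean g above {g_reference}"
            )
        alpha = float(
            optimize.brentq(
                lambda a: roi_mean_g(a) - g_reference, 0.0, alpha_max, xtol=tol
            )
        )
        achieved = roi_mean_g(alpha)
    else:
        raise ValueError(f"unknown calibration mode {mode!r}")

    return CalibrationRecord(
        alpha=alpha,
        reference_roi=roi_name,
        g_reference=g_reference,
        solver_tolerance=tol,
        calibration_mode=mode,
        achieved=achieved,
        n_roi_voxels=int(n_vox),
    )


def compute_g_map(
    mt_map: np.ndarray,
    density_map: np.ndarray | DensityMap,
    calibration: CalibrationRecord,
    affine: np.ndarray | None = None,
) -> GRatioResult:
    """Voxel-wise ``g = sqrt(1 - alpha*MT/density)`` with a validity mask.

    Invalid (masked, not clipped): non-positive or non-finite density,
    non-finite MT, or a negative radicand.  MT = 0 gives g = 1 exactly.
    """
    if isinstance(density_map, DensityMap):
        if affine is None:
            affine = density_map.affine
        density = density_map.density
    else:
        density = np.asarray(density_map, dtype=float)
    mt = np.asarray(mt_map, dtype=float)
    if mt.shape != density.shape:
        raise ValueError("MT and density maps must share one grid")
    if not calibration.alpha >= 0:
        raise ValueError("calibration alpha must be non-negative")
    if affine is None:
        affine = np.eye(4)

    with np.errstate(invalid="ignore", divide="ignore"):
        radicand = 1.0 - calibration.alpha * mt / density
    valid = np.isfinite(mt) & np.isfinite(density) & (density > 0) & (radicand >= 0)
    g = np.where(valid, np.sqrt(np.where(valid, radicand, 0.0)), np.nan)
    return GRatioResult(
        g_map=g,
        validity_mask=valid,
        calibration=calibration,
        affine=np.asarray(affine, dtype=float),
    )
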