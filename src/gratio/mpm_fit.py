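"""MT-saturation and R1 mapping from a multi-echo FLASH triplet (MPM).

The multi-parameter-mapping (MPM) protocol acquires three spoiled
multi-echo FLASH volumes — proton-density-weighted (PDw), T1-weighted
(T1w) and MT-weighted (MTw, preceded by an off-resonance saturation
pulse).  In the small-flip-angle rational approximation the spoiled
FLASH signal is

    S = A * alpha * R1 * TR / (alpha**2 / 2 + R1 * TR)

with apparent amplitude ``A`` (proton density times receive profile),
longitudinal rate ``R1 = 1/T1`` and excitation flip angle ``alpha`` in
radians.  The MT pre-pulse adds a per-excitation saturation term
``delta`` to the denominator:

    S_MT = A * alpha * R1 * TR / (alpha**2 / 2 + delta + R1 * TR)

Solving the PDw/T1w pair for ``(R1, A)`` and then the MTw equation for
``delta`` is algebraically exact under this model; ``delta`` is reported
in percent units (p.u.), the conventional scale on which white matter
sits near 2 p.u.  MT saturation is the myelin-sensitive input to the
g-ratio map.

Echoes are averaged (first 6 of 8 by default) before fitting to raise
SNR; a voxel-wise T2* decay common to the three weightings scales all
three averaged signals by the same factor and therefore cancels in R1
and MT (only the apparent amplitude absorbs it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WeightedFlashStack",
    "MPMAcquisition",
    "MPMMaps",
    "flash_signal",
    "mt_flash_signal",
    "average_echoes",
    "fit_r1_a",
    "fit_mt_sat",
    "fit_mpm",
]

DEFAULT_N_ECHOES_AVERAGED = 6


@dataclass
class WeightedFlashStack:
    """One weighted multi-echo FLASH acquisition.

    Parameters
    ----------
    volumes : ndarray, shape (x, y, z, n_echoes)
        Magnitude images, arbitrary units, >= 0.
    flip_angle : float
        Excitation flip angle in radians, in (0, pi/2).
    tr : float
        Repetition time in seconds.
    echo_times : ndarray
        Echo times in seconds, ascending, one per echo.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform shared by all echoes.
    """

    volumes: np.ndarray
    flip_angle: float
    tr: float
    echo_times: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.echo_times = np.atleast_1d(np.asarray(self.echo_times, dtype=float))
        self.affine = np.asarray(self.affine, dtype=float)
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be 4-D (x, y, z, echo)")
        if self.volumes.shape[-1] != self.echo_times.size:
            raise ValueError("number of echoes must match echo_times")
        if self.echo_times.size < 1:
            raise ValueError("need at least one echo")
        if np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo_times must be strictly ascending")
        if not 0 < self.flip_angle < np.pi / 2:
            raise ValueError("flip_angle must be in (0, pi/2) radians")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_echoes(self) -> int:
        return self.volumes.shape[-1]


@dataclass
class MPMAcquisition:
    """The co-registered PDw/T1w/MTw FLASH triplet."""

    pdw: WeightedFlashStack
    t1w: WeightedFlashStack
    mtw: WeightedFlashStack

    def __post_init__(self) -> None:
        shape = self.pdw.volumes.shape[:3]
        for name in ("t1w", "mtw"):
            stack = getattr(self, name)
            if stack.volumes.shape[:3] != shape:
                raise ValueError(f"{name} grid differs from pdw grid")
            if not np.allclose(stack.affine, self.pdw.affine, atol=1e-6):
                raise ValueError(f"{name} affine differs from pdw affine")


@dataclass
class MPMMaps:
    """Quantitative maps from the MPM fit.

    ``mt_sat`` is in percent units; ``r1`` in 1/s; ``a_app`` in the
    arbitrary units of the input signal.  ``valid`` marks voxels where
    the fit denominators were well-conditioned and signals positive;
    negative mt_sat values are retained (flagged via ``negative_mt``),
    not clipped, so downstream stages can see them.
    """

    mt_sat: np.ndarray
    r1: np.ndarray
    a_app: np.ndarray
    valid: np.ndarray
    affine: np.ndarray

    @property
    def negative_mt(self) -> np.ndarray:
        return self.valid & (self.mt_sat < 0)


def flash_signal(a: np.ndarray, r1: np.ndarray, flip_angle: float, tr: float) -> np.ndarray:
    """Forward rational-approximation FLASH signal (no MT pulse)."""
    alpha = float(flip_angle)
    return a * alpha * r1 * tr / (alpha**2 / 2.0 + r1 * tr)


def mt_flash_signal(
    a: np.ndarray, r1: np.ndarray, delta: np.ndarray, flip_angle: float, tr: float
) -> np.ndarray:
    """Forward MT-FLASH signal with per-excitation saturation ``delta``
    (fractional units, not percent)."""
    alpha = float(flip_angle)
    return a * alpha * r1 * tr / (alpha**2 / 2.0 + delta + r1 * tr)


def average_echoes(stack: WeightedFlashStack, n_echoes: int = DEFAULT_N_ECHOES_AVERAGED) -> np.ndarray:
    """Voxel-wise mean over the first ``n_echoes`` echoes (SNR boost)."""
    if n_echoes < 1 or n_echoes > stack.n_echoes:
        raise ValueError(
            f"n_echoes must be in [1, {stack.n_echoes}], got {n_echoes}"
        )
    return stack.volumes[..., :n_echoes].mean(axis=-1)


def fit_r1_a(
    pd_mean: np.ndarray,
    t1_mean: np.ndarray,
    pd_meta: tuple[float, float],
    t1_meta: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invert the PDw/T1w FLASH pair for (R1, apparent amplitude).

    ``pd_meta`` and ``t1_meta`` are ``(flip_angle_rad, tr_s)``.  Returns
    ``(r1, a_app, valid)``; voxels with non-positive signal or a
    degenerate contrast denominator (S_PD/a_PD ~ S_T1/a_T1, i.e. no T1
    contrast) are flagged invalid and set to NaN.
    """
    a_pd, tr_pd = pd_meta
    a_t1, tr_t1 = t1_meta
    s_pd = np.asarray(pd_mean, dtype=float)
    s_t1 = np.asarray(t1_mean, dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = s_pd / a_pd - s_t1 / a_t1
        scale = np.maximum(np.abs(s_pd / a_pd), np.abs(s_t1 / a_t1))
        valid = (s_pd > 0) & (s_t1 > 0) & (np.abs(denom) > 1e-9 * np.maximum(scale, 1e-300))
        r1 = 0.5 * (s_t1 * a_t1 / tr_t1 - s_pd * a_pd / tr_pd) / denom
        a_app = (
            s_pd
            * s_t1
            * (tr_pd * a_t1 / a_pd - tr_t1 * a_pd / a_t1)
            / (s_t1 * tr_pd * a_t1 - s_pd * tr_t1 * a_pd)
        )
    valid &= np.isfinite(r1) & np.isfinite(a_app) & (r1 > 0) & (a_app > 0)
    r1 = np.where(valid, r1, np.nan)
    a_app = np.where(valid, a_app, np.nan)
    return r1, a_app, valid


def fit_mt_sat(
    mt_mean: np.ndarray,
    mt_meta: tuple[float, float],
    r1: np.ndarray,
    a_app: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the MTw FLASH equation for the saturation ``delta``.

    Returns ``(mt_sat_percent, valid)``.  The inversion
    ``delta = (A * alpha / S_MT - 1) * R1 * TR - alpha**2 / 2`` is exact
    under the forward model; the result is scaled to percent units.
    """
    a_mt, tr_mt = mt_meta
    s_mt = np.asarray(mt_mean, dtype=float)
    valid = (s_mt > 0) & np.isfinite(r1) & np.isfinite(a_app)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (a_app * a_mt / s_mt - 1.0) * r1 * tr_mt - a_mt**2 / 2.0
    mt_sat = np.where(valid, delta * 100.0, np.nan)
    return mt_sat, valid


def fit_mpm(
    acq: MPMAcquisition, n_echoes: int = DEFAULT_N_ECHOES_AVERAGED
) -> MPMMaps:
    """Full MPM fit: echo averaging, R1/A inversion, MT saturation."""
    pd_mean = average_echoes(acq.pdw, n_echoes=min(n_echoes, acq.pdw.n_echoes))
    t1_mean = average_echoes(acq.t1w, n_echoes=min(n_echoes, acq.t1w.n_echoes))
    mt_mean = average_echoes(acq.mtw, n_echoes=min(n_echoes, acq.mtw.n_echoes))
    r1, a_app, valid_r1 = fit_r1_a(
        pd_mean,
        t1_mean,
        (acq.pdw.flip_angle, acq.pdw.tr),
        (acq.t1w.flip_angle, acq.t1w.tr),
    )
    mt_sat, valid_mt = fit_mt_sat(mt_mean, (acq.mtw.flip_angle, acq.mtw.tr), r1, a_app)
    return MPMMaps(
        mt_sat=mt_sat,
        r1=r1,
        a_app=a_app,
        valid=valid_r1 & valid_mt,
        affine=acq.pdw.affine.copy(),
    )
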