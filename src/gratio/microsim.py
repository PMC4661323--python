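"""Voxel-scale fiber-geometry model underlying the MR g-ratio.

A white-matter voxel is idealized as a bundle of parallel annular
cylinders ("fibers") seen in cross-section: fiber *j* has outer radius
``R_O,j`` (axon + myelin sheath) and microscopic g-ratio
``g_j = R_I,j / R_O,j`` (inner over outer radius), so its myelin annulus
has area ``pi * (R_O,j**2 - R_I,j**2)``.  Summing areas over an explicit
fiber list inside a voxel of cross-sectional area ``A`` yields the fiber
volume fraction (FVF), the myelin volume fraction (MVF) and the
extra-axonal fraction ``EVF = 1 - FVF``.

The voxel-aggregate ("MR") g-ratio is defined from the volume fractions
as ``g_MR = sqrt(1 - MVF / FVF)``.  For a population with a distribution
of per-fiber g-ratios this equals the fiber-area-weighted root mean
square of the microscopic g-ratios — an exact algebraic identity that
this module exposes on both sides, making it the analytic oracle for the
imaging pipeline: whatever the MT/diffusion stages estimate, it must
agree with these sums on synthetic ground truth.

A Rushton-type conduction-velocity factor ``g * sqrt(ln(1/g))`` is
provided as well; it is maximal at ``g = 1/sqrt(e) ~ 0.61``, the
classical "optimal" g-ratio of a myelinated fiber at fixed outer
diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Fiber",
    "FiberPopulation",
    "VolumeFractions",
    "PopulationSpec",
    "compute_volume_fractions",
    "microscopic_mean_g",
    "area_weighted_rms_g",
    "mr_g_from_fractions",
    "sample_population",
    "conduction_velocity_factor",
]


@dataclass(frozen=True)
class Fiber:
    """One myelinated (or unmyelinated) fiber in cross-section.

    Parameters
    ----------
    outer_radius : float
        Outer radius of the fiber including the myelin sheath, in µm.
    g : float
        Microscopic g-ratio, inner over outer radius, in (0, 1].
        ``g == 1`` means zero myelin thickness (unmyelinated axon).
    """

    outer_radius: float
    g: float

    def __post_init__(self) -> None:
        if not self.outer_radius > 0:
            raise ValueError(f"outer_radius must be > 0, got {self.outer_radius}")
        if not 0 < self.g <= 1:
            raise ValueError(f"g must be in (0, 1], got {self.g}")

    @property
    def inner_radius(self) -> float:
        """Axonal (inner) radius ``g * outer_radius`` in µm."""
        return self.g * self.outer_radius


@dataclass(frozen=True)
class FiberPopulation:
    """An explicit list of fibers occupying a voxel of known area.

    Each stored fiber is one draw from the underlying radius/g
    distributions, so probability-weighted expectations over binned
    distributions reduce to plain sums over the list.

    Parameters
    ----------
    fibers : sequence of Fiber
    voxel_area : float
        Cross-sectional voxel area in µm²; the summed fiber areas must
        fit inside it.
    """

    fibers: tuple[Fiber, ...]
    voxel_area: float

    def __init__(self, fibers: Sequence[Fiber], voxel_area: float) -> None:
        object.__setattr__(self, "fibers", tuple(fibers))
        object.__setattr__(self, "voxel_area", float(voxel_area))
        if not self.voxel_area > 0:
            raise ValueError("voxel_area must be > 0")
        if self.total_fiber_area() > self.voxel_area * (1 + 1e-12):
            raise ValueError(
                "fibers overflow the voxel: total fiber area "
                f"{self.total_fiber_area():.6g} exceeds voxel_area {self.voxel_area:.6g}"
            )

    def __len__(self) -> int:
        return len(self.fibers)

    def outer_radii(self) -> np.ndarray:
        return np.array([f.outer_radius for f in self.fibers], dtype=float)

    def g_values(self) -> np.ndarray:
        return np.array([f.g for f in self.fibers], dtype=float)

    def total_fiber_area(self) -> float:
        """Sum of outer cross-sectional areas, ``sum_j pi R_O,j**2``."""
        return float(np.sum(np.pi * self.outer_radii() ** 2))

    def to_table(self) -> "np.ndarray":
        """(n, 2) array of (outer_radius, g) rows, TSV-exportable."""
        return np.column_stack([self.outer_radii(), self.g_values()])


@dataclass(frozen=True)
class VolumeFractions:
    """Fiber, myelin and extra-axonal volume fractions of a voxel."""

    fvf: float
    mvf: float

    def __post_init__(self) -> None:
        if not 0 <= self.fvf <= 1:
            raise ValueError(f"fvf must be in [0, 1], got {self.fvf}")
        if not 0 <= self.mvf <= self.fvf + 1e-12:
            raise ValueError(f"mvf must be in [0, fvf], got mvf={self.mvf}, fvf={self.fvf}")

    @property
    def evf(self) -> float:
        """Extra-axonal volume fraction, ``1 - fvf``."""
        return 1.0 - self.fvf


def compute_volume_fractions(pop: FiberPopulation) -> VolumeFractions:
    """Sum fiber and myelin annulus areas into voxel volume fractions.

    ``FVF = sum_j pi R_O,j**2 / A`` and
    ``MVF = sum_j pi (R_O,j**2 - R_I,j**2) / A`` with
    ``R_I,j = g_j R_O,j``.
    """
    r_o = pop.outer_radii()
    g = pop.g_values()
    a_fiber = np.pi * r_o**2
    fvf = float(a_fiber.sum() / pop.voxel_area)
    mvf = float((a_fiber * (1.0 - g**2)).sum() / pop.voxel_area)
    return VolumeFractions(fvf=fvf, mvf=mvf)


def microscopic_mean_g(pop: FiberPopulation) -> float:
    """Unweighted mean of per-fiber g-ratios (the microscopic expectation)."""
    if len(pop) == 0:
        raise ValueError("cannot average an empty population")
    return float(pop.g_values().mean())


def area_weighted_rms_g(pop: FiberPopulation) -> float:
    """Fiber-area-weighted RMS of the microscopic g-ratios.

    ``sqrt( sum_j g_j**2 R_O,j**2 / sum_j R_O,j**2 )`` — identical to
    ``sqrt(1 - MVF/FVF)`` for the same population.
    """
    if len(pop) == 0:
        raise ValueError("cannot aggregate an empty population")
    r2 = pop.outer_radii() ** 2
    g = pop.g_values()
    return float(np.sqrt((g**2 * r2).sum() / r2.sum()))


def mr_g_from_fractions(vf: VolumeFractions) -> float:
    """Aggregate g-ratio from volume fractions, ``sqrt(1 - MVF/FVF)``.

    Undefined at ``fvf == 0``; ``mvf == 0`` (no myelin) gives exactly 1.
    """
    if vf.fvf <= 0:
        raise ValueError("mr_g is undefined for fvf = 0")
    radicand = 1.0 - vf.mvf / vf.fvf
    if radicand < -1e-12:
        raise ValueError(f"mvf > fvf gives negative radicand ({radicand})")
    return float(math.sqrt(max(radicand, 0.0)))


def conduction_velocity_factor(g: float | np.ndarray) -> float | np.ndarray:
    """Rushton's velocity factor ``g * sqrt(ln(1/g))`` for g in (0, 1).

    Conduction velocity of a myelinated fiber at fixed outer diameter is
    proportional to this factor; it has a unique maximum at
    ``g = 1/sqrt(e) ≈ 0.607``.
    """
    g_arr = np.asarray(g, dtype=float)
    if np.any(g_arr <= 0) or np.any(g_arr >= 1):
        raise ValueError("g must lie strictly inside (0, 1)")
    out = g_arr * np.sqrt(np.log(1.0 / g_arr))
    return float(out) if np.isscalar(g) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# population sampling


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for sampling a reproducible fiber population.

    radius_distribution : {"lognormal", "constant"}
        ``lognormal`` takes parameters ``median`` (µm) and ``sigma``
        (log-scale SD); ``constant`` takes ``value``.
    g_distribution : {"constant", "truncnorm", "two_pool"}
        ``constant``: point mass at ``value``.
        ``truncnorm``: normal(mean, sd) truncated (by resampling) to (0, 1].
        ``two_pool``: myelinated pool ~ truncnorm(mean, sd) with
        probability ``1 - unmyelinated_fraction``, and a point mass at
        g = 1 (unmyelinated axons) otherwise.
    voxel_area : float or None
        Voxel cross-section in µm².  If ``target_fvf`` is given instead,
        the area is scaled exactly so the realized FVF equals it.
    """

    n_fibers: int
    radius_distribution: str = "lognormal"
    radius_params: dict = field(default_factory=lambda: {"median": 0.6, "sigma": 0.4})
    g_distribution: str = "constant"
    g_params: dict = field(default_factory=lambda: {"value": 0.7})
    voxel_area: float | None = None
    target_fvf: float | None = None
    seed: int = 0

    # absolute packing ceiling for parallel circles (hexagonal bound)
    _PACKING_BOUND = np.pi / np.sqrt(12.0)

    def to_dict(self) -> dict:
        return {
            "n_fibers": self.n_fibers,
            "radius_distribution": self.radius_distribution,
            "radius_params": dict(self.radius_params),
            "g_distribution": self.g_distribution,
            "g_params": dict(self.g_params),
            "voxel_area": self.voxel_area,
            "target_fvf": self.target_fvf,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        return cls(**d)


def _sample_radii(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    kind = spec.radius_distribution
    p = spec.radius_params
    if kind == "lognormal":
        return np.exp(rng.normal(np.log(p["median"]), p["sigma"], size=spec.n_fibers))
    if kind == "constant":
        return np.full(spec.n_fibers, float(p["value"]))
    raise ValueError(f"unknown radius distribution {kind!r}")


def _sample_truncnorm_g(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Normal(mean, sd) restricted to (0, 1] by resampling rejected draws."""
    out = np.empty(n)
    remaining = np.arange(n)
    while remaining.size:
        draw = rng.normal(mean, sd, size=remaining.size)
        ok = (draw > 0) & (draw <= 1)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def _sample_g(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    kind = spec.g_distribution
    p = spec.g_params
    n = spec.n_fibers
    if kind == "constant":
        v = float(p["value"])
        if not 0 < v <= 1:
            raise ValueError("constant g must be in (0, 1]")
        return np.full(n, v)
    if kind == "truncnorm":
        return _sample_truncnorm_g(p["mean"], p["sd"], n, rng)
    if kind == "two_pool":
        frac = float(p["unmyelinated_fraction"])
        g = _sample_truncnorm_g(p["mean"], p.get("sd", 0.0) or 1e-12, n, rng)
        unmyelinated = rng.random(n) < frac
        g[unmyelinated] = 1.0
        return g
    raise ValueError(f"unknown g distribution {kind!r}")


def sample_population(spec: PopulationSpec) -> FiberPopulation:
    """Draw a reproducible fiber population from a :class:`PopulationSpec`.

    With ``target_fvf`` set, the voxel area is chosen as
    ``total_fiber_area / target_fvf`` so the realized FVF matches the
    target exactly; targets beyond the circle-packing bound
    ``pi/sqrt(12)`` are rejected as geometrically infeasible.
    """
    if spec.n_fibers < 1:
        raise ValueError("need at least one fiber")
    rng = np.random.default_rng(spec.seed)
    radii = _sample_radii(spec, rng)
    g = _sample_g(spec, rng)
    total_area = float(np.sum(np.pi * radii**2))
    if spec.target_fvf is not None:
        if not 0 < spec.target_fvf <= PopulationSpec._PACKING_BOUND:
            raise ValueError(
                f"target fvf {spec.target_fvf} outside (0, {PopulationSpec._PACKING_BOUND:.4f}]"
            )
        area = total_area / spec.target_fvf
    elif spec.voxel_area is not None:
        area = float(spec.voxel_area)
    else:
        area = total_area / 0.5  # default: half-filled voxel
    fibers = [Fiber(outer_radius=float(r), g=float(gj)) for r, gj in zip(radii, g)]
    return FiberPopulation(fibers, voxel_area=area)
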