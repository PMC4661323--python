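"""Multi-subject synthetic phantom with known microstructural ground truth.

The phantom emulates the acquisition the g-ratio pipeline expects — a
0.8 mm multi-echo FLASH triplet (PDw 5°, T1w 29°, MTw 9°; TR 25.25 /
25.25 / 29.25 ms; 8 echoes) and a 2.3 mm single-shell diffusion series
(60 directions at b = 1000 s/mm² plus 6 at b = 100 s/mm²) — over a
simple geometric "anatomy": a corpus-callosum-like arc spanning the
anterior–posterior axis with thickened genu/splenium ends, plus two
box-shaped tracts, embedded in an isotropic background.

Every structure carries a ground-truth fiber volume fraction and
g-ratio, hence MVF = FVF * (1 - g**2).  Forward models are exactly the
ones the fitting stages invert:

* MT saturation is a linear proxy of myelin, ``MT_true = kappa * MVF``
  (percent units), fed through the rational FLASH signal equations with
  a common per-voxel T2* echo decay;
* fiber density is proportional to FVF; the axially symmetric diffusion
  tensor of each voxel is constructed so its linear-anisotropy
  coefficient equals that raw density, making the density proxy's
  inversion exact.

Rician noise (magnitude of complex Gaussian) is added per modality at a
configurable SNR; between-subject variation perturbs each structure's
g and FVF per subject; an optional constant phase-encode displacement
warps the diffusion volumes to mimic susceptibility distortion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dwi_fit import DWISeries, forward_tensor_signal
from .gratio_map import DisplacementField, apply_displacement
from .mpm_fit import MPMAcquisition, WeightedFlashStack, flash_signal, mt_flash_signal

__all__ = [
    "StructureSpec",
    "PhantomSpec",
    "SyntheticSubject",
    "generate_cohort",
    "make_reference_roi",
    "fibonacci_directions",
    "add_rician_noise",
]

# acquisition constants of the emulated protocol
PDW_FLIP_DEG, T1W_FLIP_DEG, MTW_FLIP_DEG = 5.0, 29.0, 9.0
PDW_TR, T1W_TR, MTW_TR = 25.25e-3, 25.25e-3, 29.25e-3
ECHO_SPACING = 2.37e-3
N_ECHOES = 8
N_DW_HIGH, B_HIGH = 60, 1000.0
N_DW_LOW, B_LOW = 6, 100.0
AXIAL_DIFFUSIVITY = 1.7e-3  # mm^2/s, lambda_1 in structures
BACKGROUND_DIFFUSIVITY = 0.9e-3  # isotropic background


@dataclass(frozen=True)
class StructureSpec:
    """Ground truth for one geometric structure."""

    name: str
    fvf: float
    g: float

    def __post_init__(self) -> None:
        if not 0 < self.fvf < np.pi / np.sqrt(12.0):
            raise ValueError(f"{self.name}: fvf must be in (0, packing bound)")
        if not 0 < self.g < 1:
            raise ValueError(f"{self.name}: g must be in (0, 1)")

    @property
    def mvf(self) -> float:
        return self.fvf * (1.0 - self.g**2)


def _default_structures() -> tuple[StructureSpec, ...]:
    return (
        StructureSpec("cc", fvf=0.65, g=0.70),
        StructureSpec("tract_a", fvf=0.55, g=0.72),
        StructureSpec("tract_b", fvf=0.50, g=0.62),
    )


@dataclass
class PhantomSpec:
    """Full recipe for a reproducible synthetic cohort.

    Grids: an isotropic diffusion grid (``dmri_shape`` at
    ``dmri_voxel`` mm) and a finer MPM grid at ``mpm_voxel`` mm covering
    the same field of view, with consistent centered RAS affines.

    ``kappa`` converts MVF into MT saturation percent units (WM lands
    near 2 p.u. at the default); ``density_scale`` converts FVF into the
    raw fiber-density value realized as the tensor's linear-anisotropy
    coefficient.  Both global factors are absorbed downstream by the
    g-ratio calibration, mirroring the real pipeline.

    SNRs are Rician, referenced to the mean white-matter signal of the
    respective modality; ``inf`` disables noise.  Between-subject SDs
    perturb each structure's g and FVF per subject; 0 gives an
    identical cohort.
    """

    n_subjects: int = 10
    seed: int = 0
    dmri_shape: tuple[int, int, int] = (32, 32, 32)
    dmri_voxel: float = 2.3
    mpm_voxel: float = 0.8
    structures: tuple[StructureSpec, ...] = field(default_factory=_default_structures)
    kappa: float = 6.0  # p.u. MT per unit MVF
    density_scale: float = 0.6  # raw density per unit FVF
    wm_a: float = 1000.0
    wm_r1: float = 1.0  # 1/s
    wm_r2s: float = 40.0  # 1/s, common to the three weightings
    bg_a: float = 800.0
    bg_r1: float = 0.6
    bg_r2s: float = 25.0
    subject_sd_g: float = 0.02
    subject_sd_fvf: float = 0.02
    mpm_snr: float = 50.0
    dmri_snr: float = 20.0
    displacement_mm: float = 0.0  # constant phase-encode shift of the dMRI data
    displacement_axis: int = 1

    def centered_affine(self, shape: tuple[int, ...], voxel: float) -> np.ndarray:
        aff = np.diag([voxel, voxel, voxel, 1.0])
        aff[:3, 3] = -voxel * (np.asarray(shape, dtype=float) - 1) / 2.0
        return aff

    @property
    def mpm_shape(self) -> tuple[int, int, int]:
        return tuple(
            int(round(n * self.dmri_voxel / self.mpm_voxel)) for n in self.dmri_shape
        )


@dataclass
class SyntheticSubject:
    """One simulated subject with its acquisitions and ground truth.

    Ground-truth maps live on the diffusion grid (``fvf``, ``mvf``,
    ``g``, ``mt_true``, ``density_true`` = raw, un-normalized) plus
    ``mt_true_mpm`` on the MPM grid.  ``g = sqrt(1 - mvf/fvf)`` holds
    identically in white matter by construction.
    """

    subject_id: str
    mpm: MPMAcquisition
    dwi: DWISeries
    truth: dict[str, np.ndarray]
    wm_mask: np.ndarray
    structure_masks: dict[str, np.ndarray]
    dmri_affine: np.ndarray
    mpm_affine: np.ndarray
    displacement: DisplacementField | None = None
    structure_values: dict[str, dict[str, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry


def _world_grid(shape: tuple[int, int, int], affine: np.ndarray) -> tuple[np.ndarray, ...]:
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    rot, off = affine[:3, :3], affine[:3, 3]
    x = rot[0, 0] * ii + rot[0, 1] * jj + rot[0, 2] * kk + off[0]
    y = rot[1, 0] * ii + rot[1, 1] * jj + rot[1, 2] * kk + off[1]
    z = rot[2, 0] * ii + rot[2, 1] * jj + rot[2, 2] * kk + off[2]
    return x, y, z


def _structure_masks(
    shape: tuple[int, int, int], affine: np.ndarray, half_fov: float
) -> dict[str, np.ndarray]:
    """Render the fixed phantom layout on a grid by voxel-center membership.

    Geometry scales with the field of view: a midline arc along y with
    thickened ends (corpus callosum with genu/splenium bulges) and two
    lateral box tracts.
    """
    x, y, z = _world_grid(shape, affine)
    h = half_fov
    masks: dict[str, np.ndarray] = {}

    y_half = 0.70 * h
    u = y / y_half
    arc_center = 0.25 * h * (1.0 - u**2)
    arc_halfthick = 0.14 * h + 0.08 * h * np.minimum(np.abs(u), 1.0) ** 2
    masks["cc"] = (
        (np.abs(x) <= 0.25 * h)
        & (np.abs(y) <= y_half)
        & (np.abs(z - arc_center) <= arc_halfthick)
    )
    masks["tract_a"] = (
        (x >= 0.45 * h) & (x <= 0.85 * h)
        & (np.abs(y) <= 0.30 * h)
        & (z >= -0.80 * h) & (z <= -0.10 * h)
    )
    masks["tract_b"] = (
        (x >= -0.85 * h) & (x <= -0.45 * h)
        & (y >= -0.70 * h) & (y <= 0.30 * h)
        & (z >= -0.50 * h) & (z <= -0.10 * h)
    )
    # structures must not overlap; carve later boxes away from the arc
    masks["tract_a"] &= ~masks["cc"]
    masks["tract_b"] &= ~masks["cc"] & ~masks["tract_a"]
    return masks


def fibonacci_directions(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (deterministic Fibonacci sphere)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    cos_theta = 1.0 - 2.0 * i / n
    sin_theta = np.sqrt(np.maximum(1.0 - cos_theta**2, 0.0))
    return np.column_stack([sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta])


def add_rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the signal plus complex Gaussian noise of SD sigma."""
    if sigma <= 0:
        return np.asarray(signal, dtype=float).copy()
    re = signal + rng.normal(0.0, sigma, size=signal.shape)
    im = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt(re**2 + im**2)


# ---------------------------------------------------------------------------
# per-subject forward simulation


def _paint(masks: dict[str, np.ndarray], values: dict[str, float], background: float, shape) -> np.ndarray:
    out = np.full(shape, background, dtype=float)
    for name, m in masks.items():
        out[m] = values[name]
    return out


def _subject_structure_values(
    spec: PhantomSpec, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    vals: dict[str, dict[str, float]] = {}
    for s in spec.structures:
        g = float(np.clip(s.g + rng.normal(0.0, spec.subject_sd_g), 0.05, 0.98))
        fvf = float(np.clip(s.fvf + rng.normal(0.0, spec.subject_sd_fvf), 0.05, 0.85))
        vals[s.name] = {"g": g, "fvf": fvf, "mvf": fvf * (1.0 - g**2)}
    return vals


def _simulate_mpm(
    spec: PhantomSpec,
    masks_mpm: dict[str, np.ndarray],
    values: dict[str, dict[str, float]],
    mpm_affine: np.ndarray,
    rng: np.random.Generator,
) -> tuple[MPMAcquisition, np.ndarray]:
    shape = next(iter(masks_mpm.values())).shape
    wm = np.zeros(shape, dtype=bool)
    for m in masks_mpm.values():
        wm |= m
    mt_true = _paint(masks_mpm, {k: spec.kappa * v["mvf"] for k, v in values.items()}, 0.0, shape)
    a_map = np.where(wm, spec.wm_a, spec.bg_a)
    r1_map = np.where(wm, spec.wm_r1, spec.bg_r1)
    r2s_map = np.where(wm, spec.wm_r2s, spec.bg_r2s)

    echo_times = ECHO_SPACING * np.arange(1, N_ECHOES + 1)
    decay = np.exp(-echo_times[None, None, None, :] * r2s_map[..., None])
    delta = mt_true / 100.0  # percent units -> fraction

    stacks = {}
    params = {
        "pdw": (np.deg2rad(PDW_FLIP_DEG), PDW_TR, None),
        "t1w": (np.deg2rad(T1W_FLIP_DEG), T1W_TR, None),
        "mtw": (np.deg2rad(MTW_FLIP_DEG), MTW_TR, delta),
    }
    sigma = 0.0
    if np.isfinite(spec.mpm_snr):
        ref = flash_signal(spec.wm_a, spec.wm_r1, np.deg2rad(PDW_FLIP_DEG), PDW_TR)
        sigma = float(ref) * float(np.exp(-echo_times[0] * spec.wm_r2s)) / spec.mpm_snr
    for name, (flip, tr, dlt) in params.items():
        if dlt is None:
            steady = flash_signal(a_map, r1_map, flip, tr)
        else:
            steady = mt_flash_signal(a_map, r1_map, dlt, flip, tr)
        vols = steady[..., None] * decay
        if sigma > 0:
            vols = add_rician_noise(vols, sigma, rng)
        stacks[name] = WeightedFlashStack(
            volumes=vols, flip_angle=flip, tr=tr, echo_times=echo_times, affine=mpm_affine
        )
    return MPMAcquisition(**stacks), mt_true


def _tensor_field_from_density(
    density_raw: np.ndarray, wm: np.ndarray
) -> np.ndarray:
    """Axially symmetric tensors whose linear-anisotropy equals the raw density.

    With lambda_1 fixed, c_l = (l1 - l2) / (l1 + 2 l2) inverts to
    ``l2 = l1 (1 - c_l) / (1 + 2 c_l)``; the background is isotropic.
    """
    c = np.asarray(density_raw, dtype=float)
    if np.any((c[wm] < 0) | (c[wm] >= 1)):
        raise ValueError("raw density outside the attainable anisotropy range [0, 1)")
    l1 = np.where(wm, AXIAL_DIFFUSIVITY, BACKGROUND_DIFFUSIVITY)
    l2 = np.where(wm, AXIAL_DIFFUSIVITY * (1.0 - c) / (1.0 + 2.0 * c), BACKGROUND_DIFFUSIVITY)
    tensors = np.zeros(c.shape + (3, 3))
    # principal axis along world z (the dominant fiber direction of the phantom)
    tensors[..., 0, 0] = l2
    tensors[..., 1, 1] = l2
    tensors[..., 2, 2] = l1
    return tensors


def _simulate_dwi(
    spec: PhantomSpec,
    density_raw: np.ndarray,
    wm: np.ndarray,
    dmri_affine: np.ndarray,
    rng: np.random.Generator,
) -> tuple[DWISeries, DisplacementField | None]:
    bvals = np.concatenate([np.full(N_DW_LOW, B_LOW), np.full(N_DW_HIGH, B_HIGH)])
    bvecs = np.vstack([fibonacci_directions(N_DW_LOW), fibonacci_directions(N_DW_HIGH)])
    tensors = _tensor_field_from_density(density_raw, wm)
    s0 = np.where(wm, 1000.0, 1200.0)
    signals = forward_tensor_signal(s0, tensors, bvals, bvecs)

    disp = None
    if spec.displacement_mm != 0.0:
        disp = DisplacementField(
            field=np.full(density_raw.shape, float(spec.displacement_mm)),
            axis=spec.displacement_axis,
            voxel_size=spec.dmri_voxel,
        )
        warped = np.empty_like(signals)
        for i in range(signals.shape[-1]):
            warped[..., i] = apply_displacement(signals[..., i], disp)
        signals = warped

    if np.isfinite(spec.dmri_snr):
        mean_low = float(signals[..., :N_DW_LOW][wm].mean())
        sigma = mean_low / spec.dmri_snr
        signals = add_rician_noise(signals, sigma, rng)

    series = DWISeries(volumes=signals, bvals=bvals, bvecs=bvecs, affine=dmri_affine)
    return series, disp


def generate_cohort(spec: PhantomSpec) -> list[SyntheticSubject]:
    """Simulate the full cohort defined by a :class:`PhantomSpec`.

    Seeds are split hierarchically (cohort seed -> subject -> structure
    draws / MPM noise / dMRI noise), so identical specs reproduce
    bit-identical cohorts and per-subject streams are independent.
    """
    if spec.n_subjects < 1:
        raise ValueError("need at least one subject")
    dmri_affine = spec.centered_affine(spec.dmri_shape, spec.dmri_voxel)
    mpm_shape = spec.mpm_shape
    mpm_affine = spec.centered_affine(mpm_shape, spec.mpm_voxel)
    half_fov = spec.dmri_voxel * max(spec.dmri_shape) / 2.0

    masks_dmri = _structure_masks(spec.dmri_shape, dmri_affine, half_fov)
    masks_mpm = _structure_masks(mpm_shape, mpm_affine, half_fov)
    names = {s.name for s in spec.structures}
    if names != set(masks_dmri):
        raise ValueError(f"structure specs {sorted(names)} must match the layout {sorted(masks_dmri)}")

    # WM mask: per-structure one-voxel erosion on the diffusion grid, so the
    # mask stays clear of structure boundaries (and of MT resampling blends)
    wm_mask = np.zeros(spec.dmri_shape, dtype=bool)
    for m in masks_dmri.values():
        wm_mask |= ndimage.binary_erosion(m)

    subject_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    cohort = []
    for s_idx, sseed in enumerate(subject_seeds):
        draw_ss, mpm_ss, dwi_ss = sseed.spawn(3)
        values = _subject_structure_values(spec, np.random.default_rng(draw_ss))

        shape = spec.dmri_shape
        fvf = _paint(masks_dmri, {k: v["fvf"] for k, v in values.items()}, 0.0, shape)
        mvf = _paint(masks_dmri, {k: v["mvf"] for k, v in values.items()}, 0.0, shape)
        g_true = _paint(masks_dmri, {k: v["g"] for k, v in values.items()}, np.nan, shape)
        mt_true = _paint(
            masks_dmri, {k: spec.kappa * v["mvf"] for k, v in values.items()}, 0.0, shape
        )
        density_raw = spec.density_scale * fvf

        mpm_acq, mt_true_mpm = _simulate_mpm(
            spec, masks_mpm, values, mpm_affine, np.random.default_rng(mpm_ss)
        )
        dwi, disp = _simulate_dwi(
            spec, density_raw, fvf > 0, dmri_affine, np.random.default_rng(dwi_ss)
        )

        cohort.append(
            SyntheticSubject(
                subject_id=f"sub-{s_idx:02d}",
                mpm=mpm_acq,
                dwi=dwi,
                truth={
                    "fvf": fvf,
                    "mvf": mvf,
                    "g": g_true,
                    "mt_true": mt_true,
                    "density_true": density_raw,
                    "mt_true_mpm": mt_true_mpm,
                },
                wm_mask=wm_mask.copy(),
                structure_masks={k: m.copy() for k, m in masks_dmri.items()},
                dmri_affine=dmri_affine.copy(),
                mpm_affine=mpm_affine.copy(),
                displacement=disp,
                structure_values=values,
            )
        )
    return cohort


def make_reference_roi(subject: SyntheticSubject, n_intervals: int = 8) -> np.ndarray:
    """Splenium-like calibration ROI: the posterior-most anterior–posterior
    parcel of the corpus-callosum structure, restricted to its one-voxel
    eroded interior to avoid partial-volume edges."""
    from .group_stats import parcellate_cc

    cc = subject.structure_masks.get("cc")
    if cc is None or not cc.any():
        raise ValueError("phantom has no corpus-callosum structure")
    labels = parcellate_cc(cc, subject.dmri_affine, n_intervals=n_intervals)
    interior = ndimage.binary_erosion(cc)
    roi = (labels == 1) & interior
    if not roi.any():
        raise ValueError("reference ROI empty after erosion")
    return roi
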