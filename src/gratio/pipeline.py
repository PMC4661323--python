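"""End-to-end driver: phantom -> maps -> calibration -> g -> group stats.

``run_pipeline`` executes the requested stages on a synthetic cohort
and writes NIfTI maps, TSV tables, a calibration JSON and a manifest
recording the full configuration, seed and SHA-256 hashes of every
output, so a run is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .dwi_fit import fiber_density_proxy, fit_tensor_wls, tensor_indices
from .gratio_map import CalibrationRecord, calibrate_alpha, compute_g_map, resample_to_grid
from .group_stats import (
    GroupStack,
    cov_threshold_mask,
    group_summary,
    parcellate_cc,
    roi_statistics,
    wm_histogram,
)
from .io import write_volume
from .mpm_fit import fit_mpm
from .synthetic_data import PhantomSpec, generate_cohort, make_reference_roi

log = logging.getLogger("gratio")

__all__ = ["run_pipeline", "process_subject", "SubjectResult"]


@dataclass
class SubjectResult:
    """Per-subject derived maps on the diffusion grid."""

    subject_id: str
    mt_dmri: np.ndarray
    density: object  # DensityMap
    g_map: np.ndarray | None = None
    validity: np.ndarray | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def process_subject(subject, n_echoes: int = 6) -> SubjectResult:
    """MPM fit, MT resampling to the diffusion grid, tensor fit, density."""
    maps = fit_mpm(subject.mpm, n_echoes=n_echoes)
    mt_dmri = resample_to_grid(
        np.where(maps.valid, maps.mt_sat, np.nan),
        subject.mpm_affine,
        subject.dwi.volumes.shape[:3],
        subject.dmri_affine,
    )
    fit = fit_tensor_wls(subject.dwi)
    idx = tensor_indices(fit)
    density = fiber_density_proxy(idx, fit, subject.wm_mask)
    return SubjectResult(subject_id=subject.subject_id, mt_dmri=mt_dmri, density=density)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns (and writes) the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    outputs: dict[str, list[str]] = {}

    def record(stage: str, path: Path) -> None:
        outputs.setdefault(stage, []).append(str(path.relative_to(out_dir)))

    spec = PhantomSpec(seed=config.seed, **config.phantom.model_dump())
    log.info("simulating %d subjects", spec.n_subjects)
    cohort = generate_cohort(spec)

    if "simulate" in stages:
        for sub in cohort:
            p = out_dir / f"{sub.subject_id}_g_true.nii.gz"
            write_volume(sub.truth["g"], sub.dmri_affine, p)
            record("simulate", p)
        p = out_dir / "wm_mask.nii.gz"
        write_volume(cohort[0].wm_mask.astype(np.float32), cohort[0].dmri_affine, p)
        record("simulate", p)

    need_maps = any(s in stages for s in ("fit-mpm", "fit-dti", "density", "calibrate", "map", "group"))
    results: list[SubjectResult] = []
    if need_maps:
        for sub in cohort:
            log.info("fitting maps for %s", sub.subject_id)
            res = process_subject(sub, n_echoes=config.n_echoes)
            results.append(res)
            if "fit-mpm" in stages:
                p = out_dir / f"{res.subject_id}_MT_dmri.nii.gz"
                write_volume(res.mt_dmri, sub.dmri_affine, p)
                record("fit-mpm", p)
            if "density" in stages:
                p = out_dir / f"{res.subject_id}_density.nii.gz"
                write_volume(res.density.density, sub.dmri_affine, p)
                record("density", p)

    calibration: CalibrationRecord | None = None
    if config.alpha is not None:
        calibration = CalibrationRecord(
            alpha=config.alpha, reference_roi="fixed", g_reference=config.g_reference,
            calibration_mode="fixed",
        )
    elif "calibrate" in stages:
        cal_idx = config.calibration_subject
        if not 0 <= cal_idx < len(cohort):
            raise ValueError(f"calibration subject {cal_idx} outside cohort of {len(cohort)}")
        roi = make_reference_roi(cohort[cal_idx])
        calibration = calibrate_alpha(
            results[cal_idx].mt_dmri,
            results[cal_idx].density,
            roi,
            g_reference=config.g_reference,
            mode=config.calibration_mode,
            roi_name="splenium-like",
        )
        p = out_dir / "calibration.json"
        p.write_text(json.dumps(calibration.to_dict(), indent=2))
        record("calibrate", p)
        log.info("calibrated alpha = %.6g", calibration.alpha)

    if "map" in stages:
        if calibration is None:
            raise ValueError(
                "the 'map' stage needs a calibration: run 'calibrate' first or set alpha"
            )
        for sub, res in zip(cohort, results):
            g = compute_g_map(res.mt_dmri, res.density, calibration)
            res.g_map, res.validity = g.g_map, g.validity_mask
            p = out_dir / f"{res.subject_id}_g.nii.gz"
            write_volume(g.g_map, sub.dmri_affine, p)
            record("map", p)
            p = out_dir / f"{res.subject_id}_g_valid.nii.gz"
            write_volume(g.validity_mask.astype(np.float32), sub.dmri_affine, p)
            record("map", p)

    if "group" in stages:
        if not results or results[0].g_map is None:
            raise ValueError("the 'group' stage needs g maps: include the 'map' stage")
        stack = GroupStack(
            maps=np.stack([r.g_map for r in results]),
            subject_ids=[r.subject_id for r in results],
            affine=cohort[0].dmri_affine,
            modality="g",
        )
        summary = group_summary(stack)
        for name, vol in (
            ("group_mean_g", summary.mean_map),
            ("group_sd_g", summary.sd_map),
            ("group_cov_g", summary.cov_map),
        ):
            p = out_dir / f"{name}.nii.gz"
            write_volume(vol, stack.affine, p)
            record("group", p)
        cov_mask = cov_threshold_mask(summary, config.cov_threshold)
        hist = wm_histogram(
            summary.mean_map, cohort[0].wm_mask, cov_mask, bins=config.histogram_bins
        )
        p = out_dir / "wm_histogram.tsv"
        hist.to_csv(p, sep="\t", index=False)
        record("group", p)

        labels = parcellate_cc(cohort[0].structure_masks["cc"], cohort[0].dmri_affine)
        rois = {f"cc_{i}": labels == i for i in range(1, labels.max() + 1)}
        table, roi_summary = roi_statistics(stack, rois)
        for name, df in (("cc_roi_table", table), ("cc_roi_summary", roi_summary)):
            p = out_dir / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            record("group", p)

    manifest = {
        "package_version": __version__,
        "config": config.model_dump(mode="json"),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "calibration": calibration.to_dict() if calibration else None,
        "outputs": {
            stage: {f: _sha256(out_dir / f) for f in files} for stage, files in outputs.items()
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
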