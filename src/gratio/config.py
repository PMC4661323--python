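"""Run configuration: schema-validated parameters for the pipeline driver.

The configuration is a strict schema (unknown keys are rejected) and is
serialized in full into every output manifest, so any result can be
reproduced from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PhantomConfig", "RunConfig", "load_config"]

ALL_STAGES = ("simulate", "fit-mpm", "fit-dti", "density", "calibrate", "map", "group")


class PhantomConfig(BaseModel):
    """Synthetic-cohort parameters (subset of the generator's spec)."""

    model_config = ConfigDict(extra="forbid")

    n_subjects: int = 10
    dmri_shape: tuple[int, int, int] = (32, 32, 32)
    dmri_voxel: float = 2.3
    mpm_voxel: float = 0.8
    subject_sd_g: float = 0.02
    subject_sd_fvf: float = 0.02
    mpm_snr: float = 50.0
    dmri_snr: float = 20.0
    displacement_mm: float = 0.0
    displacement_axis: int = 1


class RunConfig(BaseModel):
    """Parameters of one pipeline run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: Path = Path("gratio_out")
    stages: list[str] = Field(default_factory=lambda: list(ALL_STAGES))
    n_echoes: int = 6
    calibration_mode: str = "mean-of-g"
    g_reference: float = 0.7
    calibration_subject: int = 0
    alpha: float | None = None  # fixed alpha skips calibration
    cov_threshold: float = 0.3
    prob_threshold: float = 0.5
    histogram_bins: int = 64
    log_level: str = "INFO"
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)

    def model_post_init(self, _ctx) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {ALL_STAGES}")

    def config_hash(self) -> str:
        """Hash of the scientifically relevant parameters (where the run is
        written and how verbosely it logs do not change the numbers)."""
        payload = self.model_dump(mode="json", exclude={"out_dir", "log_level"})
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    with open(path) as fh:
        return RunConfig.model_validate(json.load(fh))
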