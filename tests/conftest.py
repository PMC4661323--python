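"""Shared fixtures: small phantoms sized for fast, exact checks."""

import numpy as np
import pytest

from gratio.pipeline import process_subject
from gratio.synthetic_data import PhantomSpec, generate_cohort


@pytest.fixture(scope="session")
def noiseless_subject():
    """One subject with no noise, no between-subject variation."""
    spec = PhantomSpec(
        n_subjects=1,
        seed=1,
        dmri_shape=(24, 24, 24),
        mpm_voxel=1.15,
        subject_sd_g=0.0,
        subject_sd_fvf=0.0,
        mpm_snr=np.inf,
        dmri_snr=np.inf,
    )
    return generate_cohort(spec)[0]


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_subject):
    """Fitted MT (diffusion grid) and density maps for the noiseless subject."""
    return process_subject(noiseless_subject)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Three subjects at the default noise and between-subject variation."""
    spec = PhantomSpec(n_subjects=3, seed=7, dmri_shape=(24, 24, 24), mpm_voxel=1.15)
    return generate_cohort(spec)
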