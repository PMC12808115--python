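"""Shared fixtures: small phantom tasks and the desk-scale trained study.

The session-scoped ``desk_study`` fixture trains all four models once on
the noiseless separable phantom task (32x32 slices, T=100 diffusion steps,
n=10 samples) and runs the sigma_hat OOD sweep; the end-to-end tests all
read from it so training happens a single time per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from mrxform.data_io import make_paired_dataset
from mrxform.experiment import StudyConfig, run_study
from mrxform.phantom import PhantomSpec, generate_subject


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(
        image_size=32,
        n_slices=8,
        intensity_jitter_sd=0.0,
        bias_field_amplitude=0.0,
        noise_sd=0.0,
        geometry_jitter=0.05,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_subjects(noiseless_spec):
    return [generate_subject(noiseless_spec, i) for i in range(10)]


@pytest.fixture(scope="session")
def tiny_task():
    """A 16x16 phantom task small enough for quick optimization smoke tests."""
    spec = PhantomSpec(
        image_size=16,
        n_slices=4,
        intensity_jitter_sd=0.0,
        bias_field_amplitude=0.0,
        noise_sd=0.0,
        geometry_jitter=0.0,
        seed=1,
    )
    subjects = [generate_subject(spec, i) for i in range(6)]
    return make_paired_dataset(subjects, "t1", "t2", (0.7, 0.15, 0.15), seed=1)


@pytest.fixture(scope="session")
def desk_study():
    """Full scaled-down study: train all models, sample, score, OOD-sweep."""
    cfg = StudyConfig(calibrate=False, seed=7)
    return run_study(cfg, log=lambda *_: None)
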