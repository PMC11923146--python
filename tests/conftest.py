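"""Shared fixtures: small synthetic cohorts generated once per session."""

import numpy as np
import pytest

from ivcmossn.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def mixed_cohort():
    """A small rendered cohort with OSSN, normal and pathology images."""
    config = CohortConfig(
        n_patients=6,
        images_per_patient_mean=4,
        images_per_patient_dispersion=0,
        class_mix={"OSSN": 0.5, "normal": 0.3, "melanoma": 0.2},
        stratify_classes=True,
        mitosis_total=3,
        seed=3,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def label_cohort():
    """A 20-patient unrendered cohort (labels only) for aggregation studies."""
    config = CohortConfig(
        n_patients=20,
        images_per_patient_mean=27,
        images_per_patient_dispersion=0,
        cells_per_image_mean=30,
        cells_per_image_dispersion=0,
        class_mix={"OSSN": 0.5, "normal": 0.5},
        stratify_classes=True,
        seed=123,
    )
    _, truth = generate_cohort(config, render=False)
    return truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
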