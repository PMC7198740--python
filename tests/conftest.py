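"""Shared fixtures: phantom cohorts and a prebuilt normal database.

The expensive fixtures (20-case cohort and its registered database) are
session-scoped so the registration work is done once for all tests that
score patients or measure map gradients.
"""

import numpy as np
import pytest

from vqmaps import PhantomConfig, generate_case, generate_cohort
from vqmaps.pipeline import build_database

STUDY_SEED = 11
COHORT_N = 20


@pytest.fixture(scope="session")
def default_config():
    return PhantomConfig(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config, COHORT_N)


@pytest.fixture(scope="session")
def default_db(default_cohort):
    return build_database(default_cohort)


@pytest.fixture(scope="session")
def clean_config():
    """Fully deterministic phantom: no noise, no warp, no subject spread."""
    return PhantomConfig(
        seed=STUDY_SEED, g_sigma=0.0, deform_amp_mm=0.0,
        affine_scale_range=0.0, noise=False,
    )


@pytest.fixture(scope="session")
def clean_case(clean_config):
    return generate_case(clean_config, 0)


@pytest.fixture(scope="session")
def held_out_patient(default_config):
    """A normal phantom outside the database cohort (subject index 100)."""
    return generate_case(default_config, 100)
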