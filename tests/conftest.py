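import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gutlink as gl
from gutlink.synthetic_data import TruthConfig

# property tests must be reproducible across runs
settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

logging.getLogger("gutlink").setLevel(logging.WARNING)


NULL_CONFIG = TruthConfig(
    n_differential_bacteria=0, n_differential_virus=0, n_confounded=0,
    n_mediation_paths=0)


def null_config() -> TruthConfig:
    return NULL_CONFIG


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scale cohort (77 cases / 70 controls) with planted truth."""
    return gl.generate_cohort(seed=11)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with nothing planted (for calibration checks)."""
    return gl.generate_cohort(truth_config=NULL_CONFIG, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
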