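import numpy as np
import pytest

from roitex import (
    default_config,
    feature_table_from_subjects,
    generate_cohort,
)
from roitex.config import GeneratorConfig, GroupParams, GroupSideParams


@pytest.fixture(scope="session")
def calibrated_cohort():
    """One reference-calibrated 33-per-group cohort (seed 1), with features."""
    cfg = default_config(rng_seed=1)
    subjects, manifest = generate_cohort(cfg)
    features = feature_table_from_subjects(subjects)
    return cfg, subjects, features


def small_config(seed: int = 0, n: int = 3, pixcount: float = 120.0,
                 delta_mu_left: float = 0.0) -> GeneratorConfig:
    """A fast scaled-down two-group config for smoke and Monte-Carlo tests."""

    def side(mu):
        return GroupSideParams(
            mu_subject=mu, sigma_subject=50.0, sigma_within=30.0,
            gamma_within=0.1, pixcount_mean=pixcount, pixcount_sd=pixcount * 0.1,
        )

    groups = {
        "bipolar": GroupParams(
            female_count=min(2, n), age_mean=36.0, age_sd=12.0,
            sides={"left": side(500.0 + delta_mu_left), "right": side(470.0)},
        ),
        "control": GroupParams(
            female_count=min(2, n), age_mean=37.0, age_sd=13.0,
            sides={"left": side(500.0), "right": side(470.0)},
        ),
    }
    return GeneratorConfig(groups=groups, n_per_group=n, rng_seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
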