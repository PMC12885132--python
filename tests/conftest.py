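from datetime import date

import numpy as np
import pytest

from smokeptb.simulate import (
    CohortConfig,
    ExposureProcessParams,
    HazardParams,
    simulate_cohort,
)


def quick_config(n=600, seed=42, **kw):
    """A small, fast cohort configuration for unit tests."""
    defaults = dict(
        n_pregnancies=n,
        n_sites=6,
        n_tracts_per_site=2,
        conception_start=date(2016, 1, 1),
        conception_end=date(2018, 12, 31),
        exposure_end_date=date(2019, 12, 31),
        seed=seed,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(quick_config())


@pytest.fixture(scope="session")
def null_hazard():
    """Hazard with no exposure effect, no covariate effects, no clustering."""
    return HazardParams(beta_exposure=0.0, beta_covariates={}, sigma_site=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
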