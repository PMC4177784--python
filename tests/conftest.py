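import dataclasses

import pytest

from lipidecay.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """One default synthetic cohort (5 x 30 patients), shared across tests."""
    return generate_cohort(default_config)


@pytest.fixture()
def noise_free_config() -> CohortConfig:
    """All stochastic lipid variation off: decay and covariate effects only."""
    return CohortConfig(
        seed=5,
        random_intercept_sd=0.0,
        residual_sd=0.0,
        followup_trend_tc=(0.0, 0.0),
        followup_trend_hdl=(0.0, 0.0),
    )


def small_config(seed: int = 0, **overrides) -> CohortConfig:
    """A reduced cohort for fast fitting tests (3 subcohorts x 12 patients)."""
    base = dict(
        n_patients_per_subcohort=12,
        subcohort_periods=((1985, 1989), (1995, 1999), (2005, 2009)),
        covariate_params={
            k: (v[0], v[2], v[4])
            for k, v in CohortConfig().covariate_params.items()
        },
        seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)
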