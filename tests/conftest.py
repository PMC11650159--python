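"""Shared fixtures.

The expensive hierarchical fit on a 40-participant cohort is session-scoped
and shared between the acceptance suite and the invariant tests that need a
full-scale posterior.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import foragefit as ff


@pytest.fixture(scope="session")
def default_config() -> ff.EnvironmentConfig:
    return ff.EnvironmentConfig()


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """12-participant cohort for cheap integration tests."""
    gp = {"mdd": ff.GroupParams(), "comparison": ff.GroupParams()}
    trials, truth, participants = ff.simulate_cohort(8, 4, gp, default_config, 1234)
    return trials, truth, participants


@pytest.fixture(scope="session")
def recovery_cohort(default_config):
    """40 MDD + 1 comparison cohort, generator matched to the fitted model."""
    gp = {"mdd": ff.GroupParams(), "comparison": ff.GroupParams()}
    trials, truth, participants = ff.simulate_cohort(40, 1, gp, default_config, 11)
    return trials, truth, participants


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort, default_config):
    """Reduced-sampler hierarchical fit of the 40-participant cohort."""
    trials, _, _ = recovery_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = ff.fit_hierarchical(
            trials,
            default_config,
            ff.SamplerSettings(chains=2, warmup=500, draws=500),
            seed=3,
        )
    return fit


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
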