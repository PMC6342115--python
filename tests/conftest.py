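import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from prefsdm import (
    GridGeometry,
    MaternHyperparams,
    ModelSpec,
    ScenarioConfig,
    fit,
    make_scenario,
)


@pytest.fixture(scope="session")
def small_grid():
    return GridGeometry(16, 16)


@pytest.fixture(scope="session")
def hyper6():
    """Unit-variance field with a 6-cell range."""
    return MaternHyperparams(sigma2=1.0, range_=6.0)


@pytest.fixture(scope="session")
def small_scenario():
    """A compact preferential-sampling scenario used across model tests."""
    cfg = ScenarioConfig(
        grid=GridGeometry(16, 16),
        hyper=MaternHyperparams(sigma2=1.0, range_=3.2),
        n=40,
        b=1.0,
    )
    return make_scenario(cfg, seed=42)


@pytest.fixture(scope="session")
def small_pref_fit(small_scenario):
    """One converged preferential fit on the compact scenario."""
    fr = fit(ModelSpec(preferential=True), small_scenario.preferential, outer_maxfev=80)
    assert fr.converged
    return fr


@pytest.fixture(scope="session")
def small_nonpref_fit(small_scenario):
    fr = fit(ModelSpec(preferential=False), small_scenario.preferential, outer_maxfev=80)
    assert fr.converged
    return fr
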