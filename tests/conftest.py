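import pytest
from hypothesis import settings

from auxbias import Scenario, ScenarioSpec

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def s1_unit() -> ScenarioSpec:
    """Y-incomplete, missingness caused by Y; all active effects and variances 1."""
    return ScenarioSpec(Scenario.S1, beta_YX=1, beta_RY=1, beta_RZ=1, pi_obs=0.5)


@pytest.fixture
def s2x_unit() -> ScenarioSpec:
    """X-incomplete, missingness via unmeasured U; active effects 1."""
    return ScenarioSpec(Scenario.S2_X, beta_YX=1, beta_YU=1, beta_RU=1, beta_RZ=1, pi_obs=0.5)


@pytest.fixture
def s3y_unit() -> ScenarioSpec:
    """Y-incomplete, missingness caused by Y and X; active effects 1."""
    return ScenarioSpec(
        Scenario.S3_Y, beta_YX=1, beta_RY=1, beta_RX=1, beta_RZ=1, pi_obs=0.5
    )


@pytest.fixture
def mcar_spec() -> ScenarioSpec:
    """No path into the missingness score: data missing completely at random."""
    return ScenarioSpec(Scenario.S1, beta_YX=1, beta_RY=0, beta_RZ=0, pi_obs=0.5)
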