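import pytest

from nodal_tei.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized cohort under default (study-condition) parameters."""
    return simulate_cohort(SimulationConfig(n_patients=500, seed=123))


@pytest.fixture(scope="session")
def large_cohort():
    """n=10000 cohort for marginal checks with tight binomial bands."""
    return simulate_cohort(SimulationConfig(n_patients=10000, seed=202))
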