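import numpy as np
import pytest

from polyarch import SimulationScenario, TraitDesign, get_ncp_map, simulate_z


@pytest.fixture(scope="session")
def binary_design() -> TraitDesign:
    """The workhorse case-control design: 3500/3500, prevalence 0.001."""
    return TraitDesign("binary", n_cases=3500, n_controls=3500, prevalence=0.001)


@pytest.fixture(scope="session")
def continuous_design() -> TraitDesign:
    return TraitDesign("continuous", n_total=1000)


@pytest.fixture(scope="session")
def binary_map(binary_design):
    return get_ncp_map(binary_design)


@pytest.fixture(scope="session")
def scenario1000() -> SimulationScenario:
    return SimulationScenario(lambda_true=1000.0, seed=20_201_117)


@pytest.fixture(scope="session")
def scan1000(scenario1000) -> np.ndarray:
    """One full simulated scan (100,000 z-values) at lambda=1000."""
    return simulate_z(scenario1000, np.random.default_rng(1))
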