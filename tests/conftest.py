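import numpy as np
import pytest

from metaprl import CohortSpec, HGFParams, TaskConfig, default_priors, generate_cohort
from metaprl.cohort import build_analysis_table
from metaprl.metacog import MockScorer


@pytest.fixture(scope="session")
def config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def priors():
    return default_priors()


@pytest.fixture(scope="session")
def mock_scorer() -> MockScorer:
    return MockScorer()


@pytest.fixture(scope="session")
def cohort200():
    """Mid-sized synthetic cohort with sessions, shared across tests."""
    return generate_cohort(CohortSpec(n_total=200, n_high_paranoia=41, seed=7))


@pytest.fixture(scope="session")
def cohort200_table(cohort200, mock_scorer):
    return build_analysis_table(cohort200, mock_scorer)


def draw_population_params(rng: np.random.Generator, n: int, mean=-2.6, sd=1.0):
    """Participants' HGF parameters with population spread in mu3_0 only."""
    out = {}
    for i in range(n):
        mu3 = float(rng.normal(mean, sd))
        out[f"s{i:03d}"] = HGFParams(mu3_0=mu3, m3=mu3)
    return out
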