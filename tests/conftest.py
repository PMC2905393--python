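import numpy as np
import pytest

from stresschip.pipeline import PipelineResult, run_synthetic_analysis
from stresschip.synthetic_data import SimConfig, simulate_all


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(default_config):
    """One full synthetic dataset shared across the suite."""
    return simulate_all(default_config)


@pytest.fixture(scope="session")
def pipeline_result(default_config) -> PipelineResult:
    """One full generate-analyse-score run shared across the suite."""
    return run_synthetic_analysis(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
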