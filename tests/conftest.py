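import numpy as np
import pandas as pd
import pytest

from prolifsig import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """A fast, reduced-size cohort configuration for unit tests."""
    return SimulationConfig(
        n_patients=60,
        n_genes=120,
        n_signature_genes=20,
        module_size=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study-scale conditions (94 patients)."""
    return simulate_cohort(SimulationConfig(n_genes=400, seed=11))


@pytest.fixture
def toy_records():
    """Twenty survival records with ties and mixed censoring."""
    gen = np.random.default_rng(42)
    time = np.round(gen.exponential(50, size=20), 0) + 1
    event = gen.integers(0, 2, size=20)
    event[:2] = 1  # guarantee events exist
    return pd.DataFrame(
        {"time": time.astype(float), "event": event},
        index=[f"P{i}" for i in range(20)],
    )
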