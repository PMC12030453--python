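import pandas as pd
import pytest

from lignotrial.fiber_chemistry import composition_table
from lignotrial.synthetic_trial import SimulationConfig, generate_trial
from lignotrial.trial_data import load_fixture, plots_to_frame


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2() -> pd.DataFrame:
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table3() -> pd.DataFrame:
    return load_fixture("table3")


@pytest.fixture(scope="session")
def table4() -> pd.DataFrame:
    return load_fixture("table4")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced augmented design that keeps REML fits fast in unit tests."""
    return SimulationConfig(
        n_test_entries=12, n_checks=3, n_blocks_per_env=2, seed=42
    )


@pytest.fixture(scope="session")
def small_trial(small_config):
    plots, truth = generate_trial(small_config)
    frame = composition_table(plots_to_frame(plots))
    return frame, truth
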