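import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cardiocea.cea import compare
from cardiocea.engine import default_strategies, run_strategies, total_outcomes
from cardiocea.fixtures import default_parameters, synth_life_table

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ps():
    return default_parameters()


@pytest.fixture(scope="session")
def lt():
    return synth_life_table()


@pytest.fixture(scope="session")
def strategies():
    return default_strategies()


@pytest.fixture(scope="session")
def base_traces(ps, lt, strategies):
    """Base-case cohort traces for all three strategies (shared across
    tests; the engine is deterministic for scalar parameters)."""
    return run_strategies(strategies, ps, lt)


@pytest.fixture(scope="session")
def base_result(base_traces):
    return compare({k: total_outcomes(t) for k, t in base_traces.items()})
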