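import copy

import pytest

from ugc_cea.cea import StrategyOutcome
from ugc_cea.defaults import REFERENCE_OUTCOMES
from ugc_cea.synthetic import SyntheticSpec, synth_parameter_set


@pytest.fixture(scope="session")
def base_params():
    """Default synthetic parameter set (seed 0); treat as read-only."""
    return synth_parameter_set(SyntheticSpec(seed=0))


@pytest.fixture()
def params(base_params):
    """Mutable copy of the default parameter set."""
    return copy.deepcopy(base_params)


@pytest.fixture(scope="session")
def reference_outcomes():
    """Published (cost, QALY) points: seven dominant strategies + no screening."""
    return [StrategyOutcome(code, cost, qalys) for code, cost, qalys in REFERENCE_OUTCOMES]
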