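import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*convergence.*")


@pytest.fixture(scope="session")
def bundle():
    """One full synthetic mission shared across the suite."""
    from crewnet.simulate import make_reference_fixture

    return make_reference_fixture(seed=3)


@pytest.fixture(scope="session")
def scored_panel(bundle):
    from crewnet.psych import score_panel

    return score_panel(bundle["responses"])


@pytest.fixture(scope="session")
def roster(bundle):
    return bundle["roster"]


@pytest.fixture(scope="session")
def m1_graph(bundle):
    from crewnet.networks import aggregate_graph

    scenario = bundle["scenario"]
    return aggregate_graph(bundle["contacts"], scenario.windows[0], bundle["roster"])
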