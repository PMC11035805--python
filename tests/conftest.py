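import numpy as np
import pytest

from cartdoe import mlr, synthetic as syn


@pytest.fixture(scope="session")
def space():
    return syn.default_space()


@pytest.fixture(scope="session")
def study42():
    """A default 26-run synthetic study with the standard effect structure."""
    return syn.make_study(seed=42)


@pytest.fixture(scope="session")
def responses42(study42):
    return syn.generate_responses(study42)


@pytest.fixture(scope="session")
def growth_model(study42, responses42):
    return mlr.backward_eliminate(
        study42.space, responses42, responses42["cpd"].to_numpy(),
        response_name="cpd",
    )


@pytest.fixture(scope="session")
def exhaustion_model(study42, responses42):
    return mlr.backward_eliminate(
        study42.space, responses42, responses42["pd1lag3_pct"].to_numpy(),
        response_name="pd1lag3_pct",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
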