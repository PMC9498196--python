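import numpy as np
import pytest

from beliefsim import AgentState, Population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_population(*agents: AgentState, t: int = 0) -> Population:
    """Build a small population from explicit agent states."""
    return Population.from_agents(list(agents), t=t)
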